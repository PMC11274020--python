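"""From interval positions to proximity ranks and cumulative curves.

A herd with a planted cohesion hierarchy (per-animal spreads from 10 m, very
cohesive, to 150 m, peripheral) is simulated at study scale; the pipeline
ranks every animal within every 15-minute interval by its median distance to
herdmates, takes daily median ranks, and accumulates them.  Low final
cumulative values flag the animals that stayed central — the planted order
should be recovered.
"""

import herdrank as hr

cfg = hr.SimConfig(seed=0)  # 17 cows, 45 days, sigma 10-150 m, phi = 0.9
sim = hr.simulate_message_log(cfg)
mapped = hr.apply_collar_map(sim.messages, hr.CollarMap(sim.collar_map))
intervals, _ = hr.exclude_days(hr.bin_15min(mapped.records))

med = hr.interval_median_distances(intervals)
iranks = hr.rank_distances(med, policy="present-only")
daily = hr.daily_median_rank(iranks)
finals = hr.final_cumulative(hr.cumulative_curve(daily))

print("final cumulative daily-median rank (low = spatially central):")
for cow, value in finals.sort_values().items():
    print(f"  {cow}: {value:7.1f}")

planted = sim.hierarchy.cow_ids
rho = hr.spearman_rho([sim.hierarchy.position(c) for c in finals.index],
                      finals.to_numpy())
print(f"\nplanted order (most cohesive first): {planted[:3]} ...")
print(f"Spearman(planted order, cumulative order) = {rho:.3f}")
# rho near 1 means the cumulative curve ordering recovers the built-in
# cohesion hierarchy despite GPS noise and per-animal poll offsets
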