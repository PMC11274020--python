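"""Is the observed structure real, or GPS error?  The randomization null.

Within every 15-minute interval the per-animal median distances are shuffled
across animals, destroying identity while preserving the distance
distribution — the situation where rankings are pure noise.  Ten replicated
null pipelines give the span of cumulative finals and Mann–Whitney U maps to
hold against the structured data.
"""

import herdrank as hr

cfg = hr.SimConfig(seed=0)
sim = hr.simulate_message_log(cfg)
mapped = hr.apply_collar_map(sim.messages, hr.CollarMap(sim.collar_map))
intervals, _ = hr.exclude_days(hr.bin_15min(mapped.records))
med = hr.interval_median_distances(intervals)
daily = hr.daily_median_rank(hr.rank_distances(med))
finals = hr.final_cumulative(hr.cumulative_curve(daily))

reps = hr.run_null_replicates(med, n_reps=10, base_seed=0)
lo, hi = hr.cumulative_range(reps)
print(f"original cumulative finals: [{finals.min():.2f}, {finals.max():.2f}]")
print(f"randomized (10 replicates): [{lo:.2f}, {hi:.2f}]")
# real structure spreads the curves far apart; the null stays near
# n_days * (n_cows + 1) / 2 because every animal's rank is uniform

cmp_ = hr.build_mwu_matrices(daily, reps[:3])
s = cmp_.summary
print(f"\nanimal-vs-animal U tests significant at 0.05:")
print(f"  original data:        {s['original_significant_fraction']:.0%}")
print(f"  randomized replicates:{s['replicate_significant_fraction']:.0%}")
print(f"  original vs own null: {s['orig_vs_rep_significant_fraction']:.0%}")
# many significant cells in the original but few between null replicates
# indicate that the ranking reflects animals, not receiver inaccuracy
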