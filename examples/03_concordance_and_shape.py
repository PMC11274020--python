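"""Day-to-day concordance and the shape of each animal's rank distribution.

Computes Kendall's W over the days-by-animals matrix of daily median ranks
(W = 1: the herd lines up identically every day; E[W] = 1/m_days under
independence), then summarises each animal's rank distribution by moment
skewness, non-excess kurtosis and its density peak — the same quantities
tabulated for the real reference herd bundled with the package.
"""

import herdrank as hr

cfg = hr.SimConfig(seed=0)
sim = hr.simulate_message_log(cfg)
mapped = hr.apply_collar_map(sim.messages, hr.CollarMap(sim.collar_map))
intervals, _ = hr.exclude_days(hr.bin_15min(mapped.records))
daily = hr.daily_median_rank(hr.rank_distances(hr.interval_median_distances(intervals)))

wide = daily.pivot(index="day", columns="cow_id", values="median_rank").dropna()
conc = hr.kendalls_w(wide)
print(f"Kendall's W = {conc.w:.3f} over {conc.m_days} days x {conc.n_cows} cows "
      f"(chi2 = {conc.chi2:.1f}, df = {conc.df}, p = {conc.p:.2e})")
print(f"random-ranking reference level 1/m = {1 / conc.m_days:.3f}")

dens = hr.density_summary(daily)
print("\nper-animal shape of the daily-rank distribution:")
print(dens.round(2).to_string(index=False))

ref = hr.load_reference_shape_stats()
rho = hr.spearman_rho(ref["skewness"], ref["peak_x"])
print(f"\nreference herd: Spearman(skewness, peak location) = {rho:.2f}")
# negative rho: animals whose rank density peaks low (central animals) tend
# to be right-skewed -- occasional days on the herd edge, never the reverse
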