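# herdrank

Spatial proximity ranking for GPS-collared herds.

Virtual-fence systems (GPS collars that replace physical fencing with audio
cues and mild electric pulses) log a position for every animal every few
minutes. If a herd keeps a stable spatial structure — some animals always
central, some peripheral — the central "leader" animals could carry collars
on behalf of the group, cutting hardware costs. `herdrank` implements the
analysis chain used to look for such structure in collar message logs, for
movement ecologists and livestock researchers:

1. **Ingest** — parse collar message CSVs (polls, border warnings and zaps
   all carry GPS fixes), map collar serials to animals across hardware
   replacements, bin fixes into aligned 15-minute UTC intervals by
   coordinate-wise medians, and drop days with incomplete herd registration.
2. **Ranking** — per interval, compute all pairwise great-circle distances
   d_ij; each animal's proximity score is the median of its n−1 distances,
   m_i = median_j d_ij. Scores are ranked ascending (rank 1 = closest to the
   herd, midranks on ties). Per day, D_i = median over intervals of r_i; the
   cumulative curve C_i(T) = Σ_{t≤T} D_i(t) summarises persistent centrality.
3. **Statistics** — Kendall's coefficient of concordance over the
   days × animals matrix of daily ranks,

       W = 12 Σ_i (R_i − m(n+1)/2)² / (m²(n³−n) − m Σ_j T_j),

   with χ² = m(n−1)W on n−1 df (days are raters, animals items; E[W] = 1/m
   under independence); per-animal moment skewness, non-excess kurtosis
   (normal = 3), Gaussian-KDE density peaks (Silverman bandwidth), Spearman
   correlations and boxplot five-number summaries.
4. **Accuracy null** — shuffle which animal owns which median distance
   within every interval (preserving each interval's distance multiset),
   rerun the ranking for 10 replicates, and compare cumulative ranges and
   pairwise Mann–Whitney U matrices against the original: real structure
   gives a wide cumulative span and many significant animal-vs-animal
   differences, noise-dominated data do not.
5. **Synthetic herds** — a correlated-random-walk herd centroid with
   per-animal AR(1) displacements of spread σ_i plants a known cohesion
   hierarchy, so every stage (and the recovery claim itself) is testable
   without field data.

## Worked example

```python
import herdrank as hr

cfg = hr.SimConfig(seed=0)            # 17 cows, 45 days, sigma 10-150 m
sim = hr.simulate_message_log(cfg)
mapped = hr.apply_collar_map(sim.messages, hr.CollarMap(sim.collar_map))
intervals, _ = hr.exclude_days(hr.bin_15min(mapped.records))
med = hr.interval_median_distances(intervals)
daily = hr.daily_median_rank(hr.rank_distances(med))
finals = hr.final_cumulative(hr.cumulative_curve(daily))
reps = hr.run_null_replicates(med, n_reps=10, base_seed=0)
print(finals.min(), finals.max(), hr.cumulative_range(reps))
```

Running `python examples/04_accuracy_null.py` (the same computation with
commentary) prints:

```
original cumulative finals: [135.00, 633.25]
randomized (10 replicates): [378.00, 408.00]

animal-vs-animal U tests significant at 0.05:
  original data:        97%
  randomized replicates:9%
  original vs own null: 94%
```

The structured herd spreads its cumulative finals over ~500 rank units while
the randomized replicates stay in a ~30-unit band around
n_days·(n_cows+1)/2, and almost every animal pair differs significantly in
the original data but not between null replicates — the signature of real
spatial structure rather than GPS error. `examples/02_rank_pipeline.py`
shows the planted cohesion order recovered perfectly from the message log
(Spearman 1.000), and `examples/03_concordance_and_shape.py` prints the
concordance and per-animal shape table.

A command-line interface wraps the same pipeline:

```sh
herdrank simulate --out data/ --seed 42
herdrank run --messages data/messages.csv --collars data/collars.csv \
             --out results/ --null-reps 10 --seed 1
```

## Layout

- `src/herdrank/` — `ingest`, `ranking`, `stats`, `nullmodel`, `simulate`,
  `pipeline` (+ thin `cli`), `datasets` (bundled reference shape table).
- `examples/` — one narrative script per capability.
- `docs/methods.md` — models, conventions, parameter choices, limitations.
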