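# Methods

## The quantity being estimated

For a herd of n collared animals observed over m days, the pipeline asks
whether the herd's *spatial* organisation is stable: does the same animal
tend to sit at the centre (or the edge) of the group day after day?  The
primitive is the per-interval proximity score — in each aligned 15-minute
UTC interval, animal i's score is the median of its n−1 great-circle
distances to herdmates — converted to a within-interval rank (1 = most
central).  Medians are used at both aggregation steps (within-interval
coordinates, within-day ranks) because collar data are lossy and
heavy-tailed; a single bad fix or missed poll should not move the day's
summary.

## Ingestion conventions

- **Intervals** are half-open [t, t + 15 min) anchored at 00:00:00 UTC;
  `interval_index = floor(seconds_since_midnight / 900)`.  A fix exactly on
  a boundary belongs to the *later* interval.  Binning is idempotent: an
  already-binned stream re-bins to itself.
- **Coordinate medians** are taken per axis; for even counts, the mean of
  the two central values.  Polls, border warnings and zap events are pooled
  before the median — all three message types carry GPS fixes, and medians
  are order-free.
- **Collar replacement**: a serial belongs to exactly one animal; an animal
  may own several serials with non-overlapping validity windows (inclusive
  dates).  Overlaps are configuration errors, not warnings.
- **Strict vs lenient parsing**: strict (default) aborts on the first
  malformed row with its line number — for research reproducibility a
  silently shrinking dataset is worse than a crash.  Lenient mode skips and
  counts, preserving `len(records) + len(rejected) = rows in`.
- **Day exclusion**: a day is kept iff at least `required_cows` distinct
  animals registered at least one interval position (default: the full herd
  observed anywhere in the table).  The kept-day count is always derived
  from data, never assumed.

## Ranking conventions

- **Distance**: haversine on a sphere of radius 6 371 008.8 m.  At paddock
  extents (≤ a few km) the spherical-vs-ellipsoidal error is far below GPS
  noise.
- **Ties** receive midranks, preserving the invariant
  Σ ranks = n_present(n_present+1)/2 per interval under any tie pattern.
- **Missing animals within a kept day**: default policy `present-only`
  ranks among whoever is present (ranks 1..n_present); `complete-only`
  instead drops intervals with any absence.  Both are exposed because field
  collars lose signal for short stretches and neither choice is neutral:
  present-only keeps more data but lets interval rank scales vary;
  complete-only is scale-clean but discards most intervals at high herd
  sizes.  `complete-only` recounts group sizes rather than trusting a
  stored column, so it behaves correctly on pre-filtered tables.
- **Cumulative gaps**: if an animal has no daily rank on a kept day, the
  curve carries forward (adds nothing) and the gap is logged; the
  alternative `impute-herd-median` adds that day's herd-median rank.
  Carry-forward is the default because fabricated ranks feed straight into
  the concordance input.

## Concordance and shape statistics

- **Kendall's W** is computed on *rankings*: each day's vector of daily
  median ranks is first re-ranked 1..n with midranks (daily medians are not
  themselves a permutation), then

      W = 12 Σ_i (R_i − m(n+1)/2)² / (m²(n³−n) − m Σ_j T_j),

  T_j = Σ(t³−t) over tie groups in day j.  Significance via
  χ² = m(n−1)W, df = n−1.  Whether a published W used the tie correction is
  often unknowable, so the result carries both `W` (corrected) and
  `W_uncorrected` side by side.  Under independent random rankings
  E[W] = 1/m (because E[χ²] = n−1); the test suite verifies the mean over
  random-rank replicates at m = 45, n = 17.
- **Moments** use population (n-normalised) central moments:
  skewness m₃/m₂^{3/2}, kurtosis m₄/m₂² *non-excess* (normal = 3) — the
  convention of the classical moment tables this field reports (±0.5
  skewed, ±1 extremely skewed; kurtosis above 3 peaked).  Many libraries
  default to excess kurtosis and bias-corrected skewness; both are pinned
  here, with bias-corrected variants behind a flag.
- **Density peaks**: Gaussian kernel, bandwidth by the rule of thumb
  0.9·min(sd, IQR/1.34)·n^{−1/5} (with the classical fallback chain when the
  IQR degenerates), evaluated on a 512-point grid spanning
  [min − 3bw, max + 3bw].  The peak is the grid argmax; exact ties break to
  the lower abscissa.  Peak height is reported as density × 100, so a
  density of 0.2422 prints as 24.22 "%"; heights can exceed 100 for very
  concentrated rank distributions.  Kernel, bandwidth and grid are exposed,
  and the bandwidth used is echoed in every output row for audit, because
  peak values are not comparable across bandwidth rules.
- **Quartiles** interpolate linearly between order statistics (type 7).
  Boxplot min/max are taken over all data; the 1.5·IQR fences only decide
  which points are listed as outliers.

## The accuracy null

"Would we see this structure if positions were dominated by receiver
error?"  Two randomization modes:

- **permute** (default): within every interval, shuffle which animal owns
  which median neighbour distance.  This removes animal identity exactly
  while preserving each interval's distance multiset, making every animal's
  rank uniform on 1..n_present.  It is the sharper null and needs no noise
  model.
- **jitter**: add isotropic Gaussian error (default 5 m per axis, matching
  receivers rated 3.5–10 m accuracy) to the interval positions and
  recompute distances — the physically-motivated alternative.

Each of the (default 10) replicates reruns ranking → daily medians →
cumulative curves; outputs are the span of cumulative finals over all
animals × replicates, Kendall's W per replicate, and three Mann–Whitney U
families: animal-vs-animal within the original data, within each replicate,
and each animal against its own randomized self.  U tests use the exact
enumeration distribution when the pooled sample is ≤ 20 and tie-free,
otherwise the normal approximation with tie and continuity corrections.
P-value matrices are reported uncorrected (they are descriptive maps, not a
family of confirmatory tests); a Holm adjustment can be applied downstream.

Under the permute null with complete data, final cumulative values
concentrate near m·(n+1)/2 (405 for 45 days and 17 animals).  Missing
intervals pull the whole null down slightly because ranks then run
1..n_present; with ~3% dropout the centre sits near 394.

**Seeding.**  Replicate k uses the k-th spawned child of
`SeedSequence(base_seed)`.  Children are independent of each other *and* of
any generator seeded directly with `base_seed` — important because numpy's
`default_rng((s, 0))` produces the same stream as `default_rng(s)`, so naive
tuple seeds can silently correlate a replicate with the stream that
generated its input data.  The `(base_seed, k)` pair is recorded on each
replicate for audit.

## The synthetic herd

The generator produces the statistical situation the analysis assumes — a
cohesive herd with a *known* centrality ordering:

- The herd centroid follows a correlated random walk: lognormal step
  lengths (median 15 m per 15-minute step, log-sd 0.6) and wrapped-normal
  turning angles (sd 1 rad) — an undirected grazing drift of a few hundred
  metres per day.
- Animal i's displacement from the centroid is a first-order
  autoregressive process per axis with persistence φ = 0.9 per 15-minute
  step (decorrelation time ≈ 2.5 h) and stationary spread σ_i.  The
  ascending-σ order *is* the planted hierarchy; σ defaults span 10–150 m —
  plausible for a 160-ha coastal paddock, though no published spread
  distribution exists to calibrate against.
- Collars poll once per interval at an animal-specific phase offset
  (uniform on [0, 15) min, emulating unaligned poll timers), with isotropic
  Gaussian GPS error (default sd 2.5 m per axis, the optimistic end of the
  3.5–10 m accuracy band since fixes are medianed within intervals),
  independent message dropout (default 3%), and optional whole-day outages
  per animal — the situation the day-exclusion filter must catch.
- Defaults are 17 animals, 45 days, 96 intervals/day, origin (55.42° N,
  8.40° E), matching the study setting the pipeline targets.

What the generator deliberately does **not** emulate: directed travel and
leadership *in movement* (the hierarchy is purely a dwell-distance
hierarchy), behavioural responses to the virtual border, spatially
correlated GPS error (multipath, canopy), diurnal activity rhythms, and
herd fission–fusion.  Passing recovery tests therefore show that the
pipeline recovers a proximity hierarchy *when one exists and is stationary*;
they cannot show that real herds have one.

**Noise robustness, as measured.**  With spreads σ ≥ 50 m, adding 2.5 m GPS
error changes about a quarter of interval ranks — but almost entirely by
single adjacent swaps: fewer than 5% of interval ranks move by more than
one position, daily median ranks never move by more than one, and the final
cumulative ordering is preserved (Spearman ≥ 0.99) for error up to 10 m.
Raw interval ranks are noise-sensitive; the median/cumulative aggregation
is what makes the method robust at receiver-grade accuracy.

## Problem sizes in the test suite

The acceptance-level tests run the full study scale (17 × 45 × 96, 10 null
replicates) because those quantities are scale-dependent; unit and property
tests use 2–10 animals over hours–weeks, which exercises every code path at
a fraction of the cost.  The Mann–Whitney type-I calibration pairs
*corresponding* animals across disjoint independent null replicates (170
independent tests) rather than full cross-matrices, whose cells share
samples and would not be binomially distributed.

## Known limitations

- Ranks are relative: n_present varies under `present-only`, so interval
  ranks from days with many missing animals are on a compressed scale.
- The cumulative curve inherits any systematic missingness (an animal
  absent on many days accumulates less under carry-forward; the imputation
  policy trades that bias for fabricated values).
- KDE peak locations and heights are bandwidth-dependent; cross-study
  comparisons require the same bandwidth rule.
- The permute null destroys *all* structure, including autocorrelation
  within a day; it answers "is there any animal-distance association",
  not "how much".
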