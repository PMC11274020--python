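"""Concordance and shape statistics for daily proximity ranks.

Day-to-day agreement of a herd's spatial ranking is measured with Kendall's
coefficient of concordance W, treating days as raters and animals as items:
W = 1 means the herd lines up identically every day, while under independent
random rankings E[W] = 1/m for m days.  The distribution of an animal's
daily ranks is summarised by moment skewness and (non-excess) kurtosis, the
location and height of its kernel-density peak, and the five-number summary
behind a boxplot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ConcordanceResult:
    """Kendall's W with its chi-square significance test.

    ``w`` is the ties-corrected coefficient when ``ties_corrected`` is True;
    ``w_uncorrected`` always carries the value without the tie term so both
    variants can be reported side by side.
    """

    w: float
    chi2: float
    df: int
    p: float
    m_days: int
    n_cows: int
    ties_corrected: bool
    w_uncorrected: float

    def as_dict(self) -> dict:
        return {
            "W": self.w,
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
            "m_days": self.m_days,
            "n_cows": self.n_cows,
            "ties_corrected": self.ties_corrected,
            "W_uncorrected": self.w_uncorrected,
        }


def _tie_term(row: np.ndarray) -> float:
    """Sum of t^3 - t over groups of tied values in one day's ranking."""
    _, counts = np.unique(row, return_counts=True)
    t = counts.astype(float)
    return float(np.sum(t**3 - t))


def kendalls_w(daily_rank_matrix, ties_correction: bool = True) -> ConcordanceResult:
    """Kendall's coefficient of concordance over an m-days × n-animals matrix.

    Each day's vector of daily median ranks is first converted to a proper
    within-day ranking 1..n (midranks for ties) — W is defined on rankings,
    not on the raw medians.  With R_i the rank sum of animal i over days and
    T_j the tie term of day j,

        W = 12 Σ_i (R_i − m(n+1)/2)² / (m²(n³−n) − m Σ_j T_j)

    and significance follows χ² = m(n−1)W on n−1 degrees of freedom.

    Missing cells are an error naming the offending (day, animal); the caller
    decides how to resolve gaps (see :func:`herdrank.ranking.cumulative_curve`).
    """
    if isinstance(daily_rank_matrix, pd.DataFrame):
        mat = daily_rank_matrix
    else:
        arr = np.asarray(daily_rank_matrix, dtype=float)
        mat = pd.DataFrame(arr)
    values = mat.to_numpy(dtype=float)
    if np.isnan(values).any():
        days, cows = np.nonzero(np.isnan(values))
        offenders = [
            (mat.index[d], mat.columns[c]) for d, c in zip(days[:5], cows[:5])
        ]
        raise ValueError(f"missing daily ranks at (day, animal): {offenders}")
    m, n = values.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 days and 2 animals")

    ranks = sps.rankdata(values, method="average", axis=1)
    r_sums = ranks.sum(axis=0)
    s = float(np.sum((r_sums - m * (n + 1) / 2.0) ** 2))
    denom_plain = m**2 * (n**3 - n)
    tie_sum = float(sum(_tie_term(row) for row in ranks))
    w_uncorrected = 12.0 * s / denom_plain
    denom = denom_plain - m * tie_sum
    if denom <= 0:  # every day one big tie group
        raise ValueError("degenerate rankings: all animals tied every day")
    w_corrected = 12.0 * s / denom
    w = w_corrected if ties_correction else w_uncorrected
    chi2 = m * (n - 1) * w
    p = float(sps.chi2.sf(chi2, n - 1))
    return ConcordanceResult(
        w=float(w), chi2=float(chi2), df=n - 1, p=p, m_days=m, n_cows=n,
        ties_corrected=ties_correction, w_uncorrected=float(w_uncorrected),
    )


# ---------------------------------------------------------------------------
# distribution shape
# ---------------------------------------------------------------------------

def _check_moments_input(values) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("need at least 3 values")
    if np.var(x) == 0:
        raise ValueError("zero variance: shape statistics undefined")
    return x


def moment_skewness(values, bias_corrected: bool = False) -> float:
    """Moment skewness m3 / m2^(3/2) with n-normalised central moments.

    ``bias_corrected=True`` applies the usual small-sample adjustment instead.
    Conventional reading: beyond ±0.5 the distribution is skewed, beyond ±1
    extremely skewed.
    """
    x = _check_moments_input(values)
    return float(sps.skew(x, bias=not bias_corrected))


def moment_kurtosis(values, bias_corrected: bool = False) -> float:
    """Non-excess kurtosis m4 / m2² (normal distribution = 3).

    Values above 3 indicate a peaked distribution, below 3 a flat one.
    """
    x = _check_moments_input(values)
    return float(sps.kurtosis(x, fisher=False, bias=not bias_corrected))


def silverman_bandwidth(values) -> float:
    """Rule-of-thumb bandwidth 0.9 · min(sd, IQR/1.34) · n^(−1/5).

    Falls back to sd, then |x̄|, then 1 when the minimum term degenerates to
    zero (constant-IQR samples), mirroring the classical nrd0 fallback chain.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values for a bandwidth")
    sd = float(np.std(x, ddof=1))
    iqr = float(np.percentile(x, 75) - np.percentile(x, 25))
    lo = min(sd, iqr / 1.34)
    if lo == 0.0:
        lo = sd or abs(float(np.mean(x))) or 1.0
    return 0.9 * lo * n ** (-0.2)


@dataclass
class DensityPeak:
    """Mode of a Gaussian KDE: location, height (density × 100), bandwidth."""

    peak_x: float
    peak_y_percent: float
    bandwidth: float


def density_peak(values, bandwidth: float | None = None, grid_size: int = 512,
                 cut: float = 3.0) -> DensityPeak:
    """Location and height of the KDE mode of a sample.

    A Gaussian-kernel density estimate with Silverman's rule-of-thumb
    bandwidth (overridable) is evaluated on a ``grid_size``-point grid
    spanning [min − cut·bw, max + cut·bw]; the peak is the grid argmax, with
    exact ties broken toward the lower x.  The height is reported as density
    × 100 so that a density of 0.2422 reads as 24.22 "%".
    """
    x = np.asarray(values, dtype=float).ravel()
    if np.unique(x).size < 2:
        raise ValueError("degenerate density: all values identical")
    bw = float(bandwidth) if bandwidth is not None else silverman_bandwidth(x)
    if bw <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.linspace(x.min() - cut * bw, x.max() + cut * bw, grid_size)
    z = (grid[:, None] - x[None, :]) / bw
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (x.size * bw * np.sqrt(2 * np.pi))
    k = int(np.argmax(dens))  # first occurrence = lower x on ties
    return DensityPeak(
        peak_x=float(grid[k]), peak_y_percent=float(dens[k] * 100.0), bandwidth=bw
    )


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson on midranks, tie-aware)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    return float(sps.spearmanr(x, y).statistic)


@dataclass
class BoxplotSummary:
    """Five-number summary with 1.5·IQR outliers.

    min/max are taken over all data; the fences affect only which points are
    listed as outliers.  Quartiles use linear interpolation between order
    statistics (the common type-7 rule).
    """

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    outliers: tuple

    def as_dict(self) -> dict:
        return {
            "min": self.minimum, "q1": self.q1, "median": self.median,
            "q3": self.q3, "max": self.maximum, "outliers": list(self.outliers),
        }


def boxplot_summary(values) -> BoxplotSummary:
    """Five-number summary of a sample plus points beyond the 1.5·IQR fences."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("need at least 1 value")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    out = tuple(float(v) for v in np.sort(x[(x < lo) | (x > hi)]))
    return BoxplotSummary(
        minimum=float(x.min()), q1=float(q1), median=float(med),
        q3=float(q3), maximum=float(x.max()), outliers=out,
    )


# ---------------------------------------------------------------------------
# per-animal tables over daily ranks
# ---------------------------------------------------------------------------

def density_summary(daily: pd.DataFrame, bandwidth: float | None = None,
                    grid_size: int = 512, cut: float = 3.0) -> pd.DataFrame:
    """Per-animal shape statistics of the daily-rank distribution.

    One row per animal: moment skewness, non-excess kurtosis, KDE peak
    location (rank units), peak height (density × 100) and the bandwidth
    used — the audit trail for the density-plot reading of the herd.
    """
    rows = []
    for cow, grp in daily.groupby("cow_id", sort=True):
        x = grp["median_rank"].to_numpy(dtype=float)
        pk = density_peak(x, bandwidth=bandwidth, grid_size=grid_size, cut=cut)
        rows.append(
            {
                "cow_id": cow,
                "skewness": moment_skewness(x),
                "kurtosis": moment_kurtosis(x),
                "peak_x": pk.peak_x,
                "peak_y": pk.peak_y_percent,
                "bandwidth": pk.bandwidth,
            }
        )
    return pd.DataFrame(rows)


def boxplot_table(daily: pd.DataFrame) -> pd.DataFrame:
    """Per-animal five-number summaries of daily ranks (one row per animal)."""
    rows = []
    for cow, grp in daily.groupby("cow_id", sort=True):
        s = boxplot_summary(grp["median_rank"].to_numpy(dtype=float))
        rows.append(
            {
                "cow_id": cow, "min": s.minimum, "q1": s.q1, "median": s.median,
                "q3": s.q3, "max": s.maximum, "n_outliers": len(s.outliers),
            }
        )
    return pd.DataFrame(rows)
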