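"""Nearest-neighbour proximity ranks from interval positions.

For every 15-minute interval the great-circle distance between every pair of
animals present is computed; each animal's proximity score is the median of
its distances to all herdmates (n−1 distances for n present).  Scores are
ranked ascending within the interval — rank 1 is the animal closest to the
herd — with midranks for ties.  Interval ranks are summarised per day by
their median, and daily medians are accumulated into per-animal cumulative
rank curves whose final level summarises spatial centrality over the study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: mean Earth radius, metres (IUGG mean radius R1)
EARTH_RADIUS_M = 6_371_008.8

#: metres per degree of latitude on that sphere (~111.195 km)
METRES_PER_DEG_LAT = EARTH_RADIUS_M * np.pi / 180.0

RANKING_POLICIES = ("present-only", "complete-only")


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres between WGS84-degree points.

    Accepts scalars or broadcastable arrays.  Spherical model with
    ``EARTH_RADIUS_M``; symmetric and zero iff the points coincide.
    """
    lat1, lon1, lat2, lon2 = map(np.asarray, (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any(~np.isfinite(lat)) or np.any(np.abs(lat) > 90):
            raise ValueError("latitude outside [-90, 90] or non-finite")
    for lon in (lon1, lon2):
        if np.any(~np.isfinite(lon)) or np.any(np.abs(lon) > 180):
            raise ValueError("longitude outside [-180, 180] or non-finite")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return EARTH_RADIUS_M * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def interval_distance_matrix(lats, lons) -> np.ndarray:
    """Symmetric pairwise great-circle distance matrix for one interval."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    d = haversine_m(lats[:, None], lons[:, None], lats[None, :], lons[None, :])
    d = np.asarray(d, dtype=float)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0  # enforce exact symmetry against fp noise


def median_neighbour_distances(dmat: np.ndarray) -> np.ndarray:
    """Per-animal median of the n−1 off-diagonal distances of each row."""
    d = np.asarray(dmat, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 animals in the interval")
    off = d[~np.eye(n, dtype=bool)].reshape(n, n - 1)
    return np.median(off, axis=1)


def median_neighbour_distance(dmat: np.ndarray, index: int) -> float:
    """Median distance from the animal at ``index`` to all herdmates."""
    return float(median_neighbour_distances(dmat)[index])


def rank_within_interval(medians) -> np.ndarray:
    """Ascending ranks (1 = closest to herd) with midranks for ties."""
    medians = np.asarray(medians, dtype=float)
    if medians.size < 2:
        raise ValueError("need at least 2 animals to rank")
    return rankdata(medians, method="average")


# ---------------------------------------------------------------------------
# table-level pipeline stages
# ---------------------------------------------------------------------------

def interval_median_distances(intervals: pd.DataFrame) -> pd.DataFrame:
    """Per-interval median neighbour distance for every animal present.

    ``intervals`` is the tidy output of :func:`herdrank.ingest.bin_15min`.
    Intervals with fewer than two animals are skipped (logged).  Returns
    ``day, interval_index, cow_id, median_distance_m, n_present``.
    """
    cols = ["day", "interval_index", "cow_id", "median_distance_m", "n_present"]
    if len(intervals) == 0:
        return pd.DataFrame(columns=cols)
    df = intervals.sort_values(["day", "interval_index", "cow_id"],
                               kind="mergesort").reset_index(drop=True)
    day_codes, _ = pd.factorize(df["day"], sort=False)
    key = day_codes.astype(np.int64) * 10_000 + df["interval_index"].to_numpy()
    starts = np.flatnonzero(np.r_[True, np.diff(key) != 0])
    ends = np.r_[starts[1:], len(df)]
    lats = df["lat_med"].to_numpy()
    lons = df["lon_med"].to_numpy()
    med = np.empty(len(df))
    npres = np.empty(len(df), dtype=int)
    keep = np.ones(len(df), dtype=bool)
    n_skipped = 0
    for s, e in zip(starts, ends):
        n = e - s
        if n < 2:
            keep[s:e] = False
            n_skipped += 1
            continue
        d = interval_distance_matrix(lats[s:e], lons[s:e])
        med[s:e] = median_neighbour_distances(d)
        npres[s:e] = n
    if n_skipped:
        logger.info("interval_median_distances: skipped %d interval(s) with <2 animals",
                    n_skipped)
    out = df.loc[keep, ["day", "interval_index", "cow_id"]].copy()
    out["median_distance_m"] = med[keep]
    out["n_present"] = npres[keep]
    return out.reset_index(drop=True)


def rank_distances(med: pd.DataFrame, policy: str = "present-only",
                   herd_size: int | None = None) -> pd.DataFrame:
    """Rank median neighbour distances within each interval.

    ``policy='present-only'`` ranks among whichever animals are present
    (ranks 1..n_present); ``'complete-only'`` first drops intervals in which
    any animal is missing (n_present < herd size).
    """
    if policy not in RANKING_POLICIES:
        raise ValueError(f"policy must be one of {RANKING_POLICIES}")
    out = med.copy()
    if policy == "complete-only":
        if herd_size is None:
            herd_size = out["cow_id"].nunique()
        # recount per interval rather than trusting a possibly stale column
        sizes = out.groupby(["day", "interval_index"])["cow_id"].transform("size")
        out = out[sizes == herd_size].reset_index(drop=True)
    out["rank"] = (
        out.groupby(["day", "interval_index"])["median_distance_m"]
        .rank(method="average")
    )
    return out


def interval_ranks(intervals: pd.DataFrame, policy: str = "present-only",
                   herd_size: int | None = None) -> pd.DataFrame:
    """Convenience: :func:`interval_median_distances` then :func:`rank_distances`."""
    return rank_distances(interval_median_distances(intervals), policy, herd_size)


def daily_median_rank(iranks: pd.DataFrame) -> pd.DataFrame:
    """Median of each animal's interval ranks per day.

    Returns ``cow_id, day, median_rank, n_intervals_used``; an animal absent
    for a whole day simply has no row for that day.
    """
    if len(iranks) == 0:
        return pd.DataFrame(columns=["cow_id", "day", "median_rank", "n_intervals_used"])
    out = (
        iranks.groupby(["cow_id", "day"], as_index=False, sort=True)
        .agg(median_rank=("rank", "median"), n_intervals_used=("rank", "size"))
    )
    return out


CUMULATIVE_POLICIES = ("carry-forward", "impute-herd-median")


def cumulative_curve(daily: pd.DataFrame, policy: str = "carry-forward",
                     ) -> pd.DataFrame:
    """Running sum of daily median ranks per animal over the kept days.

    If an animal has no daily rank on some kept day, ``carry-forward``
    (default) adds nothing that day — the curve stays flat — and logs a
    warning; ``impute-herd-median`` instead adds the median of the other
    animals' daily ranks for that day.  Fabricated values distort downstream
    concordance input, hence the conservative default.

    Returns ``cow_id, day, cumulative`` over the union of days, sorted.
    """
    if policy not in CUMULATIVE_POLICIES:
        raise ValueError(f"policy must be one of {CUMULATIVE_POLICIES}")
    wide = daily.pivot(index="day", columns="cow_id", values="median_rank").sort_index()
    n_gaps = int(wide.isna().to_numpy().sum())
    if n_gaps:
        logger.warning(
            "cumulative_curve: %d animal-day gap(s) handled by policy %r",
            n_gaps, policy,
        )
        if policy == "impute-herd-median":
            row_med = wide.median(axis=1)
            wide = wide.apply(lambda col: col.fillna(row_med))
        else:
            wide = wide.fillna(0.0)
    cum = wide.cumsum()
    long = cum.reset_index().melt(id_vars="day", value_name="cumulative")
    return long.sort_values(["cow_id", "day"]).reset_index(drop=True)


def final_cumulative(curves: pd.DataFrame) -> pd.Series:
    """Final level of each animal's cumulative curve, indexed by cow_id."""
    last_day = curves["day"].max()
    fin = curves[curves["day"] == last_day].set_index("cow_id")["cumulative"]
    return fin.sort_index()
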