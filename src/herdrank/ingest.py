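"""Reading virtual-fence collar message logs into interval positions.

A collar transmits three kinds of messages — routine position polls, audio
warnings near the virtual border, and electric-pulse ("zap") events — all of
which carry a GPS fix and are therefore usable as position sources.  This
module parses such logs, resolves collar serial numbers to animal identities
(an animal may wear more than one collar over the study if hardware is
replaced), bins positions into aligned 15-minute UTC intervals by taking the
coordinate-wise median of all fixes inside an interval, and drops days on
which fewer animals than required were registered at all.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: message types accepted in the ``msg_type`` column (all carry GPS fixes)
MESSAGE_TYPES = ("poll", "warning", "zap")

#: required header of a message-log CSV
MESSAGE_COLUMNS = ("serial", "timestamp", "lat", "lon", "msg_type")

INTERVAL_SECONDS = 900
INTERVALS_PER_DAY = 96

_TZ_SUFFIX = re.compile(r"(?:Z|z|[+-]\d{2}:?\d{2})\s*$")


class MessageParseError(ValueError):
    """A message log row (or the file as a whole) is malformed."""


class CollarMapError(ValueError):
    """The serial→animal mapping is inconsistent or does not cover a record."""


@dataclass
class ParsedLog:
    """Result of parsing a message log.

    Attributes
    ----------
    records : pandas.DataFrame
        Well-formed rows with columns ``serial`` (str), ``timestamp``
        (tz-aware UTC), ``lat``, ``lon`` (float degrees), ``msg_type`` (str).
    rejected : list of (int, str)
        One ``(line_number, reason)`` entry per skipped row (lenient mode
        only; line 1 is the header).
    """

    records: pd.DataFrame
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:  # number of accepted records
        return len(self.records)


def parse_message_log(source, *, strict: bool = True) -> ParsedLog:
    """Parse a collar message log CSV.

    Parameters
    ----------
    source : path or file-like
        CSV with header ``serial,timestamp,lat,lon,msg_type``; timestamps
        ISO-8601 with an explicit UTC designator (``Z`` or numeric offset).
    strict : bool
        If True (default), any malformed row raises :class:`MessageParseError`
        naming the offending line.  If False, malformed rows are skipped and
        reported in :attr:`ParsedLog.rejected` so that
        ``len(records) + len(rejected)`` equals the number of input rows.
    """
    raw = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in MESSAGE_COLUMNS if c not in raw.columns]
    if missing:
        raise MessageParseError(f"message log is missing columns: {missing}")
    raw = raw.reset_index(drop=True)
    line_no = raw.index.to_numpy() + 2  # header is line 1

    reasons = np.full(len(raw), "", dtype=object)

    def _flag(mask: np.ndarray, reason: str) -> None:
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    ts = pd.to_datetime(raw["timestamp"], utc=True, errors="coerce", format="ISO8601")
    has_tz = raw["timestamp"].str.contains(_TZ_SUFFIX, regex=True, na=False)
    _flag((ts.isna() | ~has_tz).to_numpy(), "unparseable or non-UTC-designated timestamp")

    lat = pd.to_numeric(raw["lat"], errors="coerce")
    lon = pd.to_numeric(raw["lon"], errors="coerce")
    _flag((lat.isna() | (lat < -90) | (lat > 90)).to_numpy(), "latitude outside [-90, 90]")
    _flag((lon.isna() | (lon < -180) | (lon > 180)).to_numpy(), "longitude outside [-180, 180]")
    _flag((~raw["msg_type"].isin(MESSAGE_TYPES)).to_numpy(), f"msg_type not in {MESSAGE_TYPES}")
    _flag((raw["serial"].str.strip() == "").to_numpy(), "empty serial")

    bad = reasons != ""
    if bad.any() and strict:
        detail = "; ".join(
            f"line {ln}: {rs}" for ln, rs in zip(line_no[bad][:5], reasons[bad][:5])
        )
        raise MessageParseError(
            f"{int(bad.sum())} malformed row(s), first: {detail}"
        )

    records = pd.DataFrame(
        {
            "serial": raw["serial"].astype(str),
            "timestamp": ts,
            "lat": lat.astype(float),
            "lon": lon.astype(float),
            "msg_type": raw["msg_type"].astype(str),
        }
    )[~bad].reset_index(drop=True)
    rejected = [(int(ln), str(rs)) for ln, rs in zip(line_no[bad], reasons[bad])]
    if rejected:
        logger.info("parse_message_log: skipped %d malformed row(s)", len(rejected))
    return ParsedLog(records=records, rejected=rejected)


def write_message_log(records: pd.DataFrame, path) -> None:
    """Write records in the message-log CSV dialect this module reads.

    Timestamps are serialised as ISO-8601 with a ``Z`` designator at second
    precision, so a written log round-trips through
    :func:`parse_message_log`.
    """
    out = records[["serial", "timestamp", "lat", "lon", "msg_type"]].copy()
    ts = pd.to_datetime(out["timestamp"], utc=True)
    out["timestamp"] = ts.dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False, float_format="%.8f")


# ---------------------------------------------------------------------------
# serial → animal mapping
# ---------------------------------------------------------------------------

@dataclass
class CollarMap:
    """Mapping from collar serial numbers to animal identities.

    ``entries`` holds one row per (serial, validity window):
    ``serial, cow_id, valid_from, valid_to`` with inclusive dates.  A serial
    belongs to exactly one animal; an animal may own several serials (collar
    replacement) provided their validity windows do not overlap.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.entries.copy()
        required = ("serial", "cow_id", "valid_from", "valid_to")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise CollarMapError(f"collar map is missing columns: {missing}")
        for col in ("valid_from", "valid_to"):
            if not all(isinstance(v, date) for v in df[col]):
                df[col] = pd.to_datetime(df[col]).dt.date
        df["serial"] = df["serial"].astype(str)
        df["cow_id"] = df["cow_id"].astype(str)
        if (pd.Series(df["valid_from"].values) > pd.Series(df["valid_to"].values)).any():
            raise CollarMapError("a validity window has valid_from > valid_to")
        owners = df.groupby("serial")["cow_id"].nunique()
        multi = owners[owners > 1]
        if len(multi):
            raise CollarMapError(
                f"serial(s) mapped to more than one animal: {list(multi.index)}"
            )
        for cow, grp in df.groupby("cow_id"):
            win = grp.sort_values("valid_from")
            prev_to = None
            for _, row in win.iterrows():
                if prev_to is not None and row["valid_from"] <= prev_to:
                    raise CollarMapError(
                        f"overlapping validity windows for {cow!r}"
                    )
                prev_to = row["valid_to"]
        self.entries = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, source) -> "CollarMap":
        """Read a ``serial,cow_id,valid_from,valid_to`` CSV (dates inclusive)."""
        return cls(pd.read_csv(source, dtype={"serial": str, "cow_id": str}))

    @classmethod
    def identity(cls, serials, cow_ids=None) -> "CollarMap":
        """One serial per animal, valid for all time (convenience)."""
        serials = list(serials)
        if cow_ids is None:
            cow_ids = serials
        return cls(
            pd.DataFrame(
                {
                    "serial": serials,
                    "cow_id": list(cow_ids),
                    "valid_from": date.min,
                    "valid_to": date.max,
                }
            )
        )


@dataclass
class MappedLog:
    """Records with ``cow_id`` attached plus any rows no window covered."""

    records: pd.DataFrame
    unmapped: pd.DataFrame


def apply_collar_map(records: pd.DataFrame, collar_map: CollarMap,
                     *, strict: bool = True) -> MappedLog:
    """Attach ``cow_id`` to each record via its serial and message date.

    In strict mode a record whose serial has no validity window covering its
    date raises :class:`CollarMapError` naming the serial and date; in lenient
    mode such records are returned in :attr:`MappedLog.unmapped`.
    """
    recs = records.reset_index(drop=True).copy()
    recs["_rec"] = np.arange(len(recs))
    merged = recs.merge(collar_map.entries, on="serial", how="left")
    day = merged["timestamp"].dt.date
    in_window = (
        merged["cow_id"].notna()
        & (day >= merged["valid_from"])
        & (day <= merged["valid_to"])
    )
    matched = merged[in_window]
    if matched["_rec"].duplicated().any():  # excluded by CollarMap validation
        raise CollarMapError("a record matches more than one validity window")
    unmatched_mask = ~recs["_rec"].isin(matched["_rec"])
    unmapped = recs[unmatched_mask].drop(columns="_rec").reset_index(drop=True)
    if len(unmapped) and strict:
        first = unmapped.iloc[0]
        raise CollarMapError(
            f"{len(unmapped)} record(s) outside any validity window, first: "
            f"serial {first['serial']!r} at {first['timestamp']}"
        )
    out_cols = ["cow_id", "serial", "timestamp", "lat", "lon", "msg_type"]
    out = (
        matched.sort_values("_rec")[out_cols + ["_rec"]]
        .drop(columns="_rec")
        .reset_index(drop=True)
    )
    if len(unmapped):
        logger.info("apply_collar_map: %d unmapped record(s) dropped", len(unmapped))
    return MappedLog(records=out, unmapped=unmapped)


# ---------------------------------------------------------------------------
# interval binning and day-level exclusion
# ---------------------------------------------------------------------------

def bin_15min(records: pd.DataFrame) -> pd.DataFrame:
    """Bin mapped records into aligned 15-minute UTC intervals.

    Intervals are half-open ``[t, t + 15 min)`` starting at 00:00:00 UTC, so
    ``interval_index = floor(seconds_since_midnight / 900)`` runs 0–95 and a
    fix exactly on a boundary belongs to the later interval.  Within each
    (animal, day, interval) cell the coordinate-wise median of latitude and
    longitude is taken, pooling polls, warnings and zaps alike.

    Returns a tidy frame ``cow_id, day, interval_index, lat_med, lon_med,
    n_messages``; empty input yields an empty frame with those columns.
    """
    cols = ["cow_id", "day", "interval_index", "lat_med", "lon_med", "n_messages"]
    if len(records) == 0:
        return pd.DataFrame(columns=cols)
    if "cow_id" not in records.columns:
        raise ValueError("records must carry cow_id (run apply_collar_map first)")
    ts = records["timestamp"]
    if ts.dt.tz is None:
        raise ValueError("timestamps must be timezone-aware UTC")
    ts = ts.dt.tz_convert("UTC")
    secs = (ts - ts.dt.normalize()).dt.total_seconds()
    df = pd.DataFrame(
        {
            "cow_id": records["cow_id"].to_numpy(),
            "day": ts.dt.date.to_numpy(),
            "interval_index": (secs // INTERVAL_SECONDS).astype(int).to_numpy(),
            "lat": records["lat"].to_numpy(),
            "lon": records["lon"].to_numpy(),
        }
    )
    out = (
        df.groupby(["cow_id", "day", "interval_index"], as_index=False, sort=True)
        .agg(lat_med=("lat", "median"), lon_med=("lon", "median"), n_messages=("lat", "size"))
    )
    return out[cols]


@dataclass
class DayFilterReport:
    """Which days survived the herd-registration filter and why not."""

    required_cows: int
    kept_days: list
    excluded_days: list  # dicts: {"day", "cows_registered", "reason"}

    def to_json(self, **kwargs) -> str:
        payload = {
            "required_cows": self.required_cows,
            "kept_days": [str(d) for d in self.kept_days],
            "excluded_days": [
                {**e, "day": str(e["day"])} for e in self.excluded_days
            ],
        }
        kwargs.setdefault("indent", 2)
        return json.dumps(payload, **kwargs)


def exclude_days(intervals: pd.DataFrame, required_cows: int | None = None,
                 ) -> tuple[pd.DataFrame, DayFilterReport]:
    """Drop days on which fewer than ``required_cows`` animals registered.

    A day is kept iff the number of distinct animals with at least one
    interval position that day reaches ``required_cows`` (default: the number
    of distinct animals in the whole table, i.e. full herd registration).
    """
    if len(intervals) == 0:
        return intervals.copy(), DayFilterReport(required_cows or 0, [], [])
    herd = intervals["cow_id"].nunique()
    if required_cows is None:
        required_cows = herd
    if required_cows > herd:
        raise ValueError(
            f"required_cows={required_cows} exceeds herd size {herd}"
        )
    per_day = intervals.groupby("day")["cow_id"].nunique().sort_index()
    kept = per_day.index[per_day >= required_cows]
    excluded = per_day.index[per_day < required_cows]
    report = DayFilterReport(
        required_cows=required_cows,
        kept_days=list(kept),
        excluded_days=[
            {
                "day": d,
                "cows_registered": int(per_day[d]),
                "reason": f"cows_registered < {required_cows}",
            }
            for d in excluded
        ],
    )
    filtered = intervals[intervals["day"].isin(set(kept))].reset_index(drop=True)
    if len(excluded):
        logger.info("exclude_days: removed %d day(s)", len(excluded))
    return filtered, report
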