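"""Bundled reference data.

The package ships one small table: published per-animal shape statistics of
daily spatial-rank distributions for a 17-cow virtually fenced Angus herd
(moment skewness, non-excess kurtosis, and the location and height of each
animal's rank-density peak).  The raw GPS data behind it are not public, so
the table serves as a fixed reference for cross-checks — e.g. the moderate
negative Spearman correlation between skewness and peak location — and for
worked examples.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd


def load_reference_shape_stats() -> pd.DataFrame:
    """Per-animal shape statistics of a real herd's daily ranks.

    Columns: ``cow_id``, ``skewness`` (moment convention), ``kurtosis``
    (non-excess; normal = 3), ``peak_x`` (rank units), ``peak_y``
    (density × 100).
    """
    path = files("herdrank.data").joinpath("reference_shape_stats.csv")
    with path.open("r") as fh:
        return pd.read_csv(fh)
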