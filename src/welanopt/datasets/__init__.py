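"""Bundled fermentation-record fixtures.

Twenty-five Welan gum fermentation records from the published study are
shipped verbatim, both in raw units and min-max normalized form.  The study's
full 67-record dataset was never released; the remaining records can be
emulated with :mod:`welanopt.synth`.

The per-column extrema behind the normalized table were never published
either, but several columns pin them down exactly (a raw value mapping to 0
gives ``x_min``; a second row then gives ``x_max`` by inverting the affine
map).  :func:`implied_scaling` reconstructs them that way.
"""

from importlib import resources
from pathlib import Path

import pandas as pd

from ..data_prep import ALL_COLUMNS, ScalingParams, read_table

__all__ = ["load_printed_records", "load_printed_normalized", "implied_scaling"]


def _data_path(name: str) -> Path:
    return Path(resources.files(__package__) / "data" / name)


def load_printed_records() -> pd.DataFrame:
    """The 25 published records, raw units (g/L, mL, degC, rpm, %)."""
    return read_table(_data_path("table1_raw.csv"), require_production=True)


def load_printed_normalized() -> pd.DataFrame:
    """The same 25 records as published after min-max normalization."""
    return read_table(_data_path("table2_normalized.csv"), require_production=True)


def implied_scaling() -> ScalingParams:
    """Per-column extrema recovered by two-point inversion of the printed pair.

    For each column, pick two rows with distinct normalized values y1 != y2 and
    raw values x1, x2; the affine map gives
    ``x_min = x1 - y1 * (x2 - x1) / (y2 - y1)`` and symmetrically ``x_max``.
    Columns that are constant in the printed subset (KH2PO4, MgSO4, liquid
    volume) map to 1 resp. 0 everywhere; their extrema are not identifiable
    from the printout and are filled with the raw constant +/- a degenerate
    guard of the printed normalized value, so they are excluded here.
    """
    raw = load_printed_records()
    norm = load_printed_normalized()
    x_min: dict[str, float] = {}
    x_max: dict[str, float] = {}
    for col in ALL_COLUMNS:
        y = norm[col].to_numpy(float)
        x = raw[col].to_numpy(float)
        i = int(y.argmin())
        j = int(y.argmax())
        if y[j] - y[i] < 1e-9:
            continue  # not identifiable from the printed subset
        slope = (x[j] - x[i]) / (y[j] - y[i])
        x_min[col] = float(x[i] - y[i] * slope)
        x_max[col] = float(x[i] + (1.0 - y[i]) * slope)
    return ScalingParams(x_min=x_min, x_max=x_max)
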