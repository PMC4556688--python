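"""Packaged reference tables for the nine-group corneal ectasia design.

Three summary tables ship with the package, one per readout family:

* ``cct`` — central corneal thickness (um) before and after swelling,
* ``morphometry`` — fibril diameter (nm), nearest-spot distance (nm) and
  per-window spot density,
* ``dsc`` — collagen denaturation transition temperature (C).

Each is a mean +- SD summary per experimental group; numeric columns are
parsed to floats, and the printed decimal strings are preserved in
``*_str`` columns so report cells can be reproduced character-for-character.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_cct_table",
    "load_morphometry_table",
    "load_dsc_table",
    "format_mean_sd",
]

_FILES = {
    "cct": "table1_cct.csv",
    "morphometry": "table2_morphometry.csv",
    "dsc": "table3_dsc.csv",
}


def _load(name: str) -> pd.DataFrame:
    path = resources.files("fibrilquant.data").joinpath(_FILES[name])
    with path.open("r") as fh:
        df = pd.read_csv(fh, dtype=str)
    for col in df.columns:
        if col == "group":
            continue
        df[f"{col}_str"] = df[col]
        df[col] = df[col].astype(float)
    return df


def format_mean_sd(table: pd.DataFrame, measure: str) -> pd.Series:
    """Reconstruct the ``mean±sd`` report cells of a packaged table.

    Uses the preserved printed-decimal strings so the cells come out
    character-for-character as published (e.g. ``362±12.0``, ``40.67±0.92``).
    """
    return (
        table[f"{measure}_mean_str"] + "±" + table[f"{measure}_sd_str"]
    ).set_axis(table["group"])


def load_cct_table() -> pd.DataFrame:
    """Central corneal thickness summary (um), dextran-deswollen and swelled."""
    return _load("cct")


def load_morphometry_table() -> pd.DataFrame:
    """Fibril diameter, nearest-spot distance and spot density summary."""
    return _load("morphometry")


def load_dsc_table() -> pd.DataFrame:
    """DSC transition temperature summary (C)."""
    return _load("dsc")
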