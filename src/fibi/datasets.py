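"""Bundled example tables for the Xijiang mainstem study system.

Two small published summary tables ship with the package:

* the reference metric values (%) of the eight sensitive metrics across
  the eight historical faunal groups of the Xijiang mainstem, and
* the twelve survey sites with their habitat class (NRAD = natural
  free-flowing reach between adjacent dams, TR = reservoir transition
  zone) and the length of the natural lotic reach.

The underlying species lists are not redistributable, so these tables
support worked examples and summary statistics, not a full re-analysis.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_table", "load_sites"]


def _read(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("fibi.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, **kwargs)


def load_reference_table() -> pd.DataFrame:
    """Sensitive-metric reference values (%) per faunal group.

    Rows are the eight sensitive metrics (NFM, PF, HYF, CUF, LAF, SIF,
    FLF, SPF); columns are the eight cluster groups, labelled by their
    member sites.
    """
    return _read("xijiang_reference_metrics.csv", index_col=0)


def load_sites() -> pd.DataFrame:
    """Survey sites with habitat class and natural lotic reach length (km)."""
    df = _read("xijiang_sites.csv", index_col=0)
    df["habitat_code"] = df["habitat_type"].map({"NRAD": 1, "TR": 2})
    return df
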