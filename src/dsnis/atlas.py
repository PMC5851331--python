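"""AAL-90 region lookup (index -> anatomical name) used for edge tables."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

__all__ = ["aal90_table", "aal90_names"]


@lru_cache(maxsize=1)
def aal90_table() -> pd.DataFrame:
    """The 90-region AAL lookup shipped with the package.

    Columns: ``index`` (1-based atlas index), ``abbreviation`` (with L/R
    hemisphere suffix), ``name`` (full anatomical name, no hemisphere).
    """
    with resources.files("dsnis.data").joinpath("aal90.tsv").open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def aal90_names() -> dict[int, str]:
    """Mapping of atlas index to full anatomical name."""
    df = aal90_table()
    return dict(zip(df["index"].astype(int), df["name"]))
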