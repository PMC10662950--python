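"""Cluster composition arithmetic.

A recurring summary in progenitor-subtype analyses is the percentage
breakdown of a cluster across pseudo-time states.  The ferret truncated
radial glia (tRG) cluster analysed along the developmental trajectory is
the worked example shipped here: of the 162 tRG cells placed on the tree,
15 sat in the uncommitted progenitor state, 99 in the ependymal branch and
48 in the astrogenic branch.
"""

from __future__ import annotations

from collections.abc import Mapping

import pandas as pd

__all__ = ["TRG_STATE_COUNTS", "composition_percentages"]

#: Ferret tRG cells per pseudo-time state (worked example input).
TRG_STATE_COUNTS: dict[str, int] = {
    "uncommitted": 15,
    "ependymal": 99,
    "astrogenic": 48,
}


def composition_percentages(counts: Mapping[str, int], decimals: int = 1) -> pd.Series:
    """Percentage of each state among the total, rounded to ``decimals``.

    >>> composition_percentages({"a": 1, "b": 3})
    a    25.0
    b    75.0
    dtype: float64
    """
    s = pd.Series(dict(counts), dtype=float)
    if (s < 0).any():
        raise ValueError("counts must be nonnegative")
    total = s.sum()
    if total == 0:
        raise ValueError("total count is zero")
    return (100.0 * s / total).round(decimals)
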