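"""Pearson correlations of vegetative traits, grouped by flowering habit.

Seed viability, seed weight, emergence (stand count) and canopy height behave
differently in biennial, mixed and annual populations; correlations are
therefore computed within habit groups, with pairwise-complete handling of
missing trait values and a t-based two-sided p-value for each cell.  Small
groups still compute but carry a low-n flag, since such correlations can be
driven by drift and sampling noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .varcomp import stars

DEFAULT_TRAITS = ("seed_viability", "seed_weight", "emergence", "canopy_height")


def grouped_pearson(
    table: pd.DataFrame,
    traits=DEFAULT_TRAITS,
    group_col: str = "category",
    low_n: int = 10,
) -> pd.DataFrame:
    """Per-group Pearson correlation matrix in long format.

    Returns one row per (group, trait pair) with columns group, trait_a,
    trait_b, r, p, n, stars, low_n_flag.  Cells with fewer than 3 complete
    pairs report NaN r/p.  Grouping accepts either the three-category baseline
    or the full ontology subcategories, via ``group_col``.
    """
    traits = [t for t in traits if t in table.columns]
    if len(traits) < 2:
        raise ValueError("need at least two trait columns")
    if group_col not in table.columns:
        raise ValueError(f"grouping column {group_col!r} absent")

    rows = []
    for group, grp in table.groupby(group_col, sort=True):
        for i, ta in enumerate(traits):
            for tb in traits[i + 1 :]:
                pair = grp[[ta, tb]].dropna()
                n = len(pair)
                if n >= 3 and pair[ta].nunique() > 1 and pair[tb].nunique() > 1:
                    r, p = stats.pearsonr(pair[ta], pair[tb])
                    r, p = float(r), float(p)
                else:
                    r, p = np.nan, np.nan
                rows.append(
                    {
                        "group": group,
                        "trait_a": ta,
                        "trait_b": tb,
                        "r": r,
                        "p": p,
                        "n": n,
                        "stars": stars(p) if np.isfinite(p) else "",
                        "low_n_flag": n < low_n,
                    }
                )
    return pd.DataFrame(rows)
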