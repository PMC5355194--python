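"""Assemblage-level summaries of the historical signal.

Per analysis cell: the unweighted mean, over the species present, of the
pure-historical deviance fraction and of body size, plus species richness.
A cross-cell linear regression of mean historical fraction on mean body
size summarizes whether small-bodied assemblages carry a stronger legacy
of Quaternary habitat change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


def cell_means(occ: pd.DataFrame, per_species: pd.DataFrame) -> pd.DataFrame:
    """Per-cell unweighted means of per-species values over occupants.

    ``occ`` is a species x cell 0/1 matrix; ``per_species`` has one row per
    species (indexed like ``occ``) and any number of numeric columns.
    Cells with no occupants among the listed species are NaN; richness
    counts occupants among the listed species only.
    """
    sp = per_species.index.intersection(occ.index)
    cells = occ.columns
    mat = occ.loc[sp].to_numpy(dtype=float)
    vals = per_species.loc[sp]
    richness = mat.sum(axis=0)
    out = {"richness": richness.astype(int)}
    safe = np.where(richness > 0, richness, 1.0)
    for col in vals.columns:
        v = vals[col].to_numpy(dtype=float)
        out[f"mean_{col}"] = np.where(richness > 0, (v @ mat) / safe, np.nan)
    return pd.DataFrame(out, index=cells)


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r2: float
    t: float
    p: float
    n: int


def size_history_regression(summary: pd.DataFrame) -> RegressionSummary:
    """OLS of cell-mean historical fraction on cell-mean body size.

    Expects columns ``mean_pure_historical`` and ``mean_size_cm``; NaN
    cells are dropped.  R^2 is direction-symmetric; slope/t/p refer to the
    history ~ size direction.
    """
    df = summary[["mean_size_cm", "mean_pure_historical"]].dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 defined cells")
    x = df["mean_size_cm"].to_numpy()
    y = df["mean_pure_historical"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in cell means")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return RegressionSummary(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        t=float(res.tvalues[1]),
        p=float(res.pvalues[1]),
        n=len(df),
    )
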