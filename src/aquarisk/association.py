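"""Multivariate source-grouping support: rank correlations and rotated PCA.

Metals that co-vary across sites plausibly share a source; the two tools
here quantify that.  ``correlation_matrix`` builds a Spearman rank
correlation matrix (robust to the skewed, occasionally outlying
distributions typical of trace metals).  ``pca_rotated`` extracts
principal components from the correlation matrix of standardized
variables and optionally applies a varimax rotation so each component
loads on a compact variable group; explained variance is recomputed after
rotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = ["LoadingsTable", "correlation_matrix", "pca_rotated"]


@dataclass(frozen=True)
class LoadingsTable:
    """Variable x component loadings with explained-variance shares."""

    loadings: pd.DataFrame
    explained_pct: np.ndarray
    cumulative_pct: float
    rotation: str

    def __post_init__(self) -> None:
        if self.cumulative_pct > 100.0 + 1e-9:
            raise ValueError("cumulative explained variance cannot exceed 100%")


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Spearman correlation matrix with unit diagonal.

    Ties get average ranks.  A constant column yields NaN off-diagonals
    (its rank correlation is undefined) but keeps 1.0 on the diagonal.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 complete rows")
    cols = list(table.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        xa = table[a].to_numpy(dtype=float)
        for b in cols[i + 1 :]:
            xb = table[b].to_numpy(dtype=float)
            if np.unique(xa).size < 2 or np.unique(xb).size < 2:
                rho = np.nan
            else:
                rho = float(stats.spearmanr(xa, xb).statistic)
            out.loc[a, b] = out.loc[b, a] = rho
    return out


def pca_rotated(
    table: pd.DataFrame, n_components: int = 2, rotation: str = "varimax"
) -> LoadingsTable:
    """Principal components of the correlation matrix, optionally rotated.

    Variables are standardized (the decomposition acts on their Pearson
    correlation matrix); loadings are eigenvector * sqrt(eigenvalue).
    ``rotation`` is "varimax" or "none".  Per-component explained variance
    is the column sum of squared (rotated) loadings over the number of
    variables.  Sign convention: the largest-magnitude loading in each
    component is positive.
    """
    cols = list(table.columns)
    p = len(cols)
    if not (1 <= n_components <= p):
        raise ValueError("n_components must be in 1..n_variables")
    if len(table) < p:
        warnings.warn(
            f"only {len(table)} rows for {p} variables; loadings will be unstable",
            stacklevel=2,
        )
    x = table.to_numpy(dtype=float)
    if np.any(x.std(axis=0) == 0):
        raise ValueError("constant column makes the correlation matrix singular")
    corr = np.corrcoef(x, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    load = eigvec[:, :n_components] * np.sqrt(eigval[:n_components])
    if rotation == "varimax" and n_components > 1:
        load, _ = rotate_factors(load, "varimax")
    elif rotation not in ("varimax", "none"):
        raise ValueError(f"unknown rotation {rotation!r}")
    # deterministic sign: dominant loading of each component positive
    flip = np.sign(load[np.argmax(np.abs(load), axis=0), np.arange(load.shape[1])])
    flip[flip == 0] = 1.0
    load = load * flip
    explained = 100.0 * (load**2).sum(axis=0) / p
    order2 = np.argsort(explained)[::-1]
    load, explained = load[:, order2], explained[order2]
    name = rotation if n_components > 1 else "none"
    return LoadingsTable(
        loadings=pd.DataFrame(
            load, index=cols, columns=[f"PC{i + 1}" for i in range(load.shape[1])]
        ),
        explained_pct=explained,
        cumulative_pct=float(explained.sum()),
        rotation=name,
    )
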