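"""Eutrophication index by the logarithmic power-function universal formula.

Each of seven indicators (DO, TP, TN, COD_Mn, BOD_5, NH3-N, NO3-N) is first
normalized to a dimensionless x_j >= 1 relative to an "extremely poor"
reference concentration C_j0, then scored as

    EI_j = 10.77 * (ln x_j) ** 1.1826,

and the composite index is the weighted sum EI = sum_j W_j * EI_j, with
equal weights W_j = 1/n by default.  Higher EI means more eutrophic; the
grade-2/3 (mesotrophic/eutrophic) boundary sits at EI = 39.42.

The normalization is a ratio-to-reference transform: for harm-oriented
indicators x_j = x_max * C_j / C_j0, for dissolved oxygen (benefit) the
ratio is inverted, and either is clamped to [1, x_max].  The reference
table, x_max and all grade boundaries other than 39.42 ship as editable,
non-authoritative YAML defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrophicConfig",
    "normalize_trophic",
    "ei_single",
    "ei_composite",
    "classify_trophic",
    "ei_correlates",
    "ei_table",
]

EI_COEF = 10.77
EI_EXP = 1.1826

TROPHIC_INDICATORS = ("DO", "TP", "TN", "COD_Mn", "BOD_5", "NH3_N", "NO3_N")


@dataclass(frozen=True)
class TrophicConfig:
    """References, weights and grade boundaries for the composite EI.

    ``references`` maps indicator -> {"c0": reference concentration,
    "orientation": "harm"|"benefit"}.  ``thresholds`` are strictly
    increasing EI grade boundaries; an EI exactly on a boundary belongs to
    the higher (more eutrophic) grade.  ``grades`` has one label more than
    ``thresholds``; grade ordinals run 1..len(grades).
    """

    references: Mapping[str, Mapping]
    weights: Mapping[str, float] | None = None
    x_max: float = 100.0
    thresholds: Sequence[float] = (21.71, 39.42, 54.53, 68.26, 80.0)
    grades: Sequence[str] = (
        "oligotrophic", "mesotrophic", "light_eutrophic",
        "middle_eutrophic", "heavy_eutrophic", "hyper_eutrophic",
    )

    def __post_init__(self) -> None:
        if self.x_max <= 1:
            raise ValueError("x_max must exceed 1")
        th = list(self.thresholds)
        if any(a >= b for a, b in zip(th[:-1], th[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if len(self.grades) != len(th) + 1:
            raise ValueError("need exactly one grade label more than thresholds")
        w = self.effective_weights()
        if any(v <= 0 for v in w.values()):
            raise ValueError("weights must be positive")
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    def effective_weights(self) -> dict[str, float]:
        if self.weights is None:
            n = len(self.references)
            return {k: 1.0 / n for k in self.references}
        return dict(self.weights)


def normalize_trophic(c: float, c0: float, orientation: str = "harm", x_max: float = 100.0) -> float:
    """Dimensionless x_j in [1, x_max] for a measured concentration.

    The reference c0 is the "extremely poor" anchor: a reading at c0 maps to
    x_max.  Harm-oriented indicators scale proportionally to c; dissolved
    oxygen inverts the ratio (low DO is poor).  Readings cleaner than
    c0/x_max (or, for DO, better than x_max*c0) clamp to 1.
    """
    if c <= 0 or c0 <= 0:
        raise ValueError("concentration and reference must be positive")
    if orientation == "harm":
        x = x_max * c / c0
    elif orientation == "benefit":
        x = x_max * c0 / c
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return float(min(max(x, 1.0), x_max))


def ei_single(x: float) -> float:
    """Single-indicator score EI_j = 10.77 * (ln x)^1.1826 for x >= 1."""
    if x < 1.0:
        raise ValueError("x must be >= 1 (ln x must be non-negative)")
    return EI_COEF * math.log(x) ** EI_EXP


def ei_composite(values: Mapping[str, float], config: TrophicConfig) -> float:
    """Weighted composite EI over the configured indicators."""
    weights = config.effective_weights()
    ei = 0.0
    for name, w in weights.items():
        if name not in values or values[name] is None:
            raise ValueError(f"missing indicator {name!r}")
        ref = config.references[name]
        x = normalize_trophic(
            float(values[name]), ref["c0"], ref.get("orientation", "harm"), config.x_max
        )
        ei += w * ei_single(x)
    return ei


def classify_trophic(ei: float, config: TrophicConfig) -> tuple[int, str]:
    """(ordinal, label) of the grade containing EI; a boundary value goes to
    the higher grade."""
    if ei < 0:
        raise ValueError("EI must be non-negative")
    idx = int(np.searchsorted(np.asarray(config.thresholds, dtype=float), ei, side="right"))
    # searchsorted(side="right") puts a value equal to a boundary above it
    return idx + 1, config.grades[idx]


def ei_table(measurements: pd.DataFrame, config: TrophicConfig) -> pd.DataFrame:
    """Per-site EI and grade, aggregating seasons by arithmetic mean of the
    indicator concentrations before scoring."""
    cols = list(config.references)
    per_site = measurements.groupby("site_id", sort=True)[cols].mean()
    rows = []
    for site_id, rec in per_site.iterrows():
        ei = ei_composite(rec.to_dict(), config)
        ordinal, label = classify_trophic(ei, config)
        rows.append({"site_id": site_id, "EI": ei, "grade": ordinal, "grade_label": label})
    return pd.DataFrame(rows)


def ei_correlates(ei: pd.Series, parameters: pd.DataFrame) -> pd.Series:
    """Spearman rank correlation of EI with each parameter column.

    Average ranks on ties; a constant series yields NaN.  Requires at least
    three paired observations.
    """
    if len(ei) < 3:
        raise ValueError("need at least 3 paired observations")
    out = {}
    y = np.asarray(ei, dtype=float)
    for col in parameters.columns:
        x = parameters[col].to_numpy(dtype=float)
        if np.unique(x).size < 2 or np.unique(y).size < 2:
            out[col] = np.nan
            continue
        out[col] = float(stats.spearmanr(y, x).statistic)
    return pd.Series(out, name="spearman_rho")
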