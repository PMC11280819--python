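"""Weighted water-quality index (WQI).

WQI = k * sum_i(C_i * P_i) / sum_i(P_i) over eight parameters (pH, DO,
COD_Mn, BOD_5, NH3-N, TP, TN, NO3-N), where C_i is the parameter's
normalized 0-100 score, P_i its integer weight in 1-4, and k a subjective
constant in {1.00, 0.75, 0.50, 0.25} expressing the analyst's prior
pollution judgement (1.00 = no significant pollution; the default).

Normalization curves are piecewise-linear score tables over concentration
breakpoints; they are shipped as editable YAML defaults and are
non-authoritative conventions, not measured constants.  Scores decrease
with concentration for pollutants, increase for dissolved oxygen, and are
two-sided (peaked) for pH.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WQIConfig",
    "StandardLimits",
    "normalize_parameter",
    "compute_wqi",
    "classify_wqi",
    "exceedance_summary",
    "wqi_table",
]

WQI_PARAMETERS = ("pH", "DO", "COD_Mn", "BOD_5", "NH3_N", "TP", "TN", "NO3_N")

ALLOWED_K = (1.00, 0.75, 0.50, 0.25)


@dataclass(frozen=True)
class WQIConfig:
    """Weights, normalization curves and classification scheme.

    ``curves`` maps parameter -> list of [breakpoint, score] nodes with
    strictly increasing breakpoints and scores in [0, 100]; scores are
    linearly interpolated between nodes and clamped to the end scores
    outside them.  ``scheme`` maps class label -> lower WQI bound, in
    descending bound order; a WQI exactly on a bound belongs to the better
    class.
    """

    k: float = 1.0
    weights: Mapping[str, int] = field(default_factory=dict)
    curves: Mapping[str, Sequence[Sequence[float]]] = field(default_factory=dict)
    scheme: Sequence[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.25 <= self.k <= 1.0):
            raise ValueError("k must lie in [0.25, 1.0]")
        for p, w in self.weights.items():
            if not (1 <= w <= 4):
                raise ValueError(f"weight for {p!r} must be in 1..4, got {w}")
        for p, nodes in self.curves.items():
            xs = [n[0] for n in nodes]
            ys = [n[1] for n in nodes]
            if any(b <= a for a, b in zip(xs, xs[1:])):
                raise ValueError(f"breakpoints for {p!r} must be strictly increasing")
            if any(not (0 <= y <= 100) for y in ys):
                raise ValueError(f"scores for {p!r} must lie in [0, 100]")
        bounds = [b for _, b in self.scheme]
        if any(b >= a for b, a in zip(bounds[1:], bounds[:-1])):
            raise ValueError("scheme bounds must be strictly decreasing")


@dataclass(frozen=True)
class StandardLimits:
    """Per-parameter surface-water standard limits.

    ``limits`` maps parameter -> {"value": limit, "kind": "max"|"min"} or,
    for two-sided parameters such as pH, {"low": .., "high": ..,
    "kind": "range"}.
    """

    limits: Mapping[str, Mapping]

    def exceeds(self, parameter: str, values: np.ndarray) -> np.ndarray:
        lim = self.limits[parameter]
        kind = lim.get("kind", "max")
        if kind == "max":
            return values > lim["value"]
        if kind == "min":
            return values < lim["value"]
        if kind == "range":
            return (values < lim["low"]) | (values > lim["high"])
        raise ValueError(f"unknown limit kind {kind!r}")


def normalize_parameter(value: float, table: Sequence[Sequence[float]]) -> float:
    """Normalized 0-100 score for one raw reading, by piecewise-linear
    interpolation over the [breakpoint, score] nodes; values outside the
    table clamp to the terminal scores."""
    if value < 0:
        raise ValueError(f"negative concentration {value!r}")
    xs = np.asarray([n[0] for n in table], dtype=float)
    ys = np.asarray([n[1] for n in table], dtype=float)
    return float(np.interp(value, xs, ys))


def compute_wqi(record: Mapping[str, float], config: WQIConfig) -> float:
    """Weighted index for one site/season record.

    The parameter set is whatever the config weights name — the default
    configuration carries the standard eight.  Every weighted parameter
    must be present in the record and have a normalization curve.
    """
    num = 0.0
    den = 0.0
    for p in config.weights:
        if p not in record or record[p] is None or (
            isinstance(record[p], float) and np.isnan(record[p])
        ):
            raise ValueError(f"missing WQI parameter {p!r}")
        if p not in config.weights or p not in config.curves:
            raise ValueError(f"config lacks weight or curve for {p!r}")
        c = normalize_parameter(float(record[p]), config.curves[p])
        w = config.weights[p]
        num += c * w
        den += w
    return config.k * num / den


def classify_wqi(wqi: float, scheme: Sequence[tuple[str, float]]) -> str:
    """Label of the first class whose lower bound the WQI reaches; a value
    exactly on a bound gets the better class."""
    if not (0.0 <= wqi <= 100.0):
        raise ValueError(f"WQI {wqi!r} outside [0, 100]")
    for label, bound in scheme:
        if wqi >= bound:
            return label
    return scheme[-1][0]


def exceedance_summary(measurements: pd.DataFrame, limits: StandardLimits) -> pd.DataFrame:
    """Per-parameter exceedance rate (%), mean, sample SD and CV.

    CV = SD/mean; reported as NaN when the mean is zero.  Only parameters
    present in both the table and the limits are summarized.
    """
    rows = []
    for p, _ in limits.limits.items():
        if p not in measurements.columns:
            continue
        v = measurements[p].dropna().to_numpy(dtype=float)
        if v.size == 0:
            raise ValueError(f"no records for parameter {p!r}")
        rate = 100.0 * float(limits.exceeds(p, v).mean())
        mean = float(v.mean())
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        cv = sd / mean if mean != 0.0 else np.nan
        rows.append(
            {"parameter": p, "exceedance_pct": rate, "mean": mean, "sd": sd, "cv": cv}
        )
    return pd.DataFrame(rows).set_index("parameter")


def wqi_table(measurements: pd.DataFrame, config: WQIConfig) -> pd.DataFrame:
    """WQI and class for every site/season row of a measurement table."""
    out = measurements[["site_id", "season"]].copy()
    vals = [
        compute_wqi(rec, config)
        for rec in measurements[list(WQI_PARAMETERS)].to_dict("records")
    ]
    out["WQI"] = vals
    out["wqi_class"] = [classify_wqi(v, config.scheme) for v in vals]
    return out
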