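"""Oral-ingestion health risk for trace metals, deterministic and Monte Carlo.

The exposure metric is the average daily dose

    ADD = C * IR * EF * ED / (BW * AT)      [mg/(kg·d)]

with C the metal concentration in water (mg/L), IR daily water intake
(L/d), EF exposure frequency (d/a), ED exposure duration (a), BW body
weight (kg) and AT averaging time (d).  Carcinogenic risk is CR = ADD * SF
(SF the oral slope factor); the noncarcinogenic hazard quotient is
HQ = ADD / RfD (RfD the oral reference dose).  CR below 1e-6 is regarded
as low, between 1e-6 and 1e-4 as a potential risk, above 1e-4 as high;
HQ above 1 flags noncarcinogenic concern.

Monte Carlo propagation draws every input independently from configurable
distributions (point, normal, lognormal, triangular, uniform, with
optional truncation) for two receptor populations (adults, children) and
reports summary statistics, percentiles and threshold-exceedance
fractions.  Random substreams are keyed by the content of the
specification (metal, concentration spec, exposure spec), so identical
specifications reproduce identical draws regardless of which population
carries them.

AT is by default *derived*: ED*365 for noncarcinogenic doses and a fixed
lifetime (70 a) for carcinogenic ones, the standard convention; a
distribution for AT may be supplied instead.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DistributionSpec",
    "ExposureModel",
    "ToxicityRef",
    "add_dose",
    "carcinogenic_risk",
    "noncarcinogenic_hq",
    "classify_cr",
    "classify_hq",
    "fit_concentration",
    "monte_carlo_risk",
    "risk_ranking",
]

CR_LOW = 1e-6
CR_HIGH = 1e-4

EXPOSURE_FACTORS = ("IR", "EF", "ED", "BW")

PERCENTILES = (5, 25, 50, 75, 95)


@dataclass(frozen=True)
class DistributionSpec:
    """One input distribution: family + parameters + optional truncation.

    families and parameters:
      point      {"value"}
      normal     {"mean", "sd"}
      lognormal  {"mu", "sigma"}   (log-scale mean and sd)
      triangular {"left", "mode", "right"}
      uniform    {"low", "high"}

    Truncation bounds are applied by rejection; all sampled values must be
    strictly positive after truncation.
    """

    family: str
    params: Mapping[str, float]
    truncate: tuple[float | None, float | None] = (None, None)

    def __post_init__(self) -> None:
        needed = {
            "point": {"value"},
            "normal": {"mean", "sd"},
            "lognormal": {"mu", "sigma"},
            "triangular": {"left", "mode", "right"},
            "uniform": {"low", "high"},
        }
        if self.family not in needed:
            raise ValueError(f"unknown distribution family {self.family!r}")
        missing = needed[self.family] - set(self.params)
        if missing:
            raise ValueError(f"{self.family} spec missing parameters {sorted(missing)}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.params
        if self.family == "point":
            out = np.full(n, float(p["value"]))
        else:
            out = self._draw(n, rng)
            lo, hi = self.truncate
            for _ in range(1000):
                bad = np.zeros(n, dtype=bool)
                if lo is not None:
                    bad |= out < lo
                if hi is not None:
                    bad |= out > hi
                bad |= out <= 0.0
                if not bad.any():
                    break
                out[bad] = self._draw(int(bad.sum()), rng)
            else:
                raise ValueError("truncation bounds reject essentially all mass")
        if (out <= 0).any():
            raise ValueError("distribution produced non-positive values; truncate it")
        return out

    def _draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.params
        if self.family == "normal":
            return rng.normal(p["mean"], p["sd"], n)
        if self.family == "lognormal":
            return np.exp(rng.normal(p["mu"], p["sigma"], n))
        if self.family == "triangular":
            return rng.triangular(p["left"], p["mode"], p["right"], n)
        if self.family == "uniform":
            return rng.uniform(p["low"], p["high"], n)
        raise AssertionError(self.family)

    def mean(self) -> float:
        """Analytic mean (ignores truncation; exact for untruncated specs)."""
        p = self.params
        if self.family == "point":
            return float(p["value"])
        if self.family == "normal":
            return float(p["mean"])
        if self.family == "lognormal":
            return float(np.exp(p["mu"] + p["sigma"] ** 2 / 2.0))
        if self.family == "triangular":
            return float((p["left"] + p["mode"] + p["right"]) / 3.0)
        return float((p["low"] + p["high"]) / 2.0)


@dataclass(frozen=True)
class ExposureModel:
    """Per-population exposure-factor distributions.

    ``populations`` maps population name -> {factor -> DistributionSpec}
    for IR, EF, ED, BW and optionally AT.  ``at_mode``: "derived" computes
    AT as ED*365 (noncarcinogenic) and lifetime_years*365 (carcinogenic);
    "spec" samples the provided AT distribution for both.
    """

    populations: Mapping[str, Mapping[str, DistributionSpec]]
    at_mode: str = "derived"
    lifetime_years: float = 70.0

    def __post_init__(self) -> None:
        if self.at_mode not in ("derived", "spec"):
            raise ValueError("at_mode must be 'derived' or 'spec'")
        for pop, specs in self.populations.items():
            missing = set(EXPOSURE_FACTORS) - set(specs)
            if missing:
                raise ValueError(f"population {pop!r} missing factor(s) {sorted(missing)}")
            if self.at_mode == "spec" and "AT" not in specs:
                raise ValueError(f"population {pop!r} needs an AT spec in at_mode='spec'")


@dataclass(frozen=True)
class ToxicityRef:
    """Oral slope factors (carcinogens) and reference doses per metal.

    ``sf`` in (mg/(kg·d))^-1, defined only for metals treated as
    carcinogenic by this route; ``rfd`` in mg/(kg·d), positive.
    """

    sf: Mapping[str, float]
    rfd: Mapping[str, float]

    def __post_init__(self) -> None:
        for m, v in self.rfd.items():
            if v <= 0:
                raise ValueError(f"RfD for {m!r} must be positive")
        for m, v in self.sf.items():
            if v < 0:
                raise ValueError(f"SF for {m!r} must be non-negative")


def add_dose(c, ir, ef, ed, bw, at):
    """Average daily dose ADD = C*IR*EF*ED/(BW*AT); vectorized."""
    bw = np.asarray(bw, dtype=float)
    at = np.asarray(at, dtype=float)
    if (bw <= 0).any() if bw.ndim else bw <= 0:
        raise ValueError("BW must be positive")
    if (at <= 0).any() if at.ndim else at <= 0:
        raise ValueError("AT must be positive")
    return np.asarray(c, dtype=float) * np.asarray(ir, dtype=float) * np.asarray(
        ef, dtype=float
    ) * np.asarray(ed, dtype=float) / (bw * at)


def carcinogenic_risk(add, sf):
    """CR = ADD * SF."""
    if np.any(np.asarray(sf, dtype=float) < 0):
        raise ValueError("SF must be non-negative")
    return np.asarray(add, dtype=float) * np.asarray(sf, dtype=float)


def noncarcinogenic_hq(add, rfd):
    """HQ = ADD / RfD."""
    if np.any(np.asarray(rfd, dtype=float) <= 0):
        raise ValueError("RfD must be positive")
    return np.asarray(add, dtype=float) / np.asarray(rfd, dtype=float)


def classify_cr(cr: float) -> str:
    """Risk band for a carcinogenic risk value."""
    if cr < 0:
        raise ValueError("CR must be non-negative")
    if cr < CR_LOW:
        return "low"
    if cr <= CR_HIGH:
        return "potential"
    return "high"


def classify_hq(hq: float) -> str:
    """Band for a hazard quotient: acceptable up to and including 1."""
    if hq < 0:
        raise ValueError("HQ must be non-negative")
    return "acceptable" if hq <= 1.0 else "high"


def fit_concentration(values, family: str = "lognormal") -> DistributionSpec:
    """Fit a sampling distribution to observed concentrations of one metal.

    Default is the maximum-likelihood lognormal (log-scale mean and
    population-SD of the logs); ``family="point"`` collapses to a point
    mass at the arithmetic mean.  A constant series always yields a point
    mass.  Requires at least three strictly positive observations.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 3:
        raise ValueError("need at least 3 observations")
    if (v <= 0).any():
        raise ValueError("concentrations must be strictly positive")
    if np.unique(v).size == 1 or family == "point":
        return DistributionSpec("point", {"value": float(v.mean())})
    if family != "lognormal":
        raise ValueError(f"unsupported family {family!r}")
    logs = np.log(v)
    return DistributionSpec(
        "lognormal", {"mu": float(logs.mean()), "sigma": float(logs.std(ddof=0))}
    )


def _spec_key(*parts) -> int:
    """Stable 32-bit key from spec content (not object identity)."""
    blob = json.dumps(parts, sort_keys=True, default=str).encode()
    return zlib.crc32(blob)


def _spec_dict(spec: DistributionSpec) -> dict:
    return {"family": spec.family, "params": dict(spec.params), "truncate": list(spec.truncate)}


def monte_carlo_risk(
    conc_specs: Mapping[str, DistributionSpec],
    exposure: ExposureModel,
    toxicity: ToxicityRef,
    n_iter: int = 10_000,
    seed: int = 0,
    keep_draws: bool = False,
):
    """Monte Carlo CR/HQ for every metal x population.

    Returns ``(summary, draws)``: ``summary`` is a DataFrame indexed by
    (metal, population) with mean, standard error, percentiles and
    exceedance fractions of CR (where an SF exists) and HQ; ``draws`` maps
    (metal, population) -> {"CR": array|None, "HQ": array} when
    ``keep_draws`` is true, else is empty.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rows = []
    draws: dict = {}
    for metal in sorted(conc_specs):
        cspec = conc_specs[metal]
        for pop in sorted(exposure.populations):
            especs = exposure.populations[pop]
            key = _spec_key(
                metal,
                _spec_dict(cspec),
                {f: _spec_dict(s) for f, s in especs.items()},
                exposure.at_mode,
                exposure.lifetime_years,
            )
            rng = np.random.default_rng(np.random.SeedSequence([seed, key]))
            c = cspec.sample(n_iter, rng)
            ir = especs["IR"].sample(n_iter, rng)
            ef = especs["EF"].sample(n_iter, rng)
            ed = especs["ED"].sample(n_iter, rng)
            bw = especs["BW"].sample(n_iter, rng)
            if exposure.at_mode == "derived":
                at_nc = ed * 365.0
                at_ca = np.full(n_iter, exposure.lifetime_years * 365.0)
            else:
                at = especs["AT"].sample(n_iter, rng)
                at_nc = at_ca = at
            hq = noncarcinogenic_hq(add_dose(c, ir, ef, ed, bw, at_nc), toxicity.rfd[metal])
            cr = None
            if metal in toxicity.sf:
                cr = carcinogenic_risk(add_dose(c, ir, ef, ed, bw, at_ca), toxicity.sf[metal])
            row = {"metal": metal, "population": pop, "n_iter": n_iter}
            for name, arr in (("CR", cr), ("HQ", hq)):
                if arr is None:
                    continue
                row[f"{name}_mean"] = float(arr.mean())
                # a degenerate (all point-mass) chain must report exactly 0
                if n_iter == 1 or arr.max() == arr.min():
                    row[f"{name}_se"] = 0.0
                else:
                    row[f"{name}_se"] = float(arr.std(ddof=1) / np.sqrt(n_iter))
                for pct in PERCENTILES:
                    row[f"{name}_p{pct}"] = float(np.percentile(arr, pct))
            if cr is not None:
                row["P_CR_gt_1e6"] = float((cr > CR_LOW).mean())
                row["P_CR_gt_1e4"] = float((cr > CR_HIGH).mean())
            row["P_HQ_gt_1"] = float((hq > 1.0).mean())
            rows.append(row)
            if keep_draws:
                draws[(metal, pop)] = {"CR": cr, "HQ": hq}
    summary = pd.DataFrame(rows).set_index(["metal", "population"])
    return summary, draws


def cumulative_frequency(values: np.ndarray, n_points: int = 200) -> pd.DataFrame:
    """Empirical cumulative frequency curve of a draw vector."""
    v = np.sort(np.asarray(values, dtype=float))
    idx = np.unique(np.linspace(0, v.size - 1, min(n_points, v.size)).astype(int))
    return pd.DataFrame(
        {"value": v[idx], "cum_freq": (idx + 1) / v.size}
    )


def risk_ranking(summary: pd.DataFrame) -> dict[str, list[str]]:
    """Metals ordered by descending population-mean CR and HQ.

    Means are averaged over populations; ties break alphabetically.  Metals
    with no carcinogenic slope factor are absent from the CR ranking.
    """
    out = {}
    for col, name in (("CR_mean", "CR"), ("HQ_mean", "HQ")):
        if col not in summary.columns:
            continue
        means = summary[col].groupby(level="metal").mean().dropna()
        out[name] = sorted(means.index, key=lambda m: (-means[m], m))
    return out


def lognormal_cr_tail(
    conc_spec: DistributionSpec,
    especs: Mapping[str, DistributionSpec],
    sf: float,
    threshold: float,
    lifetime_years: float = 70.0,
) -> float:
    """Closed-form P(CR > threshold) when C is lognormal and every exposure
    factor is a point mass (AT derived as lifetime): CR = K*C with constant
    K, so the tail is a lognormal survival function."""
    if conc_spec.family != "lognormal":
        raise ValueError("closed form requires a lognormal concentration")
    k = (
        especs["IR"].params["value"]
        * especs["EF"].params["value"]
        * especs["ED"].params["value"]
        * sf
        / (especs["BW"].params["value"] * lifetime_years * 365.0)
    )
    mu, sigma = conc_spec.params["mu"], conc_spec.params["sigma"]
    z = (np.log(threshold / k) - mu) / sigma
    return float(stats.norm.sf(z))
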