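"""Geodetector: factor detector and interaction detector.

The factor detector measures how much of the spatial variance of a response
variable ``y`` (e.g. a metal concentration) is explained by a stratification
of the study sites,

    q = 1 - (sum_h N_h * sigma_h^2) / (N * sigma^2),

where the variances are population (divide-by-count) variances.  With that
convention q is exactly the between-strata share of the total sum of squares
(SSB/SST) and lies in [0, 1]: q = 0 when strata means are all equal, q = 1
when every stratum is internally constant.

The interaction detector compares q of the intersection of two
stratifications with the individual q values and labels the pair as
nonlinear/bivariable enhancement, independence, or univariable/nonlinear
weakening.  Because the intersection refines both partitions, under
population variances q(X1∩X2) >= max(q(X1), q(X2)) always holds up to
round-off; the weakening labels are retained for completeness and are only
reachable through the classification tolerance.

Continuous covariates must be discretized before detection; four
discretization methods are provided, including an exact dynamic-programming
Jenks natural-breaks optimizer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Stratification",
    "QResult",
    "InteractionResult",
    "discretize",
    "q_statistic",
    "interact",
    "factor_screen",
    "interaction_screen",
]

DISCRETIZE_METHODS = ("quantile", "equal_interval", "natural_breaks", "geometric")

#: Default classification tolerance for the interaction detector.
DEFAULT_TOLERANCE = 1e-9


@dataclass(frozen=True)
class Stratification:
    """Assignment of every site to one stratum.

    Parameters
    ----------
    labels : ndarray
        One stratum label per site (any hashable values).
    source : str
        ``"categorical"`` for a native categorical covariate,
        ``"discretized"`` for a binned continuous one.
    method : str or None
        Discretization method used, if any.
    edges : ndarray or None
        Upper class edges for discretized covariates (inclusive).
    """

    labels: np.ndarray
    source: str = "categorical"
    method: str | None = None
    edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels))
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-d array")

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def strata(self) -> list:
        return pd.unique(self.labels).tolist()

    @property
    def L(self) -> int:
        return len(self.strata)

    def counts(self) -> dict:
        vals, cnt = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(vals.tolist(), cnt.tolist()))


@dataclass(frozen=True)
class QResult:
    """Variance decomposition behind a single q value."""

    q: float
    n: int
    sst: float
    ssw: float
    sigma2: float
    stratum_counts: dict
    stratum_variances: dict
    n_singletons: int = 0

    @property
    def ssb(self) -> float:
        return self.sst - self.ssw


@dataclass(frozen=True)
class InteractionResult:
    """Outcome of the two-factor interaction detector."""

    q1: float
    q2: float
    q12: float
    category: str
    tolerance: float = DEFAULT_TOLERANCE


def _jenks_upper_edges(sorted_vals: np.ndarray, k: int) -> np.ndarray:
    """Exact Fisher/Jenks natural breaks by dynamic programming.

    Minimizes the total within-class sum of squared deviations over all
    partitions of the sorted values into ``k`` contiguous classes.  Returns
    the maximum value of each class (inclusive upper edges).  O(k n^2).
    """
    n = sorted_vals.size
    # prefix sums for O(1) within-segment SSD
    ps = np.concatenate(([0.0], np.cumsum(sorted_vals)))
    ps2 = np.concatenate(([0.0], np.cumsum(sorted_vals**2)))

    def ssd(i: int, j: int) -> float:
        # within-SSD of sorted_vals[i:j]
        m = j - i
        s = ps[j] - ps[i]
        return max((ps2[j] - ps2[i]) - s * s / m, 0.0)

    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                v = cost[c - 1, i] + ssd(i, j)
                if v < best:
                    best, arg = v, i
            cost[c, j] = best
            back[c, j] = arg
    # recover class boundaries
    edges = []
    j = n
    for c in range(k, 0, -1):
        i = back[c, j]
        edges.append(sorted_vals[j - 1])
        j = i
    return np.array(edges[::-1])


def discretize(values, method: str = "natural_breaks", n_classes: int = 5) -> Stratification:
    """Bin a continuous covariate into ``n_classes`` ordered strata.

    Methods: ``quantile`` (equal counts), ``equal_interval`` (equal width),
    ``natural_breaks`` (exact Jenks optimization), ``geometric`` (edges in
    geometric progression; requires strictly positive values).  Values equal
    to a class's upper edge fall in that class.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be 1-d")
    if np.isnan(x).any():
        raise ValueError("values contain NaN")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    distinct = np.unique(x)
    if distinct.size < 2:
        raise ValueError("cannot discretize a constant covariate")
    if n_classes > distinct.size:
        raise ValueError(
            f"n_classes={n_classes} exceeds the {distinct.size} distinct values"
        )
    if method == "quantile":
        uppers = np.quantile(x, np.arange(1, n_classes + 1) / n_classes)
    elif method == "equal_interval":
        uppers = np.linspace(x.min(), x.max(), n_classes + 1)[1:]
    elif method == "geometric":
        if x.min() <= 0:
            raise ValueError("geometric method requires strictly positive values")
        uppers = np.geomspace(x.min(), x.max(), n_classes + 1)[1:]
    elif method == "natural_breaks":
        uppers = _jenks_upper_edges(np.sort(x), n_classes)
    else:
        raise ValueError(f"unknown method {method!r}; choose from {DISCRETIZE_METHODS}")
    uppers = np.asarray(uppers, dtype=float)
    uppers[-1] = max(uppers[-1], x.max())
    labels = np.searchsorted(uppers[:-1], x, side="left")
    return Stratification(labels=labels, source="discretized", method=method, edges=uppers)


def q_statistic(y, strata: Stratification | Sequence) -> QResult:
    """Factor-detector q for response ``y`` under a stratification.

    Uses population variances so that q = SSB/SST exactly.  Raises if the
    total variance of ``y`` is zero (q undefined).  Singleton strata are
    legal (their within-variance is 0) but counted as a data-quality signal.
    """
    y = np.asarray(y, dtype=float)
    if not isinstance(strata, Stratification):
        strata = Stratification(labels=np.asarray(strata))
    if y.ndim != 1 or y.size != strata.n:
        raise ValueError("y and strata must be 1-d and the same length")
    if np.isnan(y).any():
        raise ValueError("y contains NaN")
    n = y.size
    sigma2 = float(np.var(y))  # population variance
    sst = n * sigma2
    if sst <= 0.0:
        raise ValueError("q undefined: zero total variance in y")
    ssw = 0.0
    counts: dict = {}
    variances: dict = {}
    singletons = 0
    codes, uniques = pd.factorize(strata.labels)
    for h in range(len(uniques)):
        yh = y[codes == h]
        vh = float(np.var(yh))
        ssw += yh.size * vh
        key = str(uniques[h])
        counts[key] = int(yh.size)
        variances[key] = vh
        if yh.size == 1:
            singletons += 1
    q = 1.0 - ssw / sst
    return QResult(
        q=float(q),
        n=n,
        sst=sst,
        ssw=float(ssw),
        sigma2=sigma2,
        stratum_counts=counts,
        stratum_variances=variances,
        n_singletons=singletons,
    )


def _intersect(a: Stratification, b: Stratification) -> Stratification:
    pairs = np.array(
        [f"{x}|{y}" for x, y in zip(a.labels.astype(str), b.labels.astype(str))]
    )
    return Stratification(labels=pairs, source="intersection")


def interact(
    y,
    strata_a: Stratification | Sequence,
    strata_b: Stratification | Sequence,
    tolerance: float = DEFAULT_TOLERANCE,
) -> InteractionResult:
    """Interaction detector for two stratifications of the same sites.

    The intersection stratification is formed from the distinct label pairs
    present; q12 is its factor-detector q.  Categories (checked in order):

    - ``independent``            |q12 - (q1 + q2)| <= tol
    - ``nonlinear_enhance``      q12 > q1 + q2
    - ``bivariable_enhance``     q12 > max(q1, q2) + tol
    - ``univariable_weaken``     q12 >= min(q1, q2) - tol
    - ``nonlinear_weaken``       otherwise
    """
    if not isinstance(strata_a, Stratification):
        strata_a = Stratification(labels=np.asarray(strata_a))
    if not isinstance(strata_b, Stratification):
        strata_b = Stratification(labels=np.asarray(strata_b))
    if strata_a.n != strata_b.n:
        raise ValueError("stratifications cover different numbers of sites")
    q1 = q_statistic(y, strata_a).q
    q2 = q_statistic(y, strata_b).q
    q12 = q_statistic(y, _intersect(strata_a, strata_b)).q
    if abs(q12 - (q1 + q2)) <= tolerance:
        cat = "independent"
    elif q12 > q1 + q2:
        cat = "nonlinear_enhance"
    elif q12 > max(q1, q2) + tolerance:
        cat = "bivariable_enhance"
    elif q12 >= min(q1, q2) - tolerance:
        cat = "univariable_weaken"
    else:
        cat = "nonlinear_weaken"
    return InteractionResult(q1=q1, q2=q2, q12=q12, category=cat, tolerance=tolerance)


def _stratify_column(col: pd.Series, method: str, n_classes: int) -> Stratification:
    """Native categorical columns pass through; numeric ones are discretized."""
    if pd.api.types.is_numeric_dtype(col) and col.nunique() > n_classes:
        return discretize(col.to_numpy(dtype=float), method=method, n_classes=n_classes)
    return Stratification(labels=col.to_numpy())


def factor_screen(
    responses: pd.DataFrame,
    factors: pd.DataFrame,
    method: str = "natural_breaks",
    n_classes: int = 5,
) -> pd.DataFrame:
    """q of every factor for every response column.

    Rows are responses, columns are factors, values are q.  Continuous
    factors are discretized with the given method/class count; categorical
    ones are used as-is.  Row order follows ``responses``; within the
    returned frame the factor columns keep their input order (sort per
    response when ranking).
    """
    if responses.shape[0] != factors.shape[0]:
        raise ValueError("responses and factors must describe the same sites")
    strats = {
        f: _stratify_column(factors[f], method, n_classes) for f in factors.columns
    }
    out = pd.DataFrame(index=responses.columns, columns=factors.columns, dtype=float)
    for r in responses.columns:
        y = responses[r].to_numpy(dtype=float)
        for f in factors.columns:
            out.loc[r, f] = q_statistic(y, strats[f]).q
    out.index.name = "response"
    return out


def interaction_screen(
    responses: pd.DataFrame,
    factors: pd.DataFrame,
    method: str = "natural_breaks",
    n_classes: int = 5,
    tolerance: float = DEFAULT_TOLERANCE,
) -> pd.DataFrame:
    """All pairwise interaction detections, long format.

    Columns: response, factor_a, factor_b, q1, q2, q12, category.  The
    result is symmetric in factor order; each unordered pair appears once.
    """
    if factors.shape[1] < 2:
        raise ValueError("need at least two factors")
    strats = {
        f: _stratify_column(factors[f], method, n_classes) for f in factors.columns
    }
    rows = []
    for r in responses.columns:
        y = responses[r].to_numpy(dtype=float)
        for fa, fb in itertools.combinations(factors.columns, 2):
            res = interact(y, strats[fa], strats[fb], tolerance=tolerance)
            rows.append(
                {
                    "response": r,
                    "factor_a": fa,
                    "factor_b": fb,
                    "q1": res.q1,
                    "q2": res.q2,
                    "q12": res.q12,
                    "category": res.category,
                }
            )
    return pd.DataFrame(rows)
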