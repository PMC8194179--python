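"""Shared statistical primitives.

Every analysis stage funnels its inference through this module: ordinary
least squares with a slope test, Pearson correlation, Benjamini–Hochberg
FDR, one-sided hypergeometric overrepresentation, and one-way ANOVA with a
Dunnett-type many-to-one adjustment.

Conventions
-----------
* p-values for slopes and correlations come from a two-sided t test with
  ``n - 2`` degrees of freedom and are reported only for ``n >= 3``
  (``NaN`` otherwise, since the test has no degrees of freedom).
* Degenerate responses are defined rather than propagated as ``NaN``:
  a constant response gives ``slope = 0`` and ``r_squared = 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections.abc import Collection, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegressionFit",
    "CorrelationResult",
    "ORAResult",
    "AnovaResult",
    "linear_fit",
    "pearson_correlation",
    "bh_fdr",
    "hypergeometric_enrichment",
    "ora",
    "anova_dunnett",
]


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least-squares fit of y on x.

    ``p_slope`` is the two-sided probability of a slope this extreme under
    the null of zero slope (t test, n - 2 df); ``NaN`` when n < 3.
    """

    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_two_tailed: float
    n: int


@dataclass(frozen=True)
class ORAResult:
    """One term of a hypergeometric overrepresentation analysis."""

    term_id: str
    hits_in_set: int
    set_size: int
    query_size: int
    universe_size: int
    fold_enrichment: float
    p_value: float
    fdr: float = float("nan")


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    #: (group index, Dunnett-adjusted p) for every non-control group
    adjusted_comparisons: list[tuple[int, float]] = field(default_factory=list)


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def linear_fit(x, y) -> RegressionFit:
    """OLS regression of ``y`` on ``x`` with a slope t test.

    Raises
    ------
    ValueError
        If the lengths differ, fewer than two points are given, or the
        predictor is constant (the slope is then unidentifiable).
    """
    xa = _as_float_array(x, "x")
    ya = _as_float_array(y, "y")
    if len(xa) != len(ya):
        raise ValueError(f"length mismatch: len(x)={len(xa)}, len(y)={len(ya)}")
    n = len(xa)
    if n < 2:
        raise ValueError("need at least 2 points")
    xm, ym = xa.mean(), ya.mean()
    sxx = float(np.sum((xa - xm) ** 2))
    if sxx == 0.0:
        raise ValueError("constant predictor: slope undefined")
    sxy = float(np.sum((xa - xm) * (ya - ym)))
    syy = float(np.sum((ya - ym) ** 2))
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_res = max(syy - slope * sxy, 0.0)
    r_squared = 0.0 if syy == 0.0 else 1.0 - ss_res / syy
    if n < 3:
        p = float("nan")
    elif ss_res == 0.0:
        # perfect fit: p -> 0 for a nonzero slope, 1 for a flat exact fit
        p = 1.0 if slope == 0.0 else 0.0
    else:
        se = np.sqrt(ss_res / (n - 2) / sxx)
        t = slope / se
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return RegressionFit(slope=slope, intercept=intercept,
                         r_squared=min(r_squared, 1.0), p_slope=p, n=n)


def pearson_correlation(x, y) -> CorrelationResult:
    """Sample Pearson r with two-tailed p from t = r sqrt(n-2)/sqrt(1-r^2)."""
    xa = _as_float_array(x, "x")
    ya = _as_float_array(y, "y")
    if len(xa) != len(ya):
        raise ValueError("length mismatch")
    n = len(xa)
    if n < 3:
        raise ValueError("need at least 3 points for a correlation p-value")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for a constant input")
    res = sps.pearsonr(xa, ya)
    return CorrelationResult(r=float(res.statistic),
                             p_two_tailed=float(res.pvalue), n=n)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(query: Collection[str],
                              annotated_set: Collection[str],
                              universe: Collection[str],
                              term_id: str = "term") -> ORAResult:
    """Upper-tail hypergeometric test of ``query`` against one gene set.

    ``p = P(X >= hits)`` for X ~ Hypergeom(universe, set, query);
    ``fold_enrichment = (hits/|query|) / (|set|/|universe|)``.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    s = set(annotated_set)
    if not q <= uni:
        raise ValueError("query contains genes outside the universe")
    if not s <= uni:
        raise ValueError("annotated set contains genes outside the universe")
    if not q:
        raise ValueError("empty query")
    hits = len(q & s)
    m, k, n = len(uni), len(s), len(q)
    p = float(sps.hypergeom.sf(hits - 1, m, k, n))
    fold = (hits / n) / (k / m) if k else float("nan")
    return ORAResult(term_id=term_id, hits_in_set=hits, set_size=k,
                     query_size=n, universe_size=m,
                     fold_enrichment=fold, p_value=min(p, 1.0))


def ora(query: Collection[str],
        gene_sets: Mapping[str, Collection[str]],
        universe: Collection[str]) -> list[ORAResult]:
    """Run hypergeometric enrichment over a collection of sets, BH-adjusted."""
    results = [hypergeometric_enrichment(query, genes, universe, term_id=term)
               for term, genes in gene_sets.items()]
    if results:
        fdrs = bh_fdr([r.p_value for r in results])
        results = [ORAResult(**{**r.__dict__, "fdr": float(f)})
                   for r, f in zip(results, fdrs)]
    return results


def anova_dunnett(groups: Sequence[Sequence[float]],
                  control_index: int = 0,
                  seed: int = 0) -> AnovaResult:
    """One-way ANOVA plus Dunnett many-to-one comparisons to a control.

    The adjustment uses the multivariate-t distribution of the Dunnett
    statistics (seeded quasi-Monte-Carlo evaluation); each adjusted p is
    clipped from below at its unadjusted pooled-t p so the many-to-one
    adjustment can never appear anti-conservative through integration noise.
    """
    arrs = [_as_float_array(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) < 2 for a in arrs):
        raise ValueError("every group needs at least 2 values")
    if not 0 <= control_index < len(arrs):
        raise IndexError("control_index out of range")

    k = len(arrs)
    n_total = sum(len(a) for a in arrs)
    df_between, df_within = k - 1, n_total - k
    f, p = sps.f_oneway(*arrs)
    if np.isnan(f):  # all groups identical, zero within- and between-variance
        f, p = 0.0, 1.0

    control = arrs[control_index]
    others = [a for i, a in enumerate(arrs) if i != control_index]
    other_idx = [i for i in range(k) if i != control_index]
    comparisons: list[tuple[int, float]] = []
    if others:
        with np.errstate(invalid="ignore"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = sps.dunnett(*others, control=control,
                                  alternative="two-sided",
                                  rng=np.random.default_rng(seed))
        stat = np.asarray(res.statistic, dtype=float)
        pvals = np.asarray(res.pvalue, dtype=float)
        # zero pooled variance with equal means: no evidence, p = 1
        stat = np.where(np.isnan(stat), 0.0, stat)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        # unadjusted two-sided p of the same pooled-variance statistic
        unadj = 2.0 * sps.t.sf(np.abs(stat), df_within)
        adj = np.maximum(pvals, unadj)
        comparisons = [(i, float(pa)) for i, pa in zip(other_idx, adj)]

    return AnovaResult(f_statistic=float(f), p_value=float(p),
                       df_between=df_between, df_within=df_within,
                       adjusted_comparisons=comparisons)
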