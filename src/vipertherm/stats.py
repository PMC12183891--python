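"""Summary statistics and inference for restriction-hour analyses.

Implements, from first principles, the three statistical operations the
pipeline needs: per-taxon percentile summaries of h_r, the Mann-Whitney
rank-sum comparison of current vs. future h_r samples (exact by enumeration
for small tie-free samples, tie-corrected normal approximation otherwise),
and the two-predictor ordinary least squares model of delta-h_r on latitude
and elevation with standard errors and t tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Sequence

import numpy as np
from scipy.special import betainc

from .restriction import RestrictionRecord

EXACT_ENUMERATION_MAX_N = 16


@dataclass(frozen=True)
class TaxonSummary:
    taxon: str
    scenario: str
    n_sites: int
    median_hr: float
    p5_hr: float
    p95_hr: float


@dataclass(frozen=True)
class RankSumResult:
    u: float  # U statistic of the first sample
    z: float  # tie-corrected normal deviate (nan for exact method)
    p: float  # two-sided
    method: str  # "exact" | "normal"


@dataclass(frozen=True)
class TermEstimate:
    beta: float
    se: float
    t: float
    p: float


@dataclass(frozen=True)
class RegressionResult:
    terms: Dict[str, TermEstimate]  # intercept, latitude, elevation
    df_resid: int
    scenario: str = ""


def summarize_taxon(records: Sequence[RestrictionRecord]) -> TaxonSummary:
    """Median and 5th/95th percentiles of h_r for one taxon and scenario.

    Percentiles interpolate linearly between order statistics.
    """
    if not records:
        raise ValueError("no records to summarize")
    taxa = {r.taxon for r in records}
    scenarios = {r.scenario for r in records}
    if len(taxa) > 1 or len(scenarios) > 1:
        raise ValueError(f"mixed taxa/scenarios in summary: {taxa}, {scenarios}")
    values = np.array([r.h_r for r in records], dtype=float)
    p5, p50, p95 = np.percentile(values, [5, 50, 95])
    return TaxonSummary(
        taxon=taxa.pop(),
        scenario=scenarios.pop(),
        n_sites=len(values),
        median_hr=float(p50),
        p5_hr=float(p5),
        p95_hr=float(p95),
    )


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled), dtype=float)
    ranks[order] = np.arange(1, len(pooled) + 1, dtype=float)
    # average ranks within tied groups
    vals, inv, counts = np.unique(pooled, return_inverse=True, return_counts=True)
    if (counts > 1).any():
        sums = np.zeros(len(vals))
        np.add.at(sums, inv, ranks)
        ranks = sums[inv] / counts[inv]
    return ranks


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Enumerate all C(n1+n2, n1) group labelings of the pooled ranks."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = np.arange(1, n + 1, dtype=float)  # tie-free: ranks are a permutation
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    extreme = 0
    total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - mu) >= dev - 1e-12:
            extreme += 1
        total += 1
    return extreme / total


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Two-sided Mann-Whitney test on two independent samples.

    Exact p by full enumeration when n1 + n2 <= 16 and no ties are present;
    otherwise a tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)

    if n1 + n2 <= EXACT_ENUMERATION_MAX_N and not has_ties:
        p = _exact_two_sided_p(x, y, u)
        return RankSumResult(u=u, z=float("nan"), p=p, method="exact")

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        # all observations identical: no evidence either way
        return RankSumResult(u=u, z=0.0, p=1.0, method="normal")
    # continuity correction toward the mean
    z = (u - mu - 0.5 * np.sign(u - mu)) / math.sqrt(var) if u != mu else 0.0
    p = min(1.0, math.erfc(abs(z) / math.sqrt(2.0)))
    return RankSumResult(u=u, z=z, p=max(p, np.finfo(float).tiny), method="normal")


def _t_sf_two_sided(t: float, df: int) -> float:
    """Two-sided p of a t statistic via the regularized incomplete beta."""
    if df <= 0:
        raise ValueError("df must be positive")
    if t == 0:
        return 1.0
    x = df / (df + t * t)
    return float(betainc(df / 2.0, 0.5, x))


def ols_two_predictor(
    delta: Sequence[float],
    lat: Sequence[float],
    elev: Sequence[float],
    scenario: str = "",
) -> RegressionResult:
    """OLS of delta-h_r on latitude (deg N) and elevation (m), with intercept.

    Closed-form least squares; standard errors from the residual variance and
    (X'X)^-1; two-sided p from the t distribution with n - 3 df.
    """
    y = np.asarray(delta, dtype=float)
    lat = np.asarray(lat, dtype=float)
    elev = np.asarray(elev, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if len(lat) != n or len(elev) != n:
        raise ValueError("predictor lengths differ from response")

    design = np.column_stack([np.ones(n), lat, elev])
    xtx = design.T @ design
    if np.linalg.matrix_rank(xtx) < 3:
        raise ValueError("collinear predictors")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (design.T @ y)
    resid = y - design @ beta
    df = n - 3
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 * np.diag(xtx_inv))

    terms: Dict[str, TermEstimate] = {}
    for name, b, s in zip(("intercept", "latitude", "elevation"), beta, se):
        if s == 0:
            t_stat = math.inf if b != 0 else 0.0
            p = 0.0 if b != 0 else 1.0
        else:
            t_stat = float(b / s)
            p = _t_sf_two_sided(t_stat, df)
        terms[name] = TermEstimate(beta=float(b), se=float(s), t=t_stat, p=p)
    return RegressionResult(terms=terms, df_resid=df, scenario=scenario)
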