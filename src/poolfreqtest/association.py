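"""Statistical tests for consistent allele-frequency differences.

Every test sees one locus as a 2 x 2 x k layout: k replicates, each holding a
2 x 2 table of treatment line (rows) by allele (columns).  Implemented tests:

* Cochran-Mantel-Haenszel (continuity corrected) with the Mantel-Haenszel
  common odds ratio, plus the Woolf chi-squared test of odds-ratio
  homogeneity and their combination into a "consistency call";
* the replicated G-test partition (pooled main effect + heterogeneity);
* binomial GLMs (logit link) under two model structures —
  (1) treatment + replicate + treatment:replicate with sequential
  likelihood-ratio tests, and (2) treatment only with a Wald test;
* the quasibinomial GLM (model structure 2, Pearson dispersion, t-tests);
* an ordinary linear model on the observed frequencies.

All routines exist in two forms: per-locus functions returning a
:class:`TestResult` (the reference API) and ``*_batch`` functions operating
on stacked ``(n_loci, k, 2)`` arrays — the same arithmetic vectorised across
loci, which is what makes genome-scale simulation studies tractable.

Sign convention: treatment effects are line 2 minus line 1 on the scale of
the 'A'-allele log-odds (GLMs) or frequency (LM).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, xlogy
from scipy.stats import chi2, norm
from scipy.stats import t as t_dist

from .simulate import LocusTable

__all__ = [
    "TestResult",
    "TEST_NAMES",
    "VETO_TESTS",
    "handle_zero_cells",
    "cmh_test",
    "woolf_test",
    "cmh_plus_woolf_call",
    "g_test",
    "fit_glm_binomial_m1",
    "fit_glm_binomial_m2",
    "fit_glm_quasibinomial",
    "fit_lm",
    "heterogeneity_veto",
    "run_tests",
    "cmh_batch",
    "woolf_batch",
    "g_test_batch",
    "glm_binomial_m1_batch",
    "glm_binomial_m2_batch",
    "glm_quasibinomial_batch",
    "lm_batch",
    "zero_cell_plus1_batch",
]

TEST_NAMES = (
    "cmh",
    "cmh_woolf",
    "gtest",
    "glm_binom_m1",
    "glm_binom_m2",
    "glm_quasi",
    "lm",
)

#: tests whose "consistent SNP" definition requires a non-significant
#: heterogeneity / interaction component in addition to a significant main effect
VETO_TESTS = frozenset({"cmh_woolf", "gtest", "glm_binom_m1"})

_IRLS_MAX_ITER = 25
_IRLS_REL_TOL = 1e-8


@dataclass
class TestResult:
    """Outcome of one statistical test on one locus."""

    test_name: str
    statistic: float
    df: int | tuple[int, int]
    p_main: float
    p_het: float | None = None
    effect: float | None = None
    dispersion: float | None = None
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# zero-cell handling
# ---------------------------------------------------------------------------

def zero_cell_plus1_batch(
    counts_a: np.ndarray, coverage: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Add 1 to every allele count of a locus if any of its 2k cells holds a zero.

    On a 2 x 2 x k allele-count layout the contingency-table rule ("add one to
    all cells if there are any empty cells") and the GLM rule ("add a count of
    one to each allele count if any zero counts are encountered") are the same
    operation: each table cell *is* an allele count, so every cell gains 1 and
    every coverage gains 2.  Loci without zeros pass through unchanged.
    """
    counts_a = np.asarray(counts_a, dtype=np.int64)
    coverage = np.asarray(coverage, dtype=np.int64)
    alt = coverage - counts_a
    has_zero = ((counts_a == 0) | (alt == 0)).any(axis=(1, 2))
    bump = has_zero.astype(np.int64)[:, None, None]
    return counts_a + bump, coverage + 2 * bump


def handle_zero_cells(
    table: LocusTable, mode: str = "all_cells_plus1"
) -> LocusTable:
    """Apply the add-one-to-every-count rule if the table holds any zero cell.

    ``mode`` may be "all_cells_plus1" (contingency-test wording) or
    "per_count_plus1" (GLM wording); both perform the identical adjustment
    (see :func:`zero_cell_plus1_batch`).
    """
    if mode not in ("all_cells_plus1", "per_count_plus1"):
        raise ValueError(f"unknown zero-cell mode {mode!r}")
    ca, cov = zero_cell_plus1_batch(table.counts_a[None], table.coverage[None])
    if np.array_equal(ca[0], table.counts_a):
        return table
    return replace(table, counts_a=ca[0], coverage=cov[0])


def _strata(counts_a: np.ndarray, coverage: np.ndarray):
    """Split (n, k, 2) stacks into the classical a, b, c, d stratum cells.

    a = 'A' count in line 1, b = 'a' count in line 1,
    c = 'A' count in line 2, d = 'a' count in line 2; all shaped (n, k).
    """
    a = counts_a[:, :, 0].astype(float)
    b = (coverage[:, :, 0] - counts_a[:, :, 0]).astype(float)
    c = counts_a[:, :, 1].astype(float)
    d = (coverage[:, :, 1] - counts_a[:, :, 1]).astype(float)
    return a, b, c, d


# ---------------------------------------------------------------------------
# CMH + Woolf
# ---------------------------------------------------------------------------

def cmh_batch(
    counts_a: np.ndarray, coverage: np.ndarray, zero_rule: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Continuity-corrected Mantel-Haenszel test on stacked tables.

    Returns ``(statistic, p_value, common_odds_ratio)`` arrays.  The statistic
    is ``(|sum(a_k) - sum(E_k)| - 0.5)^2 / sum(V_k)`` with E_k and V_k the
    conditional hypergeometric mean and variance of each stratum, referred to
    chi-squared with 1 df; the 0.5 continuity correction is skipped when the
    absolute deviation is already below 0.5 (it would otherwise overshoot
    zero).  The effect is the Mantel-Haenszel common odds ratio
    ``sum(a_k d_k / n_k) / sum(b_k c_k / n_k)``.
    """
    if zero_rule:
        counts_a, coverage = zero_cell_plus1_batch(counts_a, coverage)
    a, b, c, d = _strata(counts_a, coverage)
    n = a + b + c + d
    if np.any(n <= 1):
        raise ValueError("degenerate stratum: total count <= 1")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if np.any((r1 == 0) | (r2 == 0) | (c1 == 0) | (c2 == 0)):
        raise ValueError("degenerate stratum: empty margin")
    e = r1 * c1 / n
    v = r1 * r2 * c1 * c2 / (n * n * (n - 1.0))
    delta = np.abs(a.sum(axis=1) - e.sum(axis=1))
    # Yates continuity correction, applied only when it cannot overshoot zero
    yates = np.where(delta >= 0.5, 0.5, 0.0)
    stat = (delta - yates) ** 2 / v.sum(axis=1)
    p = chi2.sf(stat, 1)
    or_mh = (a * d / n).sum(axis=1) / (b * c / n).sum(axis=1)
    return stat, p, or_mh


def cmh_test(table: LocusTable) -> TestResult:
    """Cochran-Mantel-Haenszel test of conditional independence for one locus."""
    stat, p, or_mh = cmh_batch(table.counts_a[None], table.coverage[None])
    return TestResult(
        test_name="cmh",
        statistic=float(stat[0]),
        df=1,
        p_main=float(p[0]),
        effect=float(or_mh[0]),
    )


def woolf_batch(
    counts_a: np.ndarray, coverage: np.ndarray, zero_rule: bool = True
) -> tuple[np.ndarray, int, np.ndarray]:
    """Woolf chi-squared test of odds-ratio homogeneity across strata.

    Returns ``(statistic, df, p_value)`` with df = k - 1.  Weights are the
    classical inverse-variance weights ``w_k = (1/a + 1/b + 1/c + 1/d)^-1`` of
    the per-stratum log odds ratios.
    """
    k = counts_a.shape[1]
    if k < 2:
        raise ValueError("Woolf heterogeneity test needs at least 2 strata")
    if zero_rule:
        counts_a, coverage = zero_cell_plus1_batch(counts_a, coverage)
    a, b, c, d = _strata(counts_a, coverage)
    lor = np.log(a * d) - np.log(b * c)
    w = 1.0 / (1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    lbar = (w * lor).sum(axis=1) / w.sum(axis=1)
    stat = (w * (lor - lbar[:, None]) ** 2).sum(axis=1)
    return stat, k - 1, chi2.sf(stat, k - 1)


def woolf_test(table: LocusTable) -> TestResult:
    """Woolf test of homogeneity of odds ratios for one locus."""
    stat, df, p = woolf_batch(table.counts_a[None], table.coverage[None])
    return TestResult(
        test_name="woolf", statistic=float(stat[0]), df=df, p_main=float(p[0])
    )


def heterogeneity_veto(p_main, p_het, alpha: float = 0.05):
    """Combine a main-effect p-value with a heterogeneity check.

    Returns ``p_main`` where the heterogeneity test is non-significant
    (``p_het > alpha``) and 1.0 otherwise — an inconsistent locus can never be
    called at any threshold.  Vectorises over arrays.
    """
    p_main = np.asarray(p_main, dtype=float)
    p_het = np.asarray(p_het, dtype=float)
    out = np.where(p_het > alpha, p_main, 1.0)
    return float(out) if out.ndim == 0 else out


def cmh_plus_woolf_call(table: LocusTable, alpha: float = 0.05) -> float:
    """CMH p-value gated by a non-significant Woolf test at level ``alpha``."""
    p_main = cmh_test(table).p_main
    p_het = woolf_test(table).p_main
    return float(heterogeneity_veto(p_main, p_het, alpha))


# ---------------------------------------------------------------------------
# replicated G-test
# ---------------------------------------------------------------------------

def _g_stat_2x2(a, b, c, d):
    """G statistic of independence for stacked 2x2 tables (last axis = strata
    or a single pooled table); zero cells contribute zero via x*log(x)."""
    n = a + b + c + d
    g = np.zeros_like(a)
    for obs, row, col in (
        (a, a + b, a + c),
        (b, a + b, b + d),
        (c, c + d, a + c),
        (d, c + d, b + d),
    ):
        e = row * col / n
        g = g + 2.0 * (xlogy(obs, obs) - xlogy(obs, e))
    return g


def g_test_batch(
    counts_a: np.ndarray, coverage: np.ndarray, zero_rule: bool = True
) -> dict[str, np.ndarray]:
    """Replicated G-test partition on stacked tables.

    Per-stratum G statistics sum to the total G_T (df = k); the pooled table
    (summed over replicates) gives the main line-by-allele effect G_P
    (df = 1); the heterogeneity (line x allele x replicate interaction)
    component is G_H = G_T - G_P (df = k - 1).  Returns a dict with
    ``g_total``, ``g_pooled``, ``g_het``, ``p_main`` and ``p_het``.
    """
    k = counts_a.shape[1]
    if zero_rule:
        counts_a, coverage = zero_cell_plus1_batch(counts_a, coverage)
    a, b, c, d = _strata(counts_a, coverage)
    g_k = _g_stat_2x2(a, b, c, d)
    g_total = g_k.sum(axis=1)
    g_pooled = _g_stat_2x2(a.sum(axis=1), b.sum(axis=1), c.sum(axis=1), d.sum(axis=1))
    g_het = g_total - g_pooled
    return {
        "g_total": g_total,
        "g_pooled": g_pooled,
        "g_het": g_het,
        "p_main": chi2.sf(g_pooled, 1),
        "p_het": chi2.sf(np.maximum(g_het, 0.0), k - 1) if k > 1 else np.ones_like(g_het),
    }


def g_test(table: LocusTable) -> TestResult:
    """Replicated G-test for one locus: pooled main effect and heterogeneity."""
    res = g_test_batch(table.counts_a[None], table.coverage[None])
    return TestResult(
        test_name="gtest",
        statistic=float(res["g_pooled"][0]),
        df=(1, table.k - 1),
        p_main=float(res["p_main"][0]),
        p_het=float(res["p_het"][0]),
    )


# ---------------------------------------------------------------------------
# GLMs and the linear model
# ---------------------------------------------------------------------------

def _binom_deviance(y, n, mu, axis=-1):
    """Binomial deviance 2*sum[y log(y/mu) + (n-y) log((n-y)/(n-mu))]."""
    term = (
        xlogy(y, y)
        - xlogy(y, mu)
        + xlogy(n - y, n - y)
        - xlogy(n - y, n - mu)
    )
    return 2.0 * term.sum(axis=axis)


def _group_fit(counts_a: np.ndarray, coverage: np.ndarray):
    """Closed-form logistic fit of the treatment-only (two-group) model.

    A logit model with an intercept and a single two-level factor is saturated
    in the groups, so the MLE fits each treatment line's pooled proportion
    exactly.  Returns (coef, se, p1, p2, t1, t2) where coef is the log-odds
    difference line2 - line1 and t_g the total trials per group.
    """
    y1 = counts_a[:, :, 0].sum(axis=1).astype(float)
    y2 = counts_a[:, :, 1].sum(axis=1).astype(float)
    t1 = coverage[:, :, 0].sum(axis=1).astype(float)
    t2 = coverage[:, :, 1].sum(axis=1).astype(float)
    p1 = y1 / t1
    p2 = y2 / t2
    with np.errstate(divide="ignore"):
        coef = (np.log(p2) - np.log1p(-p2)) - (np.log(p1) - np.log1p(-p1))
        se = np.sqrt(1.0 / (t1 * p1 * (1.0 - p1)) + 1.0 / (t2 * p2 * (1.0 - p2)))
    return coef, se, p1, p2, t1, t2


def _pearson_x2(counts_a, coverage, p1, p2):
    """Pearson chi-squared of the two-group fit over the 2k cells."""
    cov = coverage.astype(float)
    mu = np.stack(
        [cov[:, :, 0] * p1[:, None], cov[:, :, 1] * p2[:, None]], axis=2
    )
    pi = np.stack(
        [np.broadcast_to(p1[:, None], cov[:, :, 0].shape),
         np.broadcast_to(p2[:, None], cov[:, :, 1].shape)],
        axis=2,
    )
    resid2 = (counts_a - mu) ** 2 / (mu * (1.0 - pi))
    return resid2.sum(axis=(1, 2))


def glm_binomial_m2_batch(
    counts_a: np.ndarray, coverage: np.ndarray, zero_rule: bool = True
) -> dict[str, np.ndarray]:
    """Binomial GLM, model structure 2 (treatment only), Wald z-test.

    Returns coefficient (log-odds difference, line 2 minus line 1), its
    binomial-theory standard error and the two-sided normal p-value.
    """
    if zero_rule:
        counts_a, coverage = zero_cell_plus1_batch(counts_a, coverage)
    coef, se, p1, p2, _, _ = _group_fit(counts_a, coverage)
    z = coef / se
    return {"coef": coef, "se": se, "p_main": 2.0 * norm.sf(np.abs(z)), "z": z}


def glm_quasibinomial_batch(
    counts_a: np.ndarray, coverage: np.ndarray, zero_rule: bool = True
) -> dict[str, np.ndarray]:
    """Quasibinomial GLM, model structure 2: Pearson dispersion and t-tests.

    Point estimates equal the binomial fit; the dispersion
    ``phi = Pearson X^2 / (2k - 2)`` scales the standard errors by sqrt(phi)
    and the treatment effect is referred to Student's t with 2k - 2 df.
    """
    k = counts_a.shape[1]
    if 2 * k - 2 < 1:
        raise ValueError("quasibinomial dispersion needs residual df (k >= 2)")
    if zero_rule:
        counts_a, coverage = zero_cell_plus1_batch(counts_a, coverage)
    coef, se, p1, p2, _, _ = _group_fit(counts_a, coverage)
    phi = _pearson_x2(counts_a, coverage, p1, p2) / (2 * k - 2)
    se_q = se * np.sqrt(phi)
    # phi = 0 (a perfectly fitted locus) gives t = +/-inf (p = 0) for a
    # non-zero coefficient and t = 0/0 = NaN when the coefficient is zero too,
    # matching the reference behaviour of a quasi-likelihood fit
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se_q
    return {
        "coef": coef,
        "se": se_q,
        "dispersion": phi,
        "p_main": 2.0 * t_dist.sf(np.abs(t), 2 * k - 2),
        "t": t,
    }


def _additive_deviance_irls(counts_a: np.ndarray, coverage: np.ndarray):
    """Residual deviance of the additive logit model treatment + replicate.

    Batched iteratively reweighted least squares with a shared design matrix:
    2k grouped-binomial observations per locus, k + 1 parameters (intercept,
    treatment, k - 1 replicate dummies).  Convergence: relative deviance
    change < 1e-8, at most 25 iterations.  Returns (deviance, converged).
    """
    n_loci, k, _ = counts_a.shape
    y = counts_a.reshape(n_loci, 2 * k).astype(float)
    n = coverage.reshape(n_loci, 2 * k).astype(float)

    # observation order matches reshape: (rep1,line1),(rep1,line2),(rep2,line1),...
    n_obs, n_par = 2 * k, k + 1
    x = np.zeros((n_obs, n_par))
    x[:, 0] = 1.0
    x[1::2, 1] = 1.0  # treatment indicator: 1 for line 2
    for r in range(1, k):
        x[2 * r, 1 + r] = 1.0
        x[2 * r + 1, 1 + r] = 1.0

    eta = np.zeros((n_loci, n_obs))
    dev = np.full(n_loci, np.inf)
    converged = np.zeros(n_loci, dtype=bool)
    for _ in range(_IRLS_MAX_ITER):
        pi = expit(eta)
        mu = n * pi
        w = np.clip(n * pi * (1.0 - pi), 1e-12, None)
        z = eta + (y - mu) / w
        a_mat = np.einsum("op,lo,oq->lpq", x, w, x)
        rhs = np.einsum("op,lo->lp", x, w * z)
        beta = np.linalg.solve(a_mat, rhs[..., None])[..., 0]
        eta = beta @ x.T
        new_dev = _binom_deviance(y, n, n * expit(eta))
        converged = np.abs(new_dev - dev) <= _IRLS_REL_TOL * (np.abs(new_dev) + 0.1)
        dev = new_dev
        if converged.all():
            break
    return dev, converged


def glm_binomial_m1_batch(
    counts_a: np.ndarray, coverage: np.ndarray, zero_rule: bool = True
) -> dict[str, np.ndarray]:
    """Binomial GLM, model structure 1, with sequential likelihood-ratio tests.

    Terms enter in formula order (treatment, replicate, treatment:replicate);
    each deviance drop is referred to chi-squared with the term's df, exactly
    as a sequential analysis-of-deviance table.  The full interaction model is
    saturated (2k parameters for 2k grouped observations), so the interaction
    drop equals the additive model's residual deviance.  ``p_main`` is the
    treatment LRT (1 df), ``p_het`` the interaction LRT (k - 1 df).
    """
    k = counts_a.shape[1]
    if k < 2:
        raise ValueError("model structure 1 needs k >= 2 replicates")
    if zero_rule:
        counts_a, coverage = zero_cell_plus1_batch(counts_a, coverage)
    y = counts_a.reshape(len(counts_a), -1).astype(float)
    n = coverage.reshape(len(coverage), -1).astype(float)

    p_hat = y.sum(axis=1) / n.sum(axis=1)
    dev_null = _binom_deviance(y, n, n * p_hat[:, None])

    coef, _, p1, p2, _, _ = _group_fit(counts_a, coverage)
    mu_treat = np.stack(
        [coverage[:, :, 0] * p1[:, None], coverage[:, :, 1] * p2[:, None]], axis=2
    ).reshape(len(y), -1)
    dev_treat = _binom_deviance(y, n, mu_treat)

    dev_add, converged = _additive_deviance_irls(counts_a, coverage)

    d_treatment = np.maximum(dev_null - dev_treat, 0.0)
    d_replicate = np.maximum(dev_treat - dev_add, 0.0)
    d_interaction = np.maximum(dev_add, 0.0)  # saturated model has deviance 0

    p_main = chi2.sf(d_treatment, 1)
    p_het = chi2.sf(d_interaction, k - 1)
    p_main = np.where(converged, p_main, np.nan)
    p_het = np.where(converged, p_het, np.nan)
    return {
        "dev_null": dev_null,
        "dev_treatment": d_treatment,
        "dev_replicate": d_replicate,
        "dev_interaction": d_interaction,
        "p_main": p_main,
        "p_het": p_het,
        "coef": coef,
        "converged": converged,
    }


def fit_glm_binomial_m1(table: LocusTable) -> TestResult:
    """Binomial GLM with treatment + replicate + interaction for one locus."""
    res = glm_binomial_m1_batch(table.counts_a[None], table.coverage[None])
    flags = () if bool(res["converged"][0]) else ("not_converged",)
    return TestResult(
        test_name="glm_binom_m1",
        statistic=float(res["dev_treatment"][0]),
        df=(1, table.k - 1),
        p_main=float(res["p_main"][0]),
        p_het=float(res["p_het"][0]),
        effect=float(res["coef"][0]),
        flags=flags,
    )


def fit_glm_binomial_m2(table: LocusTable) -> TestResult:
    """Binomial GLM with treatment only for one locus (Wald z-test)."""
    res = glm_binomial_m2_batch(table.counts_a[None], table.coverage[None])
    return TestResult(
        test_name="glm_binom_m2",
        statistic=float(res["z"][0]),
        df=1,
        p_main=float(res["p_main"][0]),
        effect=float(res["coef"][0]),
    )


def fit_glm_quasibinomial(table: LocusTable) -> TestResult:
    """Quasibinomial GLM (treatment only) for one locus: t-test with 2k-2 df."""
    res = glm_quasibinomial_batch(table.counts_a[None], table.coverage[None])
    return TestResult(
        test_name="glm_quasi",
        statistic=float(res["t"][0]),
        df=2 * table.k - 2,
        p_main=float(res["p_main"][0]),
        effect=float(res["coef"][0]),
        dispersion=float(res["dispersion"][0]),
    )


def lm_batch(counts_a: np.ndarray, coverage: np.ndarray) -> dict[str, np.ndarray]:
    """Ordinary least squares of the observed frequency on the treatment line.

    2k observations of f = C_A / CT per locus; the slope is the difference in
    mean frequency (line 2 minus line 1) and its p-value a t-test with
    2k - 2 df.  Loci with zero residual variance but a non-zero slope are
    flagged degenerate (p = NaN); identical frequencies everywhere give p = 1.
    """
    k = counts_a.shape[1]
    f = counts_a / coverage
    f1, f2 = f[:, :, 0], f[:, :, 1]
    m1, m2 = f1.mean(axis=1), f2.mean(axis=1)
    slope = m2 - m1
    rss = ((f1 - m1[:, None]) ** 2).sum(axis=1) + ((f2 - m2[:, None]) ** 2).sum(axis=1)
    dfree = 2 * k - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / dfree * 2.0 / k)
        t = slope / se
        p = 2.0 * t_dist.sf(np.abs(t), dfree)
    zero_rss = rss == 0.0
    p = np.where(zero_rss & (slope == 0.0), 1.0, p)
    degenerate = zero_rss & (slope != 0.0)
    p = np.where(degenerate, np.nan, p)
    return {"slope": slope, "se": se, "p_main": p, "degenerate": degenerate}


def fit_lm(table: LocusTable) -> TestResult:
    """Linear model of allele frequency on treatment line for one locus."""
    res = lm_batch(table.counts_a[None], table.coverage[None])
    flags = ("degenerate_zero_residual",) if bool(res["degenerate"][0]) else ()
    return TestResult(
        test_name="lm",
        statistic=float(res["slope"][0] / res["se"][0]) if res["se"][0] > 0 else 0.0,
        df=2 * table.k - 2,
        p_main=float(res["p_main"][0]),
        effect=float(res["slope"][0]),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# tidy multi-test driver
# ---------------------------------------------------------------------------

def run_tests(
    counts_a: np.ndarray,
    coverage: np.ndarray,
    tests: Sequence[str] | None = None,
    locus_ids: Iterable | None = None,
) -> pd.DataFrame:
    """Run the selected tests on stacked tables; one tidy row per locus x test.

    Columns: locus_id, test, statistic, p_main, p_het, effect, dispersion,
    flag.  The ``cmh_woolf`` row carries the CMH statistic and p_main together
    with the Woolf heterogeneity p_het; the veto is applied downstream (per
    alpha for FPR curves, at a fixed level for the ranking used by TPR).
    """
    counts_a = np.asarray(counts_a, dtype=np.int64)
    coverage = np.asarray(coverage, dtype=np.int64)
    if tests is None:
        tests = TEST_NAMES
    unknown = set(tests) - set(TEST_NAMES)
    if unknown:
        raise ValueError(f"unknown test name(s): {sorted(unknown)}")
    n = counts_a.shape[0]
    ids = np.arange(n) if locus_ids is None else np.asarray(list(locus_ids))

    frames: list[pd.DataFrame] = []

    def _frame(test, statistic, p_main, p_het=None, effect=None, dispersion=None, flag=None):
        frames.append(
            pd.DataFrame(
                {
                    "locus_id": ids,
                    "test": test,
                    "statistic": statistic,
                    "p_main": p_main,
                    "p_het": np.nan if p_het is None else p_het,
                    "effect": np.nan if effect is None else effect,
                    "dispersion": np.nan if dispersion is None else dispersion,
                    "flag": "" if flag is None else flag,
                }
            )
        )

    need_cmh = "cmh" in tests or "cmh_woolf" in tests
    if need_cmh:
        stat, p, or_mh = cmh_batch(counts_a, coverage)
    if "cmh" in tests:
        _frame("cmh", stat, p, effect=or_mh)
    if "cmh_woolf" in tests:
        wstat, _, wp = woolf_batch(counts_a, coverage)
        _frame("cmh_woolf", stat, p, p_het=wp, effect=or_mh)
    if "gtest" in tests:
        g = g_test_batch(counts_a, coverage)
        _frame("gtest", g["g_pooled"], g["p_main"], p_het=g["p_het"])
    if "glm_binom_m1" in tests:
        m1 = glm_binomial_m1_batch(counts_a, coverage)
        flag = np.where(m1["converged"], "", "not_converged")
        _frame("glm_binom_m1", m1["dev_treatment"], m1["p_main"],
               p_het=m1["p_het"], effect=m1["coef"], flag=flag)
    if "glm_binom_m2" in tests:
        m2 = glm_binomial_m2_batch(counts_a, coverage)
        _frame("glm_binom_m2", m2["z"], m2["p_main"], effect=m2["coef"])
    if "glm_quasi" in tests:
        q = glm_quasibinomial_batch(counts_a, coverage)
        _frame("glm_quasi", q["t"], q["p_main"], effect=q["coef"],
               dispersion=q["dispersion"])
    if "lm" in tests:
        lm = lm_batch(counts_a, coverage)
        flag = np.where(lm["degenerate"], "degenerate_zero_residual", "")
        _frame("lm", lm["slope"] / np.where(lm["se"] > 0, lm["se"], np.nan),
               lm["p_main"], effect=lm["slope"], flag=flag)

    out = pd.concat(frames, ignore_index=True)
    order = {name: i for i, name in enumerate(TEST_NAMES)}
    out["__o"] = out["test"].map(order)
    out = out.sort_values(["locus_id", "__o"]).drop(columns="__o").reset_index(drop=True)
    return out
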