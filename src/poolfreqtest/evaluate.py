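"""False-positive / true-positive rate machinery and multiple-testing corrections.

The false-positive rate of a test at a threshold alpha is the fraction of
*null* loci whose p-value falls at or below alpha; a calibrated test tracks
the 1-1 line over the alpha grid.  Power is summarised as the fraction of
seeded true positives recovered among the bottom 1% of the pooled p-value
distribution.  Bonferroni, Benjamini-Hochberg and Storey q-value corrections
are provided for genome-wide significance calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import VETO_TESTS, heterogeneity_veto

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "FprTprReport",
    "fpr_curve",
    "tpr_top_fraction",
    "bonferroni",
    "benjamini_hochberg",
    "storey_pi0",
    "storey_qvalues",
    "evaluate_results",
    "correction_summary",
]

#: the significance grid at which false-positive rates are evaluated
DEFAULT_ALPHA_GRID = (0.0001, 0.0005, 0.001, 0.005, 0.01, 0.05, 0.1, 0.5)


@dataclass
class FprTprReport:
    """FPR curve and top-fraction TPR for one test configuration."""

    test_name: str
    alpha_grid: tuple[float, ...]
    fpr: np.ndarray
    tpr: float
    n_null: int
    n_tp: int
    n_dropped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "test": self.test_name,
                "alpha": list(self.alpha_grid),
                "fpr": self.fpr,
                "tpr": self.tpr,
                "n_null": self.n_null,
                "n_tp": self.n_tp,
                "n_dropped": self.n_dropped,
            }
        )


def _clean_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def fpr_curve(p_null, alpha_grid=DEFAULT_ALPHA_GRID) -> np.ndarray:
    """Empirical false-positive rate at each alpha: fraction of null p <= alpha."""
    p = _clean_p(p_null)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("fpr_curve needs at least one null p-value")
    return np.array([(p <= a).mean() for a in alpha_grid])


def tpr_top_fraction(p_all, tp_flags, fraction: float = 0.01) -> float:
    """Fraction of true positives recovered among the bottom ``fraction`` of p-values.

    The threshold is the p-value of the floor(fraction * n)-th smallest test
    over the *pooled* (null + true positive) distribution; ties at the
    threshold are all included.  Loci with missing p-values are dropped from
    both the ranking and the true-positive denominator.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    p = _clean_p(p_all)
    flags = np.asarray(tp_flags, dtype=bool)
    if p.shape != flags.shape:
        raise ValueError("p_all and tp_flags must have the same length")
    keep = ~np.isnan(p)
    p, flags = p[keep], flags[keep]
    n_tp = int(flags.sum())
    if n_tp == 0:
        raise ValueError("no true positives among the supplied loci")
    m = int(np.floor(fraction * p.size))
    if m == 0:
        return 0.0
    threshold = np.partition(p, m - 1)[m - 1]
    return float((flags & (p <= threshold)).sum() / n_tp)


# ---------------------------------------------------------------------------
# multiple-testing corrections
# ---------------------------------------------------------------------------

def bonferroni(p, alpha: float = 0.05) -> np.ndarray:
    """Family-wise flags: p_i <= alpha / m."""
    p = _clean_p(p)
    return p <= alpha / p.size


def benjamini_hochberg(p, q: float = 0.05) -> np.ndarray:
    """Step-up false-discovery-rate control at level ``q``.

    Flags all p-values up to the largest rank i with p_(i) <= i * q / m.
    """
    p = _clean_p(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = np.arange(1, m + 1) * q / m
    passed = np.nonzero(p[order] <= thresh)[0]
    flags = np.zeros(m, dtype=bool)
    if passed.size:
        flags[order[: passed[-1] + 1]] = True
    return flags


_LAMBDA_GRID = np.arange(0.05, 0.951, 0.05)


def storey_pi0(p, lambdas=_LAMBDA_GRID, smoother: str = "cubic") -> float:
    """Estimate the null proportion pi0 from the p-value tail.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed over the lambda
    grid and smoothed with a cubic (degree-3 least-squares) fit evaluated at
    the largest lambda; ``smoother="fixed"`` instead returns the raw estimate
    at lambda = 0.5.  Estimates above 1 are capped at 1 with a warning.
    """
    p = _clean_p(p)
    m = p.size
    lambdas = np.asarray(lambdas, dtype=float)
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if smoother == "cubic":
        coeffs = np.polyfit(lambdas, pi0_l, deg=3)
        pi0 = float(np.polyval(coeffs, lambdas[-1]))
    elif smoother == "fixed":
        pi0 = float(pi0_l[np.argmin(np.abs(lambdas - 0.5))])
    else:
        raise ValueError(f"unknown smoother {smoother!r}")
    if pi0 > 1.0:
        warnings.warn(f"pi0 estimate {pi0:.3f} > 1; capped at 1", stacklevel=2)
        pi0 = 1.0
    return max(pi0, 1.0 / m)


def storey_qvalues(p, smoother: str = "cubic", pi0: float | None = None) -> np.ndarray:
    """Storey q-values: FDR-analogue of each p-value.

    q_(i) = min_{j >= i} pi0 * m * p_(j) / j over the sorted p-values, which
    makes the q-values a monotone transform of the p-values, bounded by 1.
    """
    p = _clean_p(p)
    m = p.size
    if pi0 is None:
        pi0 = storey_pi0(p, smoother=smoother)
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.minimum(qv, 1.0)
    out = np.empty(m)
    out[order] = qv
    return out


def correction_summary(p, alpha: float = 0.05) -> dict[str, int | float]:
    """Counts of loci called significant by each correction at level ``alpha``."""
    p = _clean_p(p)
    p = p[~np.isnan(p)]
    pi0 = storey_pi0(p)
    return {
        "n": int(p.size),
        "pi0": pi0,
        "bonferroni": int(bonferroni(p, alpha).sum()),
        "benjamini_hochberg": int(benjamini_hochberg(p, alpha).sum()),
        "qvalue": int((storey_qvalues(p, pi0=pi0) <= alpha).sum()),
    }


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def evaluate_results(
    results: pd.DataFrame,
    tp_flags,
    alpha_grid=DEFAULT_ALPHA_GRID,
    fraction: float = 0.01,
    het_alpha: float = 0.05,
) -> list[FprTprReport]:
    """Build an FPR/TPR report per test from a tidy results frame.

    ``results`` must hold columns locus_id, test, p_main and p_het (NaN where
    absent); ``tp_flags`` maps each locus_id to its truth flag (array indexed
    by locus_id).  FPRs are computed on null loci only.  For consistency-call
    tests (cmh_woolf, gtest, glm_binom_m1) the heterogeneity veto enters the
    FPR per alpha (a locus counts as a false positive at alpha only if
    p_main <= alpha *and* p_het > alpha) and the TPR ranking uses the veto at
    the fixed level ``het_alpha``.
    """
    tp_flags = np.asarray(tp_flags, dtype=bool)
    reports: list[FprTprReport] = []
    for test, grp in results.groupby("test", sort=False):
        ids = grp["locus_id"].to_numpy()
        p_main = grp["p_main"].to_numpy(dtype=float)
        p_het = grp["p_het"].to_numpy(dtype=float)
        is_tp = tp_flags[ids]
        ok = ~np.isnan(p_main)
        if test in VETO_TESTS:
            ok &= ~np.isnan(p_het)
        n_dropped = int((~ok).sum())
        p_main, p_het, is_tp = p_main[ok], p_het[ok], is_tp[ok]

        null_main, null_het = p_main[~is_tp], p_het[~is_tp]
        if test in VETO_TESTS:
            fpr = np.array(
                [((null_main <= a) & (null_het > a)).mean() for a in alpha_grid]
            )
            p_rank = heterogeneity_veto(p_main, p_het, het_alpha)
        else:
            fpr = fpr_curve(null_main, alpha_grid)
            p_rank = p_main

        tpr = (
            tpr_top_fraction(p_rank, is_tp, fraction) if is_tp.any() else float("nan")
        )
        reports.append(
            FprTprReport(
                test_name=str(test),
                alpha_grid=tuple(alpha_grid),
                fpr=fpr,
                tpr=tpr,
                n_null=int((~is_tp).sum()),
                n_tp=int(is_tp.sum()),
                n_dropped=n_dropped,
            )
        )
    return reports
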