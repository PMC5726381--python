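"""Neutral drift simulator for replicated pool-seq experiments.

Generates per-SNP allele-count contingency tables under an instantaneous
fission model: an ancestral allele frequency is drawn from a symmetric beta
distribution at mutation-drift equilibrium, each treatment line drifts away
from it by an amount controlled by F_ST, and the observed read counts arise
from two rounds of binomial sampling (chromosomes into the pool, then reads
from the pool).  Optionally a fraction of loci is seeded as true positives
by adding a consistent frequency shift to one treatment line.

All draws flow from a single ``numpy.random.Generator`` so a dataset is
reproducible from its seed alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "SimParams",
    "LocusTable",
    "SimDataset",
    "draw_ancestral_freq",
    "draw_line_freq",
    "apply_tp_shift",
    "sample_pool_count",
    "draw_coverage",
    "sample_read_counts",
    "effective_sample_size",
    "rescale_counts",
    "simulate_locus",
    "simulate_dataset",
    "read_dataset_tsv",
]

COVERAGE_MODES = ("variable", "fixed", "neff")

#: maximum number of rejection / redraw rounds before aborting with a diagnostic
_MAX_REDRAW_ROUNDS = 1000


@dataclass(frozen=True)
class SimParams:
    """All population-genetic and sampling parameters of one simulation run.

    Parameters
    ----------
    theta:
        Scaled mutation rate 4*N_e*u = 4*N_e*v; both shape parameters of the
        beta distribution of the ancestral allele frequency.
    fst:
        Neutral divergence of each line from the ancestral population, in
        [0, 1).  The drift variance of a line frequency is fst * p * (1 - p).
    k:
        Number of biological replicates (pairs of treatment lines).
    pool_n_diploid:
        Pool size N in diploid individuals; the pool holds n = 2N chromosomes.
    coverage_mode:
        "variable" (negative-binomial read depth), "fixed" (constant depth
        ``fixed_coverage``) or "neff" (variable depth, counts rescaled per
        cell to the effective sample size).
    coverage_mean, coverage_dispersion, coverage_min:
        Negative-binomial mean, size parameter and lower rejection bound of
        the read depth in variable/neff modes.
    fixed_coverage:
        Read depth used when coverage_mode == "fixed".
    n_loci:
        Number of independent SNPs to simulate.
    tp_fraction, tp_shift:
        Fraction of loci seeded as true positives and the additive frequency
        shift applied to line 1 of every replicate at those loci.
    seed:
        Seed of the single random generator driving the whole dataset.
    """

    theta: float = 0.2
    fst: float = 0.2
    k: int = 4
    pool_n_diploid: int = 100
    coverage_mode: str = "variable"
    coverage_mean: float = 200.0
    coverage_dispersion: float = 2.0
    coverage_min: int = 10
    fixed_coverage: int = 200
    n_loci: int = 1000
    tp_fraction: float = 0.0
    tp_shift: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError(f"theta must be > 0, got {self.theta}")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.pool_n_diploid < 1:
            raise ValueError("pool_n_diploid must be >= 1")
        if self.coverage_mode not in COVERAGE_MODES:
            raise ValueError(
                f"coverage_mode must be one of {COVERAGE_MODES}, got {self.coverage_mode!r}"
            )
        if self.coverage_min < 1:
            raise ValueError("coverage_min must be >= 1")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage_mean and coverage_dispersion must be > 0")
        if self.fixed_coverage < 1:
            raise ValueError("fixed_coverage must be >= 1")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0.0 <= self.tp_fraction <= 1.0:
            raise ValueError("tp_fraction must be in [0, 1]")
        if not 0.0 <= self.tp_shift <= 1.0:
            raise ValueError("tp_shift must be in [0, 1]")

    @property
    def n_chrom(self) -> int:
        """Number of chromosomes in the pool, n = 2N."""
        return 2 * self.pool_n_diploid

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class LocusTable:
    """A 2 x 2 x k allele-count table for one SNP.

    Arrays are shaped ``(k, 2)`` with axis 0 the replicate and axis 1 the
    treatment line (index 0 = line 1, the shifted line at true positives;
    index 1 = line 2).  ``counts_a + counts_alt == coverage`` cell-wise.
    """

    counts_a: np.ndarray
    coverage: np.ndarray
    line_freqs: np.ndarray | None = None
    ancestral_freq: float = float("nan")
    is_true_positive: bool = False
    locus_id: str | int | None = None

    def __post_init__(self) -> None:
        self.counts_a = np.asarray(self.counts_a)
        self.coverage = np.asarray(self.coverage)
        if self.counts_a.shape != self.coverage.shape or self.counts_a.ndim != 2:
            raise ValueError("counts_a and coverage must both be (k, 2) arrays")
        if np.any(self.counts_a < 0) or np.any(self.counts_a > self.coverage):
            raise ValueError("counts must satisfy 0 <= counts_a <= coverage")

    @property
    def k(self) -> int:
        return self.counts_a.shape[0]

    @property
    def counts_alt(self) -> np.ndarray:
        return self.coverage - self.counts_a

    def is_monomorphic(self) -> bool:
        """True if the same allele is absent from all 2k cells."""
        return bool(np.all(self.counts_a == 0) or np.all(self.counts_alt == 0))


# ---------------------------------------------------------------------------
# elementary draws
# ---------------------------------------------------------------------------

def draw_ancestral_freq(params: SimParams, rng: np.random.Generator, size=None):
    """Ancestral 'A' allele frequency ~ Beta(theta, theta), strictly in (0, 1).

    Boundary values (possible only through floating-point underflow at small
    theta) are redrawn.
    """
    p = rng.beta(params.theta, params.theta, size=size)
    scalar = np.isscalar(p) or (isinstance(p, np.ndarray) and p.ndim == 0)
    p = np.atleast_1d(np.asarray(p, dtype=float))
    for _ in range(_MAX_REDRAW_ROUNDS):
        bad = (p <= 0.0) | (p >= 1.0)
        if not bad.any():
            break
        p[bad] = rng.beta(params.theta, params.theta, size=int(bad.sum()))
    else:  # pragma: no cover - essentially unreachable
        raise RuntimeError("could not draw an interior beta variate")
    return float(p[0]) if scalar and size is None else p


def draw_line_freq(p, fst: float, rng: np.random.Generator):
    """Line frequency from a normal(mean=p, var=fst*p*(1-p)) truncated to [0, 1].

    The truncation renormalises the density on [0, 1]; mean and variance are
    the parameters of the *untruncated* normal.  Where the drift variance is
    zero (fst == 0 or p on a boundary) the ancestral frequency is returned
    exactly.  Sampling is by inverse CDF, which vectorises over ``p``.
    """
    if fst < 0:
        raise ValueError(f"fst must be >= 0, got {fst}")
    p_arr = np.asarray(p, dtype=float)
    scalar = p_arr.ndim == 0
    p_arr = np.atleast_1d(p_arr)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("p must be in [0, 1]")
    out = p_arr.copy()
    var = fst * p_arr * (1.0 - p_arr)
    pos = var > 0
    if pos.any():
        mu = p_arr[pos]
        sigma = np.sqrt(var[pos])
        lo = ndtr((0.0 - mu) / sigma)
        hi = ndtr((1.0 - mu) / sigma)
        u = rng.uniform(lo, hi)
        out[pos] = np.clip(mu + sigma * ndtri(u), 0.0, 1.0)
    return float(out[0]) if scalar else out


def apply_tp_shift(f, shift: float):
    """Additive true-positive frequency shift, clamped at 1.0."""
    if shift < 0:
        raise ValueError("shift must be >= 0")
    return np.minimum(np.asarray(f, dtype=float) + shift, 1.0) if np.ndim(f) else float(
        min(f + shift, 1.0)
    )


def sample_pool_count(f, n_chrom: int, rng: np.random.Generator):
    """Count of 'A' chromosomes sampled into the pool, ~ Binomial(n_chrom, f)."""
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    return rng.binomial(n_chrom, f)


def draw_coverage(params: SimParams, rng: np.random.Generator, size=None):
    """Read depth CT per cell under the configured coverage model.

    In "variable" and "neff" modes CT ~ NegativeBinomial(mean=coverage_mean,
    size=coverage_dispersion), rejection-resampled until CT >= coverage_min
    (which preserves the negative-binomial shape above the cutoff).  In
    "fixed" mode CT == fixed_coverage.
    """
    if params.coverage_mode == "fixed":
        return (
            params.fixed_coverage
            if size is None
            else np.full(size, params.fixed_coverage, dtype=np.int64)
        )
    r = params.coverage_dispersion
    prob = r / (r + params.coverage_mean)
    ct = rng.negative_binomial(r, prob, size=size)
    ct = np.atleast_1d(np.asarray(ct))
    for _ in range(_MAX_REDRAW_ROUNDS):
        low = ct < params.coverage_min
        if not low.any():
            break
        ct[low] = rng.negative_binomial(r, prob, size=int(low.sum()))
    else:
        raise RuntimeError(
            f"coverage_min={params.coverage_min} not attainable from "
            f"NB(mean={params.coverage_mean}, size={params.coverage_dispersion}) "
            f"within {_MAX_REDRAW_ROUNDS} rejection rounds"
        )
    return int(ct[0]) if size is None else ct


def sample_read_counts(f_pool, ct, rng: np.random.Generator):
    """Second binomial round: reads are drawn with replacement from the pool."""
    c_a = rng.binomial(ct, f_pool)
    return c_a, np.asarray(ct) - c_a if np.ndim(ct) else ct - c_a


def effective_sample_size(n_chrom, ct):
    """Effective number of independent observations in a pool-seq count.

    n_eff = (n * CT - 1) / (n + CT), discounting the double binomial sampling
    of CT reads from a finite pool of n chromosomes.  Always strictly below
    min(n, CT) and approaches n as CT grows.
    """
    n_arr = np.asarray(n_chrom, dtype=float)
    ct_arr = np.asarray(ct, dtype=float)
    out = (n_arr * ct_arr - 1.0) / (n_arr + ct_arr)
    return float(out) if out.ndim == 0 else out


def rescale_counts(c_a, ct, target):
    """Rescale an allele count to be out of ``round(target)`` units.

    The target (e.g. a non-integer n_eff) is rounded half-to-even to an
    integer T; the 'A' count is T times the observed proportion, rounded
    half-to-even; the complement is obtained by subtraction so the rescaled
    cell always sums to T exactly.
    """
    ct_arr = np.asarray(ct)
    if np.any(ct_arr == 0):
        raise ValueError("cannot rescale a cell with zero coverage")
    t = np.rint(np.asarray(target, dtype=float)).astype(np.int64)
    c_new = np.rint(np.asarray(c_a, dtype=float) / ct_arr * t).astype(np.int64)
    alt_new = t - c_new
    if np.ndim(c_a) == 0 and np.ndim(target) == 0:
        return int(c_new), int(alt_new)
    return c_new, alt_new


# ---------------------------------------------------------------------------
# locus / dataset generation
# ---------------------------------------------------------------------------

def _simulate_block(
    params: SimParams, is_tp: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw raw tables for ``len(is_tp)`` loci, without the fixation screen.

    Returns (ancestral_freq (m,), line_freqs (m,k,2), counts_a (m,k,2),
    coverage (m,k,2)).
    """
    m = is_tp.shape[0]
    k = params.k
    p = draw_ancestral_freq(params, rng, size=m)
    f = draw_line_freq(np.broadcast_to(p[:, None, None], (m, k, 2)).copy(), params.fst, rng)
    if is_tp.any() and params.tp_shift > 0:
        f[is_tp, :, 0] = apply_tp_shift(f[is_tp, :, 0], params.tp_shift)
    x = sample_pool_count(f, params.n_chrom, rng)
    f_pool = x / params.n_chrom
    ct = draw_coverage(params, rng, size=(m, k, 2))
    ct = np.asarray(ct, dtype=np.int64)
    c_a, _ = sample_read_counts(f_pool, ct, rng)
    if params.coverage_mode == "neff":
        target = effective_sample_size(params.n_chrom, ct)
        c_a, alt = rescale_counts(c_a, ct, target)
        ct = c_a + alt
    return p, f, c_a.astype(np.int64), ct


def _monomorphic_mask(counts_a: np.ndarray, coverage: np.ndarray) -> np.ndarray:
    alt = coverage - counts_a
    return np.all(counts_a == 0, axis=(1, 2)) | np.all(alt == 0, axis=(1, 2))


def simulate_locus(
    params: SimParams, is_tp: bool, rng: np.random.Generator
) -> LocusTable:
    """Simulate one SNP, redrawing (including the ancestral frequency) until
    the locus is not fixed for the same allele across all 2k cells."""
    flag = np.array([bool(is_tp)])
    for _ in range(_MAX_REDRAW_ROUNDS):
        p, f, c_a, ct = _simulate_block(params, flag, rng)
        if not _monomorphic_mask(c_a, ct)[0]:
            return LocusTable(
                counts_a=c_a[0],
                coverage=ct[0],
                line_freqs=f[0],
                ancestral_freq=float(p[0]),
                is_true_positive=bool(is_tp),
            )
    raise RuntimeError(
        f"locus stayed monomorphic after {_MAX_REDRAW_ROUNDS} redraws; "
        "parameters make polymorphic tables vanishingly rare"
    )


@dataclass
class SimDataset:
    """A simulated dataset: stacked per-locus arrays plus the generating params.

    ``counts_a``, ``coverage`` and ``line_freqs`` are shaped
    ``(n_loci, k, 2)``; ``ancestral_freq`` and ``is_true_positive`` are
    per-locus vectors.
    """

    params: SimParams
    counts_a: np.ndarray
    coverage: np.ndarray
    line_freqs: np.ndarray
    ancestral_freq: np.ndarray
    is_true_positive: np.ndarray

    @property
    def n_loci(self) -> int:
        return self.counts_a.shape[0]

    def tables(self) -> Iterator[LocusTable]:
        for i in range(self.n_loci):
            yield LocusTable(
                counts_a=self.counts_a[i],
                coverage=self.coverage[i],
                line_freqs=self.line_freqs[i] if self.line_freqs is not None else None,
                ancestral_freq=float(self.ancestral_freq[i]),
                is_true_positive=bool(self.is_true_positive[i]),
                locus_id=i,
            )

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format counts: one row per (locus, replicate, line)."""
        n, k, _ = self.counts_a.shape
        locus = np.repeat(np.arange(n), 2 * k)
        rep = np.tile(np.repeat(np.arange(1, k + 1), 2), n)
        line = np.tile([1, 2], n * k)
        ca = self.counts_a.reshape(-1)
        cov = self.coverage.reshape(-1)
        return pd.DataFrame(
            {
                "locus_id": locus,
                "replicate": rep,
                "line": line,
                "count_A": ca,
                "count_a": cov - ca,
                "coverage": cov,
                "is_true_positive": np.repeat(self.is_true_positive.astype(int), 2 * k),
            }
        )

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": np.arange(self.n_loci),
                "is_true_positive": self.is_true_positive.astype(int),
                "ancestral_freq": self.ancestral_freq,
            }
        )

    def write(self, prefix: str | Path) -> dict[str, Path]:
        """Write ``<prefix>.counts.tsv``, ``<prefix>.truth.tsv`` and
        ``<prefix>.meta.json``; returns the paths."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": prefix.with_suffix(".counts.tsv"),
            "truth": prefix.with_suffix(".truth.tsv"),
            "meta": prefix.with_suffix(".meta.json"),
        }
        self.to_frame().to_csv(paths["counts"], sep="\t", index=False)
        self.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
        paths["meta"].write_text(
            json.dumps({"format": "poolfreqtest.dataset", "params": self.params.to_dict()},
                       indent=2)
            + "\n"
        )
        return paths


def simulate_dataset(params: SimParams) -> SimDataset:
    """Simulate ``params.n_loci`` independent SNPs.

    Exactly ``round(tp_fraction * n_loci)`` loci (the leading block) are
    seeded as true positives.  Loci fixed for the same allele across all 2k
    cells are fully redrawn (new ancestral frequency included) until the
    dataset contains none.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_loci
    n_tp = int(round(params.tp_fraction * n))
    is_tp = np.zeros(n, dtype=bool)
    is_tp[:n_tp] = True

    p, f, c_a, ct = _simulate_block(params, is_tp, rng)
    for _ in range(_MAX_REDRAW_ROUNDS):
        bad = _monomorphic_mask(c_a, ct)
        if not bad.any():
            break
        p2, f2, c2, ct2 = _simulate_block(params, is_tp[bad], rng)
        p[bad] = p2
        f[bad] = f2
        c_a[bad] = c2
        ct[bad] = ct2
    else:
        raise RuntimeError(
            f"monomorphic loci persisted after {_MAX_REDRAW_ROUNDS} redraw rounds"
        )
    return SimDataset(
        params=params,
        counts_a=c_a,
        coverage=ct,
        line_freqs=f,
        ancestral_freq=p,
        is_true_positive=is_tp,
    )


def read_dataset_tsv(counts_path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a long-format counts TSV back into stacked arrays.

    Returns (counts_a (n,k,2), coverage (n,k,2), is_true_positive (n,)).
    """
    df = pd.read_csv(counts_path, sep="\t", comment="#")
    required = {"locus_id", "replicate", "line", "count_A", "coverage"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts TSV missing columns: {sorted(missing)}")
    df = df.sort_values(["locus_id", "replicate", "line"])
    loci = df["locus_id"].unique()
    k = df["replicate"].nunique()
    n = len(loci)
    if len(df) != n * k * 2:
        raise ValueError("counts TSV is not a complete (locus x replicate x line) grid")
    ca = df["count_A"].to_numpy(dtype=np.int64).reshape(n, k, 2)
    cov = df["coverage"].to_numpy(dtype=np.int64).reshape(n, k, 2)
    if "is_true_positive" in df.columns:
        tp = df["is_true_positive"].to_numpy().reshape(n, k * 2)[:, 0].astype(bool)
    else:
        tp = np.zeros(n, dtype=bool)
    return ca, cov, tp
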