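"""popoolation2 "sync" file support: parsing, SNP filtering and table assembly.

A sync file is tab-separated with columns chrom, pos, ref and then one
``A:T:C:G:N:del`` read-count field per pool.  This module reads such files
(gzip-transparent), calls truly biallelic SNPs, applies coverage filters,
orients the major allele, optionally rescales counts (fixed total or
effective sample size) and assembles the 2 x 2 x k tables consumed by the
association tests, so the quasibinomial pipeline runs identically on real
data and on simulator exports.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .simulate import LocusTable, SimDataset, effective_sample_size, rescale_counts

__all__ = [
    "SyncRecord",
    "PoolDesign",
    "SyncParseError",
    "read_sync",
    "write_sync",
    "call_biallelic",
    "filter_coverage",
    "to_locus_table",
    "sync_to_tables",
    "default_design",
]

logger = logging.getLogger(__name__)

#: nucleotide order of a sync count field
SYNC_ALLELES = ("A", "T", "C", "G", "N", "del")


class SyncParseError(ValueError):
    """Malformed sync line; the message names the file line number."""


@dataclass
class SyncRecord:
    """One genomic position with per-pool nucleotide read counts.

    ``pools`` is an ``(n_pools, 6)`` integer array in A, T, C, G, N, del order
    (the fixed column order of the sync format); coordinates are 1-based.
    """

    chrom: str
    pos: int
    ref: str
    pools: np.ndarray

    def __post_init__(self) -> None:
        self.pools = np.asarray(self.pools, dtype=np.int64)
        if self.pools.ndim != 2 or self.pools.shape[1] != 6:
            raise ValueError("pools must be an (n_pools, 6) array")
        if self.pos < 1:
            raise ValueError("sync positions are 1-based (pos >= 1)")
        if np.any(self.pools < 0):
            raise ValueError("read counts must be non-negative")

    @property
    def n_pools(self) -> int:
        return self.pools.shape[0]


@dataclass(frozen=True)
class PoolDesign:
    """Assignment of sync pool columns to (replicate, treatment line).

    ``pairs[r] = (i, j)`` maps 0-based pool column i to line 1 and j to
    line 2 of replicate r.  All pool indices must be distinct.
    """

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        flat = [i for pair in self.pairs for i in pair]
        if len(set(flat)) != len(flat):
            raise ValueError("pool columns must be assigned to at most one cell")
        if any(i < 0 for i in flat):
            raise ValueError("pool indices must be non-negative")

    @property
    def k(self) -> int:
        return len(self.pairs)

    @property
    def max_pool(self) -> int:
        return max(i for pair in self.pairs for i in pair)

    @classmethod
    def from_string(cls, spec: str) -> "PoolDesign":
        """Parse a design string like ``"1:4,2:5,3:6"`` (1-based pool columns,
        line1:line2 per replicate)."""
        pairs = []
        for part in spec.split(","):
            try:
                i, j = part.split(":")
                pairs.append((int(i) - 1, int(j) - 1))
            except ValueError as exc:
                raise ValueError(f"bad design element {part!r}; expected 'i:j'") from exc
        return cls(pairs=tuple(pairs))


def default_design(k: int) -> PoolDesign:
    """Design matching the simulator's sync export: pools in (rep, line) order."""
    return PoolDesign(pairs=tuple((2 * r, 2 * r + 1) for r in range(k)))


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_sync(path: str | Path, strict: bool = True) -> Iterator[SyncRecord]:
    """Stream SyncRecords from a (possibly gzipped) sync file.

    With ``strict=True`` a malformed line raises :class:`SyncParseError`
    naming the line number; with ``strict=False`` the line is skipped with a
    logged warning, which tolerates real-world files.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 4:
                    raise SyncParseError(
                        f"{path}:{lineno}: expected >= 4 tab-separated fields, "
                        f"got {len(fields)}"
                    )
                chrom, pos_s, ref = fields[0], fields[1], fields[2]
                pools = []
                for fld in fields[3:]:
                    parts = fld.split(":")
                    if len(parts) != 6:
                        raise SyncParseError(
                            f"{path}:{lineno}: pool field {fld!r} is not A:T:C:G:N:del"
                        )
                    pools.append([int(x) for x in parts])
                yield SyncRecord(
                    chrom=chrom, pos=int(pos_s), ref=ref, pools=np.array(pools)
                )
            except (SyncParseError, ValueError) as exc:
                if strict:
                    if isinstance(exc, SyncParseError):
                        raise
                    raise SyncParseError(f"{path}:{lineno}: {exc}") from exc
                logger.warning("skipping malformed sync line %s:%d (%s)", path, lineno, exc)


def write_sync(
    source: SimDataset | Iterable[SyncRecord], path: str | Path
) -> None:
    """Write sync records, or a simulated dataset, to ``path``.

    A :class:`~poolfreqtest.simulate.SimDataset` is exported with the 'A'
    allele mapped to nucleotide A and the alternative allele to T, pools
    ordered (replicate 1 line 1, replicate 1 line 2, ...), chrom "sim" and
    1-based positions equal to locus_id + 1 (see :func:`default_design`).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with _open_text(path, "wt") as fh:
        if isinstance(source, SimDataset):
            n, k, _ = source.counts_a.shape
            ca = source.counts_a.reshape(n, 2 * k)
            cov = source.coverage.reshape(n, 2 * k)
            for i in range(n):
                cells = [
                    f"{ca[i, j]}:{cov[i, j] - ca[i, j]}:0:0:0:0" for j in range(2 * k)
                ]
                fh.write("\t".join(["sim", str(i + 1), "N", *cells]) + "\n")
        else:
            for rec in source:
                cells = [":".join(str(x) for x in pool) for pool in rec.pools]
                fh.write("\t".join([rec.chrom, str(rec.pos), rec.ref, *cells]) + "\n")


# ---------------------------------------------------------------------------
# SNP calling and filtering
# ---------------------------------------------------------------------------

def call_biallelic(rec: SyncRecord, min_count: int = 10) -> tuple[int, int] | None:
    """Call a truly biallelic SNP from pooled counts.

    Counts of A/T/C/G are summed across pools (N and deletions are ignored);
    alleles whose pooled total reaches ``min_count`` qualify.  The record is
    accepted only if exactly two alleles qualify, and the major (larger total)
    allele becomes the 'A' allele of the locus.  Returns (major_index,
    minor_index) into the sync nucleotide order, or None to reject.
    """
    totals = rec.pools[:, :4].sum(axis=0)
    qualifying = np.nonzero(totals >= min_count)[0]
    if qualifying.size != 2:
        return None
    i, j = qualifying
    return (int(i), int(j)) if totals[i] >= totals[j] else (int(j), int(i))


def filter_coverage(
    rec: SyncRecord,
    alleles: tuple[int, int],
    min_cov: int = 10,
    max_cov: int = 500,
) -> bool:
    """Accept a called SNP only if every pool's coverage is within bounds.

    Coverage of a pool is the sum of the two called alleles' counts (other
    nucleotides, Ns and deletions do not count toward depth).
    """
    cov = rec.pools[:, alleles[0]] + rec.pools[:, alleles[1]]
    return bool(np.all(cov >= min_cov) and np.all(cov <= max_cov))


def _parse_rescale(rescale) -> tuple[str, float | None]:
    if isinstance(rescale, tuple):
        return rescale
    if rescale == "raw":
        return ("raw", None)
    if isinstance(rescale, str) and ":" in rescale:
        kind, value = rescale.split(":", 1)
        if kind in ("fixed", "neff"):
            return (kind, float(value))
    raise ValueError(
        f"rescale must be 'raw', 'fixed:<T>' or 'neff:<n_chrom>', got {rescale!r}"
    )


def to_locus_table(
    rec: SyncRecord,
    design: PoolDesign,
    rescale="raw",
    alleles: tuple[int, int] | None = None,
    min_count: int = 10,
) -> LocusTable:
    """Assemble the 2 x 2 x k table of a called SNP under a pool design.

    ``rescale`` is "raw" (counts pass through), "fixed:<T>" (each cell
    rescaled to be out of T) or "neff:<n_chrom>" (each cell rescaled to the
    effective sample size computed from that cell's own coverage).
    """
    if alleles is None:
        alleles = call_biallelic(rec, min_count=min_count)
        if alleles is None:
            raise ValueError(f"{rec.chrom}:{rec.pos} is not a biallelic SNP")
    if rec.n_pools <= design.max_pool:
        raise ValueError(
            f"design references pool {design.max_pool + 1} but the record has "
            f"only {rec.n_pools} pools"
        )
    kind, value = _parse_rescale(rescale)
    major, minor = alleles
    ca = np.empty((design.k, 2), dtype=np.int64)
    cov = np.empty((design.k, 2), dtype=np.int64)
    for r, (i, j) in enumerate(design.pairs):
        for col, pool_idx in ((0, i), (1, j)):
            c_major = int(rec.pools[pool_idx, major])
            c_minor = int(rec.pools[pool_idx, minor])
            ct = c_major + c_minor
            if kind == "raw":
                ca[r, col], cov[r, col] = c_major, ct
            elif kind == "fixed":
                new_major, new_minor = rescale_counts(c_major, ct, value)
                ca[r, col], cov[r, col] = new_major, new_major + new_minor
            else:  # neff
                target = effective_sample_size(value, ct)
                new_major, new_minor = rescale_counts(c_major, ct, target)
                ca[r, col], cov[r, col] = new_major, new_major + new_minor
    return LocusTable(
        counts_a=ca, coverage=cov, locus_id=f"{rec.chrom}:{rec.pos}"
    )


def sync_to_tables(
    path: str | Path,
    design: PoolDesign,
    min_count: int = 10,
    min_cov: int = 10,
    max_cov: int = 500,
    rescale="raw",
    strict: bool = True,
) -> tuple[list[LocusTable], pd.DataFrame]:
    """Full sync pipeline: parse, call biallelic SNPs, filter coverage, assemble.

    Returns the accepted LocusTables and a filter log (locus, reason) for the
    rejected positions.  Filters run in a fixed order: biallelic call first,
    coverage bounds second.
    """
    tables: list[LocusTable] = []
    rejected: list[tuple[str, str]] = []
    n_seen = 0
    for rec in read_sync(path, strict=strict):
        n_seen += 1
        if n_seen % 10_000 == 0:
            logger.info("processed %d sync positions", n_seen)
        locus = f"{rec.chrom}:{rec.pos}"
        alleles = call_biallelic(rec, min_count=min_count)
        if alleles is None:
            rejected.append((locus, "not_biallelic"))
            continue
        if not filter_coverage(rec, alleles, min_cov=min_cov, max_cov=max_cov):
            rejected.append((locus, "coverage_out_of_bounds"))
            continue
        tables.append(to_locus_table(rec, design, rescale=rescale, alleles=alleles))
    log = pd.DataFrame(rejected, columns=["locus", "reason"])
    return tables, log
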