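"""Readers, writers and the core count containers.

The pipeline's universal input is the "sync" format popularised by
PoPoolation2: one TAB-separated row per genomic position carrying, for each
pool, a colon-separated count 6-tuple ``A:T:C:G:N:del``.  Coordinates are
1-based inclusive in sync and GFF3; BED output is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .design import PoolDesign

SYNC_CLASSES = ("A", "T", "C", "G", "N", "del")
_NUCS = ("A", "T", "C", "G")
# column indices of the four nucleotide classes inside the 6-tuple
_NUC_IDX = np.array([0, 1, 2, 3])


class SyncFormatError(ValueError):
    """Malformed sync input; the message names the offending line."""


class GffFormatError(ValueError):
    """Malformed GFF3 input; the message names the offending line."""


class AlleleCountTable:
    """Per-site, per-pool counts of the six sync classes (A,T,C,G,N,del).

    Parameters
    ----------
    chrom, pos, ref : array-like
        Sequence name, 1-based position, reference base per site.
    counts : ndarray of shape (n_sites, n_pools, 6)
        Non-negative read counts in sync class order.

    Records are sorted by (chrom, pos) on construction; duplicate
    (chrom, pos) records are rejected.
    """

    def __init__(self, chrom, pos, ref, counts) -> None:
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        ref = np.asarray(ref, dtype=object)
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim != 3 or counts.shape[2] != 6:
            raise ValueError("counts must have shape (n_sites, n_pools, 6)")
        n = counts.shape[0]
        if not (len(chrom) == len(pos) == len(ref) == n):
            raise ValueError("chrom/pos/ref/counts lengths disagree")
        if np.any(counts < 0):
            raise ValueError("negative counts")
        if n and np.any(pos < 1):
            raise ValueError("positions must be >= 1 (1-based)")
        order = np.lexsort((pos, chrom)) if n else np.array([], dtype=int)
        self.chrom = chrom[order]
        self.pos = pos[order]
        self.ref = ref[order]
        self.counts = counts[order]
        if n > 1:
            same = (self.chrom[1:] == self.chrom[:-1]) & (
                self.pos[1:] == self.pos[:-1]
            )
            if np.any(same):
                i = int(np.flatnonzero(same)[0])
                raise ValueError(
                    f"duplicate record {self.chrom[i]}:{self.pos[i]}"
                )

    @property
    def n_sites(self) -> int:
        return int(self.counts.shape[0])

    @property
    def n_pools(self) -> int:
        return int(self.counts.shape[1])

    def __len__(self) -> int:
        return self.n_sites

    def coverage(self) -> np.ndarray:
        """Per-site, per-pool coverage: the sum of the six count classes."""
        return self.counts.sum(axis=2)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AlleleCountTable):
            return NotImplemented
        return (
            np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.counts, other.counts)
        )


class BiallelicSite(NamedTuple):
    chrom: str
    pos: int
    major_allele: str
    minor_allele: str
    major_counts: np.ndarray
    minor_counts: np.ndarray


class BiallelicTable:
    """Sites reduced to their two most frequent nucleotides.

    ``major_counts``/``minor_counts`` have shape (n_sites, n_pools); the
    major allele is the one with the larger summed count across pools.
    Third/fourth alleles and N/del reads are discarded.
    """

    def __init__(self, chrom, pos, major, minor, major_counts, minor_counts):
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.major = np.asarray(major, dtype=object)
        self.minor = np.asarray(minor, dtype=object)
        self.major_counts = np.asarray(major_counts, dtype=np.int64)
        self.minor_counts = np.asarray(minor_counts, dtype=np.int64)

    @property
    def n_sites(self) -> int:
        return int(len(self.pos))

    @property
    def n_pools(self) -> int:
        if self.major_counts.ndim == 2:
            return int(self.major_counts.shape[1])
        return 0

    def __len__(self) -> int:
        return self.n_sites

    def site(self, i: int) -> BiallelicSite:
        return BiallelicSite(
            str(self.chrom[i]),
            int(self.pos[i]),
            str(self.major[i]),
            str(self.minor[i]),
            self.major_counts[i],
            self.minor_counts[i],
        )

    def __iter__(self):
        return (self.site(i) for i in range(self.n_sites))

    def snp_ids(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)]


@dataclass(frozen=True)
class GeneModel:
    """A gene as the UTR-to-UTR span extended by a flank on both sides."""

    gene_id: str
    chrom: str
    span_start: int  # 1-based inclusive, flank applied, clamped at 1
    span_end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.span_start > self.span_end:
            raise ValueError(
                f"gene {self.gene_id}: span_start > span_end"
            )
        if self.span_start < 1:
            raise ValueError(f"gene {self.gene_id}: span_start < 1")

    def contains(self, chrom: str, pos: int) -> bool:
        return (
            chrom == self.chrom and self.span_start <= pos <= self.span_end
        )


def read_sync(path, design: PoolDesign) -> AlleleCountTable:
    """Read a sync file into an :class:`AlleleCountTable`.

    Each data line must carry ``chrom pos ref`` followed by exactly one
    ``A:T:C:G:N:del`` 6-tuple per pool in *design*.  Malformed lines raise
    :class:`SyncFormatError` naming the line number.
    """
    n_pools = design.n_lines
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    counts: list[list[int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3 + n_pools:
                raise SyncFormatError(
                    f"line {lineno}: expected {3 + n_pools} columns "
                    f"(3 + {n_pools} pools), got {len(fields)}"
                )
            chrom, pos_s, ref = fields[:3]
            try:
                pos = int(pos_s)
            except ValueError:
                raise SyncFormatError(
                    f"line {lineno}: non-integer position {pos_s!r}"
                ) from None
            row: list[int] = []
            for pool_field in fields[3:]:
                parts = pool_field.split(":")
                if len(parts) != 6:
                    raise SyncFormatError(
                        f"line {lineno}: count field {pool_field!r} is not "
                        "a 6-tuple A:T:C:G:N:del"
                    )
                try:
                    vals = [int(x) for x in parts]
                except ValueError:
                    raise SyncFormatError(
                        f"line {lineno}: non-integer count in "
                        f"{pool_field!r}"
                    ) from None
                if any(v < 0 for v in vals):
                    raise SyncFormatError(
                        f"line {lineno}: negative count in {pool_field!r}"
                    )
                row.extend(vals)
            chroms.append(chrom)
            poss.append(pos)
            refs.append(ref)
            counts.append(row)
    arr = (
        np.asarray(counts, dtype=np.int64).reshape(len(counts), n_pools, 6)
        if counts
        else np.empty((0, n_pools, 6), dtype=np.int64)
    )
    return AlleleCountTable(chroms, poss, refs, arr)


def write_sync(table: AlleleCountTable, path) -> None:
    """Write an :class:`AlleleCountTable` back to sync format."""
    with open(path, "w") as fh:
        for i in range(table.n_sites):
            pools = "\t".join(
                ":".join(str(int(c)) for c in table.counts[i, p])
                for p in range(table.n_pools)
            )
            fh.write(f"{table.chrom[i]}\t{table.pos[i]}\t{table.ref[i]}\t{pools}\n")


def reduce_to_biallelic(
    table: AlleleCountTable,
    min_cov: int = 10,
    min_minor_count: int = 4,
) -> BiallelicTable:
    """Reduce each site to its two most frequent nucleotides and filter.

    A site is kept iff every pool's coverage is >= *min_cov* and the
    summed minor-allele count across pools is >= *min_minor_count*.
    Alleles are ranked by summed count over all pools, ties broken
    alphabetically; N/del and any third/fourth allele reads are dropped.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    if min_minor_count < 0:
        raise ValueError("min_minor_count must be >= 0")
    if table.n_sites == 0:
        return BiallelicTable(
            [], [], [], [],
            np.empty((0, table.n_pools), dtype=np.int64),
            np.empty((0, table.n_pools), dtype=np.int64),
        )
    nuc = table.counts[:, :, _NUC_IDX]  # (n, P, 4)
    totals = nuc.sum(axis=1)  # (n, 4) summed over pools
    # rank alleles by (count desc, alphabetical asc); A<C<G<T
    alpha_rank = np.array([0, 3, 1, 2])  # A,T,C,G -> alphabetical order
    key = totals * 8 - alpha_rank  # count dominates; ties favour earlier letter
    order = np.argsort(-key, axis=1, kind="stable")
    maj_idx = order[:, 0]
    min_idx = order[:, 1]
    rows = np.arange(table.n_sites)
    major_counts = nuc[rows, :, maj_idx]
    minor_counts = nuc[rows, :, min_idx]
    keep = np.all(table.coverage() >= min_cov, axis=1) & (
        minor_counts.sum(axis=1) >= min_minor_count
    )
    letters = np.array(_NUCS, dtype=object)
    return BiallelicTable(
        table.chrom[keep],
        table.pos[keep],
        letters[maj_idx[keep]],
        letters[min_idx[keep]],
        major_counts[keep],
        minor_counts[keep],
    )


_UTR_TYPES = ("five_prime_UTR", "three_prime_UTR")


def read_gff_genes(path, flank_bp: int = 1000) -> list[GeneModel]:
    """Load gene models from GFF3 as UTR-to-UTR spans with a flank.

    Each gene's span runs from the outermost UTR boundary to the outermost
    UTR boundary of its transcripts (falling back to the gene feature's own
    bounds when no UTR features are annotated), then extended by *flank_bp*
    on both sides and clamped at position 1.  Strand is recorded but the
    flank is symmetric regardless of strand.
    """
    import gffutils

    _validate_gff_lines(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        starts = [gene.start]
        ends = [gene.end]
        utr_starts: list[int] = []
        utr_ends: list[int] = []
        for utr in db.children(gene, featuretype=_UTR_TYPES):
            utr_starts.append(utr.start)
            utr_ends.append(utr.end)
        if utr_starts:
            starts, ends = utr_starts, utr_ends
        span_start = max(1, min(starts) - flank_bp)
        span_end = max(ends) + flank_bp
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                span_start=span_start,
                span_end=span_end,
                strand=gene.strand or ".",
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.span_start, g.gene_id))
    return genes


def _validate_gff_lines(path) -> None:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GffFormatError(
                    f"line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                int(fields[3]), int(fields[4])
            except ValueError:
                raise GffFormatError(
                    f"line {lineno}: non-integer coordinates "
                    f"{fields[3]!r}..{fields[4]!r}"
                ) from None


def read_go_map(path) -> dict[str, set[str]]:
    """Read a two-column TSV mapping gene_id -> GO term (one pair per line)."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"line {lineno}: expected 2 tab-separated columns"
                )
            mapping.setdefault(fields[0], set()).add(fields[1])
    return mapping


def write_candidates_bed(
    chroms: Sequence[str],
    positions: Sequence[int],
    scores: Sequence[float],
    path,
) -> None:
    """Write candidate SNPs as 6-column BED (0-based half-open intervals).

    A SNP at 1-based position p becomes the interval [p-1, p); name is
    ``chrom:pos``, score column carries the SNP's SNR, strand is ``.``.
    """
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for c, p, s in zip(chroms, positions, scores):
            fh.write(f"{c}\t{p - 1}\t{p}\t{c}:{p}\t{s:.6g}\t.\n")


def write_stats_tsv(stats: pd.DataFrame, path) -> None:
    """Write the per-SNP statistics table as TSV (full float precision)."""
    stats.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_stats_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gene_list(path) -> list[str]:
    """Read a candidate gene list: one gene id per line, '#' comments."""
    out: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
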