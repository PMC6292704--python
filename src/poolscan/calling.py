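"""Candidate SNP calling and the combinatorial significance null.

A SNP is a candidate when it passes, in every pair of a comparison set,
both filters at once: F_ST above a threshold (default 0.9, strict) and a
Bonferroni-adjusted Fisher P below alpha (default 1e-9, strict).  For the
2-control x 4-selection design the "true" comparison set is the eight
selection-vs-control pairs.

The combinatorial null re-applies the identical criteria to every
possible same-size set of line pairs — C(15, 8) = 6435 sets for six lines
— and ranks the true set's candidate count among them.  When the true set
is the strict maximum the empirical P attains its floor 1/6435 ~ 1.554e-4
(the observed set counts in both numerator and denominator).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .design import PoolDesign
from .io import GeneModel
from .stats import PairwiseStats


@dataclass(frozen=True)
class ComparisonSet:
    """A set of k unordered line-index pairs to apply the criteria over."""

    pairs: tuple[tuple[int, int], ...]
    is_true_set: bool = False

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("comparison set contains duplicate pairs")


def true_comparison_set(design: PoolDesign) -> ComparisonSet:
    """The biologically informative set: all between-regime pairs."""
    return ComparisonSet(tuple(design.between_pairs()), is_true_set=True)


def enumerate_comparison_sets(
    design: PoolDesign, k: int | None = None
) -> list[ComparisonSet]:
    """All C(C(L,2), k) k-subsets of the design's line pairs.

    ``k`` defaults to the number of between-regime pairs (8 for the
    2x4 design, giving 6435 sets); the true set is flagged.
    """
    all_pairs = design.all_pairs()
    if k is None:
        k = len(design.between_pairs())
    if k > len(all_pairs):
        raise ValueError(
            f"k={k} exceeds the {len(all_pairs)} available pairs"
        )
    true_set = frozenset(design.between_pairs())
    sets = []
    for combo in itertools.combinations(all_pairs, k):
        sets.append(
            ComparisonSet(combo, is_true_set=frozenset(combo) == true_set)
        )
    assert len(sets) == comb(len(all_pairs), k)
    return sets


def candidate_mask(
    stats: PairwiseStats,
    cset: ComparisonSet,
    fst_threshold: float = 0.9,
    alpha: float = 1e-9,
) -> np.ndarray:
    """Boolean per-SNP candidate flags under one comparison set.

    A SNP qualifies iff, in every pair of the set, F_ST > fst_threshold
    and adjusted P < alpha (both strict).  Any undefined pair disqualifies
    the SNP.
    """
    idx = [stats.pair_index(p) for p in cset.pairs]
    fst = stats.fst[:, idx]
    padj = stats.p_adjusted[:, idx]
    ok = (fst > fst_threshold) & (padj < alpha) & ~np.isnan(fst)
    return np.all(ok, axis=1)


def call_candidates(
    stats: PairwiseStats,
    cset: ComparisonSet | None = None,
    fst_threshold: float = 0.9,
    alpha: float = 1e-9,
) -> pd.DataFrame:
    """Per-SNP candidate calls over a comparison set (default: true set).

    Returns one row per SNP with the set's per-pair F_ST and adjusted P
    plus the conjunctive ``is_candidate`` flag.
    """
    if cset is None:
        cset = true_comparison_set(stats.design)
    mask = candidate_mask(stats, cset, fst_threshold, alpha)
    sites = stats.sites
    data: dict[str, object] = {
        "chrom": sites.chrom,
        "pos": sites.pos,
        "snp_id": sites.snp_ids(),
    }
    p_adj = stats.p_adjusted
    for pair in cset.pairs:
        k = stats.pair_index(pair)
        label = stats.design.pair_label(pair)
        data[f"fst_{label}"] = stats.fst[:, k]
        data[f"padj_{label}"] = p_adj[:, k]
    data["is_candidate"] = mask
    return pd.DataFrame(data)


@dataclass
class CombinatorialNull:
    """Result of the all-subsets null over comparison sets."""

    counts: np.ndarray  # candidate count per set
    is_true: np.ndarray  # flag per set
    empirical_p: float
    sets: list[ComparisonSet] = field(repr=False)

    @property
    def true_count(self) -> int:
        return int(self.counts[self.is_true][0])

    @property
    def true_is_strict_max(self) -> bool:
        others = self.counts[~self.is_true]
        return bool(others.size == 0 or self.true_count > others.max())

    def frame(self, design: PoolDesign) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "set": [
                    "+".join(design.pair_label(p) for p in s.pairs)
                    for s in self.sets
                ],
                "is_true_set": self.is_true,
                "n_candidates": self.counts,
            }
        )


def combinatorial_null(
    stats: PairwiseStats,
    fst_threshold: float = 0.9,
    alpha: float = 1e-9,
    k: int | None = None,
) -> CombinatorialNull:
    """Rank the true set's candidate count among all k-subsets of pairs.

    The empirical P is the fraction of sets (observed set included) whose
    candidate count is >= the true set's count; with 6435 sets its floor
    is 1/6435 ~ 1.554e-4, attained when the true set is the strict
    maximum.
    """
    sets = enumerate_comparison_sets(stats.design, k=k)
    # one boolean pass-matrix, then each set is a column conjunction
    idx_of = {pair: stats.pair_index(pair) for pair in stats.pairs}
    fst = stats.fst
    padj = stats.p_adjusted
    passes = (fst > fst_threshold) & (padj < alpha) & ~np.isnan(fst)
    counts = np.empty(len(sets), dtype=np.int64)
    is_true = np.zeros(len(sets), dtype=bool)
    for i, cset in enumerate(sets):
        cols = [idx_of[p] for p in cset.pairs]
        counts[i] = int(np.all(passes[:, cols], axis=1).sum())
        is_true[i] = cset.is_true_set
    if not is_true.any():
        raise ValueError(
            "true between-regime set is not among the enumerated sets "
            "(k differs from the number of between-regime pairs)"
        )
    true_count = counts[is_true][0]
    empirical_p = float((counts >= true_count).sum() / len(sets))
    return CombinatorialNull(
        counts=counts, is_true=is_true, empirical_p=empirical_p, sets=sets
    )


def assign_snps_to_genes(
    candidates: pd.DataFrame, genes: list[GeneModel]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map candidate SNPs onto (flank-extended) gene spans.

    A SNP is assigned to every gene whose span contains its position
    (1-based inclusive bounds), so SNPs inside overlapping genes count for
    each of them.  Returns ``(gene_table, snp_table)``: per-gene assigned
    SNP counts (genes with >= 1 SNP), and the per-SNP assignment with
    intergenic SNPs marked by an empty gene list.
    """
    cand = candidates[candidates["is_candidate"]] if (
        "is_candidate" in candidates
    ) else candidates
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    starts = {
        c: np.array([g.span_start for g in gs])
        for c, gs in by_chrom.items()
    }
    ends = {
        c: np.array([g.span_end for g in gs]) for c, gs in by_chrom.items()
    }
    snp_rows = []
    gene_hits: dict[str, int] = {}
    for chrom, pos in zip(cand["chrom"], cand["pos"]):
        hits: list[str] = []
        gs = by_chrom.get(chrom)
        if gs is not None:
            inside = (starts[chrom] <= pos) & (pos <= ends[chrom])
            hits = [gs[i].gene_id for i in np.flatnonzero(inside)]
        for gid in hits:
            gene_hits[gid] = gene_hits.get(gid, 0) + 1
        snp_rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "genes": ",".join(hits),
                "intergenic": not hits,
            }
        )
    snp_table = pd.DataFrame(
        snp_rows, columns=["chrom", "pos", "genes", "intergenic"]
    )
    gene_table = pd.DataFrame(
        sorted(gene_hits.items()), columns=["gene_id", "n_snps"]
    )
    return gene_table, snp_table
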