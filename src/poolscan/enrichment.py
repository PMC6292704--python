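"""Functional structure in candidate genes.

Two tests live here:

* an exact multi-set intersection test — the probability that m gene sets
  of fixed sizes, each drawn independently and uniformly from a common
  background of n genes, share at least k members.  For m = 2 this is the
  classical hypergeometric overlap test; for m > 2 the intersection size
  follows a Markov chain (the overlap of the next set with the current
  intersection is hypergeometric), which gives the exact distribution by
  iterated conditioning.

* a permutation GO enrichment test in the style of Gowinda: the null
  resamples candidate-set-sized SNP draws (not gene draws), so gene
  length / SNP density bias is inherited by the null distribution.  Each
  gene counts once per draw no matter how many of its SNPs are sampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneModel
from .calling import assign_snps_to_genes


@dataclass(frozen=True)
class IntersectionProblem:
    """Background size n, set sizes n_1..n_m, observed intersection k."""

    background: int
    set_sizes: tuple[int, ...]
    observed: int

    def __post_init__(self) -> None:
        if self.background < 1:
            raise ValueError("background size must be >= 1")
        if not self.set_sizes:
            raise ValueError("need at least one set")
        if any(s < 0 or s > self.background for s in self.set_sizes):
            raise ValueError("set sizes must lie in [0, background]")
        if not 0 <= self.observed <= min(self.set_sizes):
            raise ValueError(
                "observed intersection must lie in [0, min(set sizes)]"
            )


def multiset_intersection_distribution(
    background: int, set_sizes: tuple[int, ...] | list[int]
) -> np.ndarray:
    """Exact pmf of the m-set intersection size under uniform draws.

    Entry j is P(|S_1 ∩ ... ∩ S_m| = j) for j = 0..min(set sizes).
    Computed by chaining hypergeometric transitions: conditional on the
    running intersection having size a, its overlap with the next set of
    size n_t is Hypergeom(n, a, n_t).
    """
    sizes = list(set_sizes)
    if not sizes:
        raise ValueError("need at least one set")
    kmax = min(sizes)
    # running intersection size can be as large as the first set
    dist = np.zeros(sizes[0] + 1)
    dist[sizes[0]] = 1.0  # a set intersects itself fully
    support = np.arange(sizes[0] + 1)
    for n_t in sizes[1:]:
        new = np.zeros_like(dist)
        for a in np.flatnonzero(dist > 0):
            # overlap of a uniform size-n_t set with a fixed size-a set
            trans = hypergeom.pmf(support, background, a, n_t)
            new += dist[a] * np.where(np.isfinite(trans), trans, 0.0)
        dist = new
    return dist[: kmax + 1]


def multiset_intersection_pvalue(problem: IntersectionProblem) -> float:
    """P(intersection size >= observed) for the uniform-draw null.

    Reduces exactly to the hypergeometric survival function for m = 2.
    """
    if len(problem.set_sizes) == 2:
        n1, n2 = problem.set_sizes
        return float(
            hypergeom.sf(problem.observed - 1, problem.background, n1, n2)
        )
    dist = multiset_intersection_distribution(
        problem.background, problem.set_sizes
    )
    return float(dist[problem.observed :].sum())


def intersection_table(
    background: int, named_sets: dict[str, set[str]]
) -> pd.DataFrame:
    """Exact P-values for every intersection of two or more named sets.

    Mirrors the output style of multi-set overlap tools: one row per
    combination of sets, with the observed overlap and its tail
    probability against the uniform-draw null over *background* genes.
    """
    import itertools

    names = list(named_sets)
    rows = []
    for r in range(2, len(names) + 1):
        for combo in itertools.combinations(names, r):
            sets = [named_sets[c] for c in combo]
            observed = len(set.intersection(*sets))
            problem = IntersectionProblem(
                background, tuple(len(s) for s in sets), observed
            )
            rows.append(
                {
                    "sets": "&".join(combo),
                    "degree": r,
                    "observed": observed,
                    "expected": background
                    * np.prod([len(s) / background for s in sets]),
                    "p_value": multiset_intersection_pvalue(problem),
                }
            )
    return pd.DataFrame(rows)


def go_permutation_test(
    candidate_snps: np.ndarray,
    n_snps: int,
    snp_genes: list[list[str]],
    annotation: dict[str, set[str]],
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """SNP-resampling GO enrichment (Gowinda-style).

    Parameters
    ----------
    candidate_snps : int array
        Indices (into the full SNP list) of the candidate SNPs.
    n_snps : int
        Total number of tested SNPs; permutations draw candidate-sized
        SNP subsets uniformly without replacement from ``range(n_snps)``.
    snp_genes : list of list of str
        For each SNP, the gene ids it falls in (possibly several for
        overlapping genes, empty if intergenic).
    annotation : dict gene_id -> set of GO term ids
        Genes absent from the SNP-covered background are dropped (their
        number is reported in the ``n_dropped_genes`` DataFrame attr).
    n_perm : int
        Number of permutations (>= 100).
    seed : int or Generator
        RNG seed or stream.

    Returns a per-term table with the observed candidate gene count, the
    +1-corrected empirical P ``(1 + #{perm >= obs}) / (1 + n_perm)`` and
    Benjamini-Hochberg FDR across terms.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    candidate_snps = np.asarray(candidate_snps, dtype=np.int64)
    if candidate_snps.size and (
        candidate_snps.min() < 0 or candidate_snps.max() >= n_snps
    ):
        raise ValueError("candidate SNP indices outside range(n_snps)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    background = {g for gs in snp_genes for g in gs}
    dropped = [g for g in annotation if g not in background]
    ann = {g: t for g, t in annotation.items() if g in background}

    genes = sorted(background)
    gene_idx = {g: i for i, g in enumerate(genes)}
    terms = sorted({t for ts in ann.values() for t in ts})
    term_idx = {t: i for i, t in enumerate(terms)}
    # flat (gene, term) incidence for fast per-permutation counting
    gt_gene: list[int] = []
    gt_term: list[int] = []
    for g, ts in ann.items():
        for t in ts:
            gt_gene.append(gene_idx[g])
            gt_term.append(term_idx[t])
    gt_gene_a = np.array(gt_gene, dtype=np.int64)
    gt_term_a = np.array(gt_term, dtype=np.int64)
    # flat (snp, gene) incidence
    sg_snp: list[int] = []
    sg_gene: list[int] = []
    for s, gs in enumerate(snp_genes):
        for g in gs:
            sg_snp.append(s)
            sg_gene.append(gene_idx[g])
    sg_snp_a = np.array(sg_snp, dtype=np.int64)
    sg_gene_a = np.array(sg_gene, dtype=np.int64)

    def term_counts(snp_mask: np.ndarray) -> np.ndarray:
        gene_hit = np.zeros(len(genes), dtype=bool)
        gene_hit[sg_gene_a[snp_mask[sg_snp_a]]] = True
        return np.bincount(
            gt_term_a[gene_hit[gt_gene_a]], minlength=len(terms)
        )

    obs_mask = np.zeros(n_snps, dtype=bool)
    obs_mask[candidate_snps] = True
    observed = term_counts(obs_mask)

    n_cand = candidate_snps.size
    exceed = np.zeros(len(terms), dtype=np.int64)
    for _ in range(n_perm):
        draw = rng.choice(n_snps, size=n_cand, replace=False)
        mask = np.zeros(n_snps, dtype=bool)
        mask[draw] = True
        exceed += term_counts(mask) >= observed
    p_emp = (1.0 + exceed) / (1.0 + n_perm)
    fdr = (
        multipletests(p_emp, method="fdr_bh")[1]
        if len(terms)
        else np.array([])
    )
    term_bg = np.bincount(gt_term_a, minlength=len(terms)) if terms else []
    out = pd.DataFrame(
        {
            "term": terms,
            "n_background_genes": term_bg,
            "observed_genes": observed,
            "p_empirical": p_emp,
            "fdr_bh": fdr,
        }
    )
    out.attrs["n_dropped_genes"] = len(dropped)
    out.attrs["n_perm"] = n_perm
    return out


def go_test_from_candidates(
    candidates: pd.DataFrame,
    genes: list[GeneModel],
    annotation: dict[str, set[str]],
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Convenience wrapper: candidate calls + gene models -> GO table."""
    all_snps = candidates[["chrom", "pos"]].copy()
    all_snps["is_candidate"] = False  # assign every tested SNP
    _, snp_table = assign_snps_to_genes(all_snps.drop(columns="is_candidate"), genes)
    snp_genes = [
        g.split(",") if g else [] for g in snp_table["genes"]
    ]
    cand_idx = np.flatnonzero(candidates["is_candidate"].to_numpy())
    return go_permutation_test(
        cand_idx,
        len(candidates),
        snp_genes,
        annotation,
        n_perm=n_perm,
        seed=seed,
    )
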