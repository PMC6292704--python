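"""Per-SNP pairwise differentiation statistics.

For every unordered pair of pools the scan computes a per-SNP F_ST from
sample heterozygosities and a two-sided Fisher's exact test on the 2x2
major/minor read-count table, Bonferroni-corrected over the whole test
family.  A per-SNP signal-to-noise ratio (SNR) contrasts the mean F_ST of
the between-regime pairs against the mean F_ST of the within-regime pairs
on a log2 scale:

    SNR = log2((1 + mean F_ST between) / (1 + mean F_ST within))

so SNR = 1 when the regimes are fully differentiated (F_ST = 1) with no
differentiation within regimes, SNR = 0 when between- and within-regime
differentiation are equal, and SNR < 0 when lines differ more within
regimes than between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import PoolDesign
from .io import BiallelicTable


def fst_pair(c1_major, c1_minor, c2_major, c2_minor, correct: bool = False):
    """Per-SNP F_ST between two pools from major/minor read counts.

    Classical heterozygosity form: with sample frequencies
    p_i = minor/(major+minor), pi_within is the mean of 2*p_i*(1-p_i) and
    pi_total = 2*pbar*(1-pbar) at pbar = (p_1+p_2)/2; F_ST =
    (pi_total - pi_within)/pi_total, defined as 0 when pi_total = 0 and
    clamped to [0, 1].  Accepts scalars or arrays; sites where either pool
    has zero coverage yield NaN (undefined).

    With ``correct=True`` both heterozygosities get the small-sample
    factor n/(n-1) at n = the pool's read depth, an optional variant for
    low coverage; the default matches common Pool-seq practice.
    """
    c1_major = np.asarray(c1_major, dtype=float)
    c1_minor = np.asarray(c1_minor, dtype=float)
    c2_major = np.asarray(c2_major, dtype=float)
    c2_minor = np.asarray(c2_minor, dtype=float)
    n1 = c1_major + c1_minor
    n2 = c2_major + c2_minor
    defined = (n1 > 0) & (n2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(n1 > 0, c1_minor / np.where(n1 > 0, n1, 1), np.nan)
        p2 = np.where(n2 > 0, c2_minor / np.where(n2 > 0, n2, 1), np.nan)
        h1 = 2.0 * p1 * (1.0 - p1)
        h2 = 2.0 * p2 * (1.0 - p2)
        if correct:
            h1 = h1 * np.where(n1 > 1, n1 / (n1 - 1.0), np.nan)
            h2 = h2 * np.where(n2 > 1, n2 / (n2 - 1.0), np.nan)
        pi_within = 0.5 * (h1 + h2)
        pbar = 0.5 * (p1 + p2)
        pi_total = 2.0 * pbar * (1.0 - pbar)
        if correct:
            ntot = n1 + n2
            pi_total = pi_total * np.where(
                ntot > 1, ntot / (ntot - 1.0), np.nan
            )
        fst = np.where(
            pi_total > 0, (pi_total - pi_within) / np.where(
                pi_total > 0, pi_total, 1.0
            ), 0.0
        )
    fst = np.clip(fst, 0.0, 1.0)
    fst = np.where(defined, fst, np.nan)
    if fst.ndim == 0:
        return float(fst)
    return fst


def fisher_pair(c1_major, c1_minor, c2_major, c2_minor) -> float:
    """Two-sided Fisher's exact P for one 2x2 major/minor count table.

    Uses the minimum-likelihood convention (the P-value sums the
    hypergeometric probabilities of all tables no more probable than the
    observed one).  An all-zero table returns 1 by convention.
    """
    table = np.array(
        [[c1_major, c1_minor], [c2_major, c2_minor]], dtype=np.int64
    )
    if np.any(table < 0):
        raise ValueError("negative counts")
    if table.sum() == 0:
        return 1.0
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def fisher_many(c1_major, c1_minor, c2_major, c2_minor) -> np.ndarray:
    """Vector of two-sided Fisher P-values, memoising repeated tables."""
    c1_major = np.asarray(c1_major, dtype=np.int64)
    c1_minor = np.asarray(c1_minor, dtype=np.int64)
    c2_major = np.asarray(c2_major, dtype=np.int64)
    c2_minor = np.asarray(c2_minor, dtype=np.int64)
    out = np.empty(c1_major.shape, dtype=float)
    if out.size == 0:
        return out
    cache: dict[tuple[int, int, int, int], float] = {}
    it = np.nditer(
        [c1_major, c1_minor, c2_major, c2_minor], flags=["multi_index"]
    )
    for a, b, c, d in it:
        key = (int(a), int(b), int(c), int(d))
        p = cache.get(key)
        if p is None:
            p = fisher_pair(*key)
            cache[key] = p
        out[it.multi_index] = p
    return out


def bonferroni(p, m: int):
    """Bonferroni adjustment: min(1, p*m) for a family of m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)


def snr(mean_between, mean_within):
    """Signal-to-noise ratio log2((1 + Fbar_between)/(1 + Fbar_within)).

    Bounded in [-1, 1] for means in [0, 1]; monotone increasing in the
    between-regime mean and decreasing in the within-regime mean.
    """
    mb = np.asarray(mean_between, dtype=float)
    mw = np.asarray(mean_within, dtype=float)
    if np.any((mb < 0) | (mb > 1) | (mw < 0) | (mw > 1)):
        raise ValueError("mean F_ST values must be within [0, 1]")
    out = np.log2((1.0 + mb) / (1.0 + mw))
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class PairwiseStats:
    """All pairwise per-SNP statistics for one biallelic table.

    Attributes
    ----------
    sites : BiallelicTable
        The SNPs the statistics refer to.
    pairs : list of (int, int)
        Unordered line-index pairs, in :meth:`PoolDesign.all_pairs` order.
    fst : ndarray (n_sites, n_pairs)
        Per-SNP pairwise F_ST (NaN where undefined).
    fisher_p : ndarray (n_sites, n_pairs)
        Raw two-sided Fisher P-values.
    bonferroni_m : int
        Test-family size used for the Bonferroni adjustment: number of
        SNPs times the number of between-regime pairs (every performed
        selection-vs-control test counts).
    """

    design: PoolDesign
    sites: BiallelicTable
    pairs: list[tuple[int, int]]
    fst: np.ndarray
    fisher_p: np.ndarray
    bonferroni_m: int

    def pair_index(self, pair: tuple[int, int]) -> int:
        try:
            return self.pairs.index(tuple(sorted(pair)))
        except ValueError:
            raise KeyError(f"pair {pair} not in stats") from None

    @property
    def p_adjusted(self) -> np.ndarray:
        return bonferroni(self.fisher_p, self.bonferroni_m)

    def mean_fst(self, pairs: list[tuple[int, int]]) -> np.ndarray:
        idx = [self.pair_index(p) for p in pairs]
        return self.fst[:, idx].mean(axis=1)

    def snr(self) -> np.ndarray:
        """Per-SNP SNR over the design's between/within pair partition."""
        mb = self.mean_fst(self.design.between_pairs())
        mw = self.mean_fst(self.design.within_pairs())
        out = np.full(len(mb), np.nan)
        ok = ~(np.isnan(mb) | np.isnan(mw))
        out[ok] = snr(mb[ok], mw[ok])
        return out


def pairwise_stats(
    sites: BiallelicTable,
    design: PoolDesign,
    pairs: list[tuple[int, int]] | None = None,
    correct_fst: bool = False,
) -> PairwiseStats:
    """Compute F_ST and Fisher P for every pair over all SNPs.

    The Bonferroni family size is n_sites x n_between_pairs regardless of
    which pairs are evaluated, so candidate criteria stay identical when
    the combinatorial null swaps comparison sets in and out.
    """
    if sites.n_pools != design.n_lines:
        raise ValueError(
            f"table has {sites.n_pools} pools but design has "
            f"{design.n_lines} lines"
        )
    if pairs is None:
        pairs = design.all_pairs()
    n_sites = sites.n_sites
    n_pairs = len(pairs)
    fst = np.empty((n_sites, n_pairs))
    fisher = np.empty((n_sites, n_pairs))
    for k, (i, j) in enumerate(pairs):
        fst[:, k] = fst_pair(
            sites.major_counts[:, i],
            sites.minor_counts[:, i],
            sites.major_counts[:, j],
            sites.minor_counts[:, j],
            correct=correct_fst,
        )
        fisher[:, k] = fisher_many(
            sites.major_counts[:, i],
            sites.minor_counts[:, i],
            sites.major_counts[:, j],
            sites.minor_counts[:, j],
        )
    m = max(1, n_sites * len(design.between_pairs()))
    return PairwiseStats(
        design=design,
        sites=sites,
        pairs=[tuple(p) for p in pairs],
        fst=fst,
        fisher_p=fisher,
        bonferroni_m=m,
    )


def stats_frame(stats: PairwiseStats) -> pd.DataFrame:
    """Flatten pairwise statistics into one tidy row per SNP."""
    sites = stats.sites
    data: dict[str, object] = {
        "chrom": sites.chrom,
        "pos": sites.pos,
        "major": sites.major,
        "minor": sites.minor,
    }
    p_adj = stats.p_adjusted
    for k, pair in enumerate(stats.pairs):
        label = stats.design.pair_label(pair)
        data[f"fst_{label}"] = stats.fst[:, k]
        data[f"p_{label}"] = stats.fisher_p[:, k]
        data[f"padj_{label}"] = p_adj[:, k]
    mb = stats.mean_fst(stats.design.between_pairs())
    mw = stats.mean_fst(stats.design.within_pairs())
    data["mean_fst_between"] = mb
    data["mean_fst_within"] = mw
    data["snr"] = stats.snr()
    return pd.DataFrame(data)
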