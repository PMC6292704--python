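"""Model/results interface tying the scan together.

:class:`PoolFstScan` is built from Pool-seq count data plus a design and,
on :meth:`~PoolFstScan.fit`, runs the full per-SNP differentiation scan:
biallelic reduction, all pairwise F_ST and Fisher tests, the
signal-to-noise ratio and the conjunctive candidate criterion.  The
returned :class:`ScanResults` carries the per-SNP statistics and exposes
the downstream analyses — the combinatorial null over comparison sets,
gene annotation and GO enrichment — plus a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as pio
from .calling import (
    CombinatorialNull,
    assign_snps_to_genes,
    call_candidates,
    combinatorial_null,
    true_comparison_set,
)
from .design import PoolDesign, default_design
from .enrichment import go_test_from_candidates
from .io import AlleleCountTable, BiallelicTable, GeneModel
from .stats import PairwiseStats, pairwise_stats, stats_frame


class PoolFstScan:
    """Pairwise F_ST outlier scan over a multi-line Pool-seq experiment.

    Parameters
    ----------
    counts : AlleleCountTable
        Raw six-class counts per site and pool.
    design : PoolDesign, optional
        Line labels/regimes/pool sizes; defaults to the 2-control x
        4-selection design.
    min_cov, min_minor_count : int
        Biallelic-reduction filters: minimum per-pool coverage and
        minimum summed minor-allele count.
    correct_fst : bool
        Apply the small-sample n/(n-1) heterozygosity correction.
    """

    def __init__(
        self,
        counts: AlleleCountTable,
        design: PoolDesign | None = None,
        min_cov: int = 10,
        min_minor_count: int = 4,
        correct_fst: bool = False,
    ) -> None:
        self.design = design if design is not None else default_design()
        if counts.n_pools != self.design.n_lines:
            raise ValueError(
                f"count table has {counts.n_pools} pools, design has "
                f"{self.design.n_lines} lines"
            )
        self.counts = counts
        self.min_cov = min_cov
        self.min_minor_count = min_minor_count
        self.correct_fst = correct_fst

    @classmethod
    def from_sync(
        cls, path, design: PoolDesign | None = None, **kwargs
    ) -> "PoolFstScan":
        """Build the model straight from a sync file."""
        d = design if design is not None else default_design()
        return cls(pio.read_sync(path, d), design=d, **kwargs)

    def fit(
        self, fst_threshold: float = 0.9, alpha: float = 1e-9
    ) -> "ScanResults":
        """Run the scan and return results.

        ``fst_threshold`` and ``alpha`` are the (strict) candidate
        cutoffs: F_ST above the threshold and Bonferroni-adjusted Fisher
        P below alpha in every between-regime pair.
        """
        sites = pio.reduce_to_biallelic(
            self.counts, self.min_cov, self.min_minor_count
        )
        stats = pairwise_stats(
            sites, self.design, correct_fst=self.correct_fst
        )
        return ScanResults(self, stats, fst_threshold, alpha)


class ScanResults:
    """Fitted scan: per-SNP pairwise statistics and candidate calls."""

    def __init__(
        self,
        model: PoolFstScan,
        stats: PairwiseStats,
        fst_threshold: float,
        alpha: float,
    ) -> None:
        self.model = model
        self.design = model.design
        self.pairwise = stats
        self.fst_threshold = fst_threshold
        self.alpha = alpha
        self.calls = call_candidates(
            stats, None, fst_threshold=fst_threshold, alpha=alpha
        )

    # -- per-SNP tables -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.pairwise.sites.n_sites

    @property
    def is_candidate(self) -> np.ndarray:
        return self.calls["is_candidate"].to_numpy()

    @property
    def n_candidates(self) -> int:
        return int(self.is_candidate.sum())

    @property
    def snr(self) -> np.ndarray:
        return self.pairwise.snr()

    def stats_table(self) -> pd.DataFrame:
        """Tidy per-SNP table: all pairwise F_ST/P, SNR, candidate flag."""
        frame = stats_frame(self.pairwise)
        frame["is_candidate"] = self.is_candidate
        return frame

    # -- downstream analyses --------------------------------------------
    def combinatorial_null(self, k: int | None = None) -> CombinatorialNull:
        """All-subsets null over comparison sets at this fit's cutoffs."""
        return combinatorial_null(
            self.pairwise,
            fst_threshold=self.fst_threshold,
            alpha=self.alpha,
            k=k,
        )

    def assign_to_genes(self, genes: list[GeneModel]):
        """Candidate SNP -> gene assignment over extended gene spans."""
        return assign_snps_to_genes(self.calls, genes)

    def go_enrichment(
        self,
        genes: list[GeneModel],
        annotation: dict[str, set[str]],
        n_perm: int = 10_000,
        seed: int = 0,
    ) -> pd.DataFrame:
        return go_test_from_candidates(
            self.calls, genes, annotation, n_perm=n_perm, seed=seed
        )

    # -- output ----------------------------------------------------------
    def to_tsv(self, path) -> None:
        pio.write_stats_tsv(self.stats_table(), path)

    def to_bed(self, path) -> None:
        mask = self.is_candidate
        snr = self.snr
        pio.write_candidates_bed(
            self.pairwise.sites.chrom[mask],
            self.pairwise.sites.pos[mask],
            np.nan_to_num(snr[mask]),
            path,
        )

    def summary(self) -> str:
        """Human-readable summary of the fitted scan."""
        from statsmodels.iolib.table import SimpleTable

        snr = self.snr
        snr_ok = snr[~np.isnan(snr)]
        frac_le0 = (
            float((snr_ok <= 0).mean()) if snr_ok.size else float("nan")
        )
        rows = [
            ("Lines", str(self.design.n_lines)),
            ("Between-regime pairs", str(len(self.design.between_pairs()))),
            ("Within-regime pairs", str(len(self.design.within_pairs()))),
            ("SNPs after filtering", str(self.n_sites)),
            ("F_ST threshold", f"> {self.fst_threshold:g}"),
            ("Adjusted-P threshold", f"< {self.alpha:g}"),
            ("Bonferroni family size", str(self.pairwise.bonferroni_m)),
            ("Candidate SNPs", str(self.n_candidates)),
            ("Median SNR", f"{np.median(snr_ok):.4f}" if snr_ok.size else "nan"),
            ("Fraction SNR <= 0", f"{frac_le0:.3f}"),
        ]
        table = SimpleTable(
            rows, headers=["", ""], title="Pool-seq F_ST outlier scan"
        )
        return table.as_text()

    def plot_snr(self, ax=None, bins: int = 60):
        """Histogram of the per-SNP SNR (candidates overlaid in red)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        snr = self.snr
        ok = ~np.isnan(snr)
        ax.hist(snr[ok], bins=bins, color="0.6", label="all SNPs")
        mask = self.is_candidate & ok
        if mask.any():
            ax.hist(snr[mask], bins=bins, color="crimson", label="candidates")
        ax.set_xlabel("log2 F_ST signal-to-noise ratio")
        ax.set_ylabel("SNPs")
        ax.legend()
        return ax
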