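"""Synthetic evolve-and-resequence (E&R) data with known ground truth.

The generator emulates the study design the scan expects: six replicate
lines (two control, four selection) descended from one outbred base
population, evolved independently under Wright-Fisher drift for G
generations, with directional selection of coefficient s acting at
designated causal loci in the selection lines only.  Each line is then
"sequenced" as a pool: pool_size chromosomes are binomially sampled from
the population frequency, and reads are binomially sampled from the pool
at Poisson-distributed depth (the classical Pool-seq double-sampling
model).  Loci are unlinked (independent trajectories).

Output is a sync-format count table plus a truth table recording each
locus's causal status, selection coefficient, ancestral frequency and
final per-line population frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import PoolDesign, SELECTION, default_design
from .io import AlleleCountTable

CHROM_ARMS = ("X", "2L", "2R", "3L", "3R")
_ARM_LENGTH = 25_000_000  # positions drawn uniformly within each arm


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic E&R experiment.

    Attributes
    ----------
    n_loci : int
        Total number of simulated SNPs (neutral + causal).
    n_causal : int
        Number of loci under directional selection in the selection lines.
    N : int
        Diploid census size of every line (2N gene copies resampled per
        generation).
    G : int
        Generations of evolution after the split from the base population.
        The experiment being emulated ran for >= 144 generations; the
        default here is a scaled-down 100 so that a full scan stays cheap.
    s : float
        Selection coefficient of the favoured allele at causal loci
        (fitnesses 1+s, 1+h*s, 1), applied in selection lines only.
    h : float
        Dominance of the favoured allele (0.5 = genic selection).
    base_freq_beta : (float, float)
        Shape parameters of the Beta distribution of ancestral minor/major
        frequencies, truncated to ``base_freq_range``.  The default
        Beta(0.5, 0.5) gives the U-shaped spectrum typical of standing
        variation.
    base_freq_range : (float, float)
        Truncation interval for ancestral frequencies.
    causal_start_freq : float
        Ancestral frequency of the favoured allele at causal loci.  The
        default 0.05 is the conventional low starting frequency of a
        beneficial variant segregating in the base population.
    pool_size : int
        Chromosomes sampled into each pool.
    mean_coverage : float
        Poisson mean of per-site read depth per pool.
    error_rate : float
        Optional symmetric sequencing error: each read flips allele with
        this probability.  Off (0.0) by default so sampling oracles are
        exact.
    seed : int
        Seed of the generator's RNG stream.
    """

    n_loci: int = 10_000
    n_causal: int = 50
    N: int = 500
    G: int = 100
    s: float = 0.5
    h: float = 0.5
    base_freq_beta: tuple[float, float] = (0.5, 0.5)
    base_freq_range: tuple[float, float] = (0.05, 0.95)
    causal_start_freq: float = 0.05
    pool_size: int = 200
    mean_coverage: float = 80.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_causal <= self.n_loci:
            raise ValueError("need 0 <= n_causal <= n_loci")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.G < 0:
            raise ValueError("G must be >= 0")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be > 0")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        lo, hi = self.base_freq_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("base_freq_range must be within [0, 1]")
        if not 0 <= self.causal_start_freq <= 1:
            raise ValueError("causal_start_freq must be in [0, 1]")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")


def simulate_base_population(
    config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the ancestral state: positions, frequencies, causal labels.

    Frequencies are i.i.d. draws from the truncated Beta; loci are placed
    on the five chromosome arms at uniformly random positions and sorted.
    The first ``n_causal`` loci (after sorting) are flagged causal and
    their favoured-allele frequency is reset to ``causal_start_freq``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_loci
    lo, hi = config.base_freq_range
    a, b = config.base_freq_beta
    freq = np.empty(n)
    filled = 0
    while filled < n:  # rejection sampling of the truncated Beta
        draw = rng.beta(a, b, size=max(n - filled, 16))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        freq[filled : filled + take] = ok[:take]
        filled += take
    chrom = rng.choice(CHROM_ARMS, size=n)
    pos = rng.integers(1, _ARM_LENGTH + 1, size=n)
    base = pd.DataFrame({"chrom": chrom, "pos": pos, "freq": freq})
    base.sort_values(["chrom", "pos"], inplace=True, kind="stable")
    base.drop_duplicates(["chrom", "pos"], inplace=True)
    base.reset_index(drop=True, inplace=True)
    is_causal = np.zeros(len(base), dtype=bool)
    if config.n_causal:
        causal_idx = rng.choice(
            len(base), size=config.n_causal, replace=False
        )
        is_causal[causal_idx] = True
        base.loc[is_causal, "freq"] = config.causal_start_freq
    base["is_causal"] = is_causal
    base["s"] = np.where(is_causal, config.s, 0.0)
    return base


def wright_fisher_trajectory(
    p0,
    N: int,
    G: int,
    s: float = 0.0,
    h: float = 0.5,
    regime: str = SELECTION,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Evolve allele frequencies for G generations of Wright-Fisher.

    Per generation: the deterministic selection update with fitnesses
    1+s (AA), 1+h*s (Aa), 1 (aa) — applied only when ``regime ==
    "selection"`` — followed by binomial resampling of 2N gene copies.
    Frequencies 0 and 1 are absorbing.  Accepts a scalar or vector ``p0``
    (``s`` may be a matching vector) and returns the final frequencies.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    p = np.atleast_1d(np.asarray(p0, dtype=float)).copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p0 must be within [0, 1]")
    s_arr = np.broadcast_to(np.asarray(s, dtype=float), p.shape).copy()
    if regime != SELECTION:
        s_arr = np.zeros_like(p)
    two_n = 2 * N
    for _ in range(G):
        q = 1.0 - p
        w_bar = (
            p * p * (1.0 + s_arr)
            + 2.0 * p * q * (1.0 + h * s_arr)
            + q * q
        )
        p_sel = (p * p * (1.0 + s_arr) + p * q * (1.0 + h * s_arr)) / w_bar
        p = rng.binomial(two_n, p_sel) / two_n
    out = np.asarray(p)
    return out if np.ndim(p0) else float(out[0])


def sample_pool_reads(
    pop_freq,
    pool_size: int,
    coverage_mean: float,
    rng: np.random.Generator | None = None,
    error_rate: float = 0.0,
):
    """Pool-seq double sampling: population -> pool -> reads.

    The pool frequency is Binomial(pool_size, pop_freq)/pool_size; read
    depth is Poisson(coverage_mean); focal-allele reads are
    Binomial(depth, pool frequency).  With a nonzero ``error_rate`` each
    read flips allele with that probability.  Returns (other_count,
    focal_count) arrays — counts of the non-focal and focal allele.
    """
    if rng is None:
        rng = np.random.default_rng()
    p = np.atleast_1d(np.asarray(pop_freq, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("pop_freq must be within [0, 1]")
    q = rng.binomial(pool_size, p) / pool_size
    depth = rng.poisson(coverage_mean, size=p.shape)
    if error_rate:
        q = q * (1.0 - error_rate) + (1.0 - q) * error_rate
    focal = rng.binomial(depth, q)
    other = depth - focal
    if np.ndim(pop_freq) == 0:
        return int(other[0]), int(focal[0])
    return other, focal


_ALLELE_COL = {"A": 0, "T": 1, "C": 2, "G": 3}


def simulate_experiment(
    config: SimConfig, design: PoolDesign | None = None
) -> tuple[AlleleCountTable, pd.DataFrame]:
    """Run the full six-line E&R simulation.

    Returns the sync-style count table (pools ordered as in *design*,
    default C1, C2, S1..S4) and the truth table with per-locus causal
    status, s, ancestral frequency and final per-line population
    frequencies.  Fully deterministic under a fixed config seed.
    """
    if design is None:
        design = default_design(pool_size=config.pool_size)
    rng = np.random.default_rng(config.seed)
    base = simulate_base_population(config, rng)
    n = len(base)
    p0 = base["freq"].to_numpy()
    s_vec = base["s"].to_numpy()

    final = np.empty((design.n_lines, n))
    for k in range(design.n_lines):
        final[k] = wright_fisher_trajectory(
            p0,
            config.N,
            config.G,
            s=s_vec,
            h=config.h,
            regime=design.regimes[k],
            rng=rng,
        )

    # The tracked ("focal") allele is A, the alternative T; the reference
    # base is reported as T (the allele at frequency 1 - p in the base).
    counts = np.zeros((n, design.n_lines, 6), dtype=np.int64)
    for k in range(design.n_lines):
        other, focal = sample_pool_reads(
            final[k],
            design.pool_sizes[k],
            config.mean_coverage,
            rng=rng,
            error_rate=config.error_rate,
        )
        counts[:, k, _ALLELE_COL["A"]] = focal
        counts[:, k, _ALLELE_COL["T"]] = other

    table = AlleleCountTable(
        base["chrom"].to_numpy(),
        base["pos"].to_numpy(),
        np.array(["T"] * n, dtype=object),
        counts,
    )
    truth = base[["chrom", "pos", "is_causal", "s"]].copy()
    truth.rename(columns={"freq": "ancestral_freq"}, inplace=True)
    truth["ancestral_freq"] = p0
    for k, line in enumerate(design.line_ids):
        truth[f"final_freq_{line}"] = final[k]
    return table, truth
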