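# Methods

## Data model and coordinates

The pipeline's universal input is a sync-format count table: per genomic
position and per pool, the six read-count classes A, T, C, G, N, del.
Sync and GFF3 coordinates are 1-based inclusive; BED output is 0-based
half-open (a SNP at position p becomes the interval [p−1, p)). A pool's
coverage at a site is the sum of its six classes. Tables are sorted by
(chromosome, position) on load and duplicate positions are rejected.

Sites are reduced to biallelic form before any statistic is computed:
the two alleles with the highest summed counts across all pools are
kept (ties broken alphabetically, which makes triallelic reduction
deterministic), N/del and third/fourth-allele reads are discarded, and a
site survives only if every pool's coverage is at least `min_cov`
(default 10) and the summed minor count is at least `min_minor_count`
(default 4). These defaults follow common Pool-seq filtering practice
and are plain configuration — both filters only ever shrink the site
list, never reorder statistics.

## Differentiation statistics

**F_ST.** Per SNP and pool pair, the classical heterozygosity estimator:
with sample minor-allele frequencies p₁, p₂ from read counts,
π_within = mean of 2pᵢ(1−pᵢ), π_total = 2p̄(1−p̄) at p̄ = (p₁+p₂)/2, and
F_ST = (π_total − π_within)/π_total, set to 0 when π_total = 0 and
clamped to [0, 1]. A pair with zero coverage in either pool is undefined
(NaN) and disqualifies the SNP from candidacy. An optional variant
multiplies the heterozygosities by n/(n−1) at read depth n for
small-sample bias; it is off by default because the plain form is the
common per-SNP Pool-seq default and the two agree closely at the
coverages this scan targets.

**Fisher's exact test.** Two-sided P on the 2×2 major/minor table by the
minimum-likelihood convention (sum of hypergeometric probabilities no
larger than the observed table's), delegated to
`scipy.stats.fisher_exact` and verified in the test suite against
exhaustive enumeration over the hypergeometric support for every table
with total count ≤ 60. The all-zero table is defined as P = 1.

**Multiple testing.** Bonferroni with family size m = (number of tested
SNPs) × (number of between-regime pairs) — the most conservative reading
of correcting every performed selection-vs-control test. The family size
is held fixed when the combinatorial null evaluates alternative
comparison sets, so all 6435 sets face identical criteria.

**Signal-to-noise ratio.** SNR = log2((1 + F̄_b)/(1 + F̄_w)) with F̄_b,
F̄_w the per-SNP mean F_ST over the 8 between-regime and 7 within-regime
pairs. This is the simplest log2 contrast that satisfies the three
anchor properties the ratio is meant to have: exactly 1 at complete
fixation between regimes with no within-regime differentiation, exactly
0 at equal differentiation, strictly monotone in both arguments (hence
negative when within-regime drift exceeds the regime contrast), and
bounded in [−1, 1].

## Candidate calling and the combinatorial null

A SNP is a candidate iff F_ST > 0.9 **and** Bonferroni-adjusted
P < 10⁻⁹ in **every** between-regime pair. Both comparisons are strict:
a SNP at exactly the threshold is not a candidate. The criterion is
monotone — raising the F_ST threshold or lowering alpha can only remove
candidates.

Significance of the candidate count uses a combinatorial null: the
identical criterion is applied to all C(15, 8) = 6435 eight-pair subsets
of the 15 line pairs (not only those spanning both regimes), and the
empirical P is the fraction of sets — observed set included in numerator
and denominator, the standard permutation convention — whose candidate
count is at least the true set's. Its floor is therefore
1/6435 ≈ 1.554 × 10⁻⁴, attained when the true set is the strict maximum.

Candidate SNPs are assigned to genes defined as the UTR-to-UTR span
(falling back to the gene feature's bounds when no UTRs are annotated)
extended by 1 kb on both sides, clamped at position 1. Flanks are
symmetric regardless of strand — the definition is strand-blind and
assignment to the conservative superset is intended. A SNP inside
overlapping spans counts for every such gene; a gene is a candidate gene
once it has ≥ 1 assigned SNP.

## Enrichment tests

**GO permutation test.** The null resamples SNPs, not genes: each of
`n_perm` permutations draws |candidates| SNPs uniformly without
replacement from all tested SNPs, maps them to genes, and counts
distinct genes per GO term, so the gene length / SNP density bias of the
observed candidate set is built into the null (the core idea of the
Gowinda approach). Empirical P uses the +1 correction,
(1 + #{perm ≥ obs})/(1 + n_perm), so it is never zero; FDR across terms
is Benjamini–Hochberg (chosen over a resampling FDR for simplicity and
well-definedness). Annotated genes not covered by any tested SNP are
dropped from the background and their count reported.

**Multi-set intersection test.** For m gene sets of sizes n₁..n_m drawn
independently and uniformly from a background of n genes, the
intersection size follows a Markov chain: conditional on the running
intersection having size a, its overlap with the next set is
Hypergeometric(n, a, n_t). Iterating this conditioning gives the exact
distribution for any m; the reported P is the upper tail at the observed
overlap. For m = 2 the chain collapses to the classical hypergeometric
overlap test (verified exactly in the tests); for m ≥ 3 it is checked
against brute-force enumeration (tiny backgrounds) and Monte-Carlo
simulation. Transitions use `scipy.stats.hypergeom` pmfs, which are
computed from log-gammas internally, so no explicit log-space
convolution is needed at realistic gene-universe sizes. The background
size is an explicit input — the test is only as meaningful as the
universe it conditions on.

## The synthetic experiment generator

The simulator emulates the study design the scan assumes: six lines (two
control, four selection) split from one outbred base population, evolved
independently for G generations of Wright–Fisher resampling (binomial
sampling of 2N gene copies), with directional selection (fitnesses 1+s,
1+hs, 1; defaults s = 0.5, h = 0.5) applied at designated causal loci in
selection lines only. Sequencing is the classical Pool-seq double
sampling: pool frequency ~ Binomial(pool_size, population frequency)/
pool_size, read depth ~ Poisson(mean_coverage), minor reads ~
Binomial(depth, pool frequency); an optional symmetric error rate is off
by default so the sampling oracles stay exact.

Defaults: N = 500 diploids per line, G = 100 generations (a scaled-down
stand-in for the ≥ 144-generation experiments this design emulates, kept
at 100 so a full scan stays cheap), pools of 200 chromosomes at 80×
mean coverage. Ancestral frequencies are i.i.d. Beta(0.5, 0.5) truncated
to [0.05, 0.95] — a U-shaped spectrum typical of standing variation with
the sub-5% tail excluded, since such sites are unreliable in Pool-seq
and are removed by the minor-count filter anyway. Causal loci start the
favoured allele at 0.05, the conventional low starting frequency of a
beneficial variant in E&R power analyses. Loci are unlinked (independent
trajectories); linkage, hitchhiking, inversions, migration and
sequencing error are deliberately not modelled, so passing tests show
the statistics behave correctly under drift + selection + double
sampling, not that real fly data are free of linked-selection artefacts.

All randomness flows through one `numpy` Generator seeded from the
config, so a fixed config is byte-identical across runs, including the
emitted sync file.

### What recovery the defaults imply

With selection lines fixed for the favoured allele and a control line
still near the 0.05 ancestral frequency, the pairwise F_ST is
1 − 2c/(1+c) at control frequency c, i.e. ≈ 0.905 — just above the 0.9
candidate threshold. Candidacy therefore requires both control pools'
sampled minor frequency to fall below 1/19 ≈ 0.053, and the double
sampling noise (sd ≈ 0.03 at 80×) puts each control near a coin flip
unless drift has carried it lower. The scan consequently recovers
roughly 40% of causal loci under the default conditions while keeping
the neutral false-positive rate at ~0 and the true comparison set the
strict maximum of the combinatorial null; the acceptance script reports
the measured rates. Recovery is a steep function of the causal starting
frequency, which is a property of the biology being emulated, not a
tuning knob of the scan.

## Numerical and design notes

- Strict inequalities at both candidate cutoffs; ties at a threshold are
  conservative (not called).
- Biallelic tie-breaks, set enumeration order and permutation draws are
  all deterministic under a fixed seed; `--threads` never affects
  results.
- Empty inputs are valid everywhere: an empty sync file flows through
  scan/null/annotate to header-only outputs with exit code 0.
- Bonferroni family size uses the post-filter SNP count; SNPs removed by
  the coverage/minor-count filters are not tests.
- The scan's per-SNP tables are plain pandas DataFrames; TSV round-trips
  preserve values to better than 10⁻¹² relative.

## Problem sizes used in the test suite

Unit and property tests run on hundreds-to-thousands of simulated loci;
the end-to-end recovery experiment uses 10,050 loci (50 causal) at full
design scale, and oracle-equivalence checks enumerate all 2×2 tables
with total ≤ 60 and 10⁵-draw Monte-Carlo references. These sizes keep a
full run to a few minutes on one CPU while leaving Monte-Carlo standard
errors well inside the asserted tolerances.
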