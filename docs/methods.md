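# Methods

This document records the statistical model behind each `gmspop` component,
all tunable parameters with their defaults and units, the scope and limits of
the synthetic-data generator, and the numerical and design decisions that are
not obvious from the code.

## Genotype model and file formats

Genotypes are diploid counts of a designated allele 1: `0`, `1`, `2`, with
`9` for missing. A dataset is an `n_samples × n_snps` int8 matrix plus a
sample table (`sample_id`, `sex`, `population`) and a SNP table (`snp_id`,
`chrom`, `pos_cm`, `pos_bp`, `allele1`, `allele2`). SNPs are stored sorted
by chromosome then physical position; chromosome labels sort numerically
when they are integers ("2" before "10") and lexically otherwise.

**EIGENSTRAT** (`.geno/.snp/.ind`) stores the count of the `.snp` file's
first allele, so round trips are exact.

**PLINK text** (`.ped/.map`) stores two allele letters per genotype and
carries no allele-order information. On read, allele 1 of a SNP is defined
as the first allele of the first heterozygous sample at that SNP, falling
back to the first allele encountered; an absent second allele is recorded as
the placeholder `0`. A PLINK round trip therefore preserves the data only
up to per-SNP allele orientation. `equals_up_to_orientation` compares two
datasets under this equivalence: per SNP, the allele pair must match
directly (same calls) or swapped (calls recoded `g → 2−g`); a `0`
placeholder is resolved through the shared concrete allele; datasets with
irreconcilable allele pairs are unequal.

**Merging** joins two datasets on `(chrom, pos_bp)`. At each shared site the
second dataset's alleles are oriented to the first's: identical pairs pass
through, reversed pairs are recoded `2−g`, and strand flips are resolved by
base complement. A∕T and C∕G pairs complement to themselves, so they never
reach the flip path and are either matched directly or — when the allele
sets genuinely differ, e.g. (A,C) vs (A,G) — dropped as irreconcilable.
Sites absent from either dataset are dropped (intersection merge).

## Quality control (`QcConfig` defaults)

| Parameter | Default | Meaning |
|---|---|---|
| `max_sample_missing` | 0.05 | remove samples with > 5% missing calls |
| `max_locus_missing_per_pop` | 0.05 | remove SNPs with > 5% missing calls in any population |
| `min_maf` | 3.3e-4 | remove SNPs below this pooled minor-allele frequency (removes monomorphic sites at typical sample sizes) |
| `hwe_alpha` | 5e-5 | remove SNPs failing the Hardy–Weinberg exact test in any population |
| `hwe_min_pop_size` | 20 | HWE is only tested in populations with at least this many genotyped samples (the exact test has no power below that) |
| `kinship_first_degree_min` | 2^−2.5 ≈ 0.177 | KING kinship above which a pair counts as first-degree |
| `prune_window` / `prune_step` / `prune_r2` | 200 / 25 / 0.4 | LD pruning: windows of 200 variants advanced by 25, removing one of each pair with r² > 0.4 |

The HWE test is the standard exact (permutation-free) test on genotype
counts, computed with log-gamma factorials for overflow safety; it is
validated against an integer-factorial enumeration oracle.

Kinship uses the KING-robust within-family estimator
`φ̂ = (N_het,het − 2·N_opposite-hom) / (N_het,i + N_het,j)` over loci
non-missing in both samples, computed within populations only. Duplicate
samples give exactly φ̂ = 0.5; first-degree pairs fall in (0.177, 0.354].
Removal is greedy: while any first-degree pair remains, remove the sample
with the most first-degree partners, ties broken by higher missing rate,
then by sample id — this keeps the maximum number of unrelated samples in
the common star-shaped cases (one parent linked to several children).

Each filter is idempotent: applied to its own output it removes nothing.

## f-statistics

Per-population allele-1 frequencies `p̂` come with observed allele counts
`n` (2 × non-missing samples). All estimators average per-SNP products over
the SNPs where every involved population has data.

- **Outgroup f3**: `f3(X, Y; O) = mean[(o − x)(o − y) − o(1−o)/(n_O − 1)]`.
  The subtracted term removes the bias from sampling noise at the outgroup
  apex; it vanishes as `n_O → ∞`.
- **f4**: `f4(W, X; Y, O) = mean[(w − x)(y − o)]`, antisymmetric in each
  pair, zero in expectation under treeness of `(W,X)|(Y,O)`.
- **Standard errors** use the weighted block jackknife (Busing et al. 1999)
  with blocks that never span chromosomes; the default scheme cuts each
  chromosome into 5 Mb bins on physical position (`fixed_cm` and
  `fixed_snp_count` schemes are available). Block weights are the per-block
  SNP counts; with equal blocks the estimator reduces exactly to the classic
  delete-one jackknife. No shrinkage or small-block correction beyond the
  Busing weighting is applied: at genome scale (hundreds of blocks) the
  weighted jackknife is already well calibrated (validated: mean SE within
  1.1× the empirical SD over replicate simulations), and any further
  adjustment would be another tuning knob to justify.
- **NJ tree**: distances `d(X, Y) = 1 − f3(X, Y; O)` feed standard
  neighbor joining (Q-criterion). Negative branch lengths arising from
  sampling noise are clamped to zero. Bipartitions are canonicalized to the
  smaller leaf side (for an even split, the side containing the
  lexicographically smallest leaf), making topology comparison unambiguous.

## Selection scan

Per-SNP Hudson FST: `1 − (h1 + h2)/D`, `h_i = p̂_i(1−p̂_i) n_i/(n_i−1)`,
`D = p̂1(1−p̂2) + p̂2(1−p̂1)`; undefined (NaN) when both populations are
fixed for the same allele. Weir–Cockerham FST is provided for sensitivity
analysis; the two agree in the large-sample limit.

PBS for (target A, ingroup B, outgroup C):
`PBS_A = (T_AB + T_AC − T_BC)/2` with `T = −ln(1 − FST)`. FST values are
clamped to `[0, 1 − 1e−9]` before the log: negative per-SNP FST estimates
are sampling noise around zero, and the upper clamp keeps `T` finite at
fixed differences. The three rotations of a triple sum to
`(T_AB + T_AC + T_BC)/2` exactly.

Outliers are the top `q` quantile by rank: `k = ceil(q · m_defined)` SNPs,
with boundary ties all included, never fewer than one. The two-comparison
design runs the scan twice (regional vs. neighbor, regional vs. ancient
reference); `region_specific` is the set difference of outlier sets,
isolating signals not shared with the older comparison.

## IBD summary

Segments (9-column tab format: ids, haplotype indices, chromosome, bp span,
LOD, length in cM) are binned by genetic length — default bins (1, 5] and
(5, ∞) cM, left-open so a 5.0 cM segment falls in the short bin — and
summarized per population pair as mean total sharing: the sum of segment
lengths divided by the number of sample pairs (n_A·n_B across populations,
n·(n−1)/2 within). Pairs with no segments contribute zeros to the
denominator, so bin totals are additive across any re-binning.

## PCA and projection

PCA is fit on reference samples only: calls are mean-centered and scaled by
`sqrt(p̄(1−p̄))` per SNP (frequencies from the reference), missing reference
calls mean-imputed, then SVD. A non-reference sample is placed by least
squares over its non-missing loci: coordinates `c` minimize
`‖x_obs − L_obs c‖²` where `L` holds the loadings. A complete reference
sample reprojects onto its own coordinates to machine precision; projection
error grows monotonically with the fraction of masked loci.

## Synthetic-data generator: scope and limits

The generator draws root allele frequencies uniformly on
`[maf_low, maf_high]` (defaults 0.05–0.95) and evolves each tree branch with
a Balding–Nichols Beta step: child frequency
`~ Beta(p(1−F)/F, (1−p)(1−F)/F)` with per-branch drift `F ∈ [0, 1)`
(`F = 0` copies the parent). Admixture edges replace a node's frequency by
`α·source + (1−α)·parent` between contemporaneous nodes. Leaves emit diploid
genotypes binomially; missing calls are masked uniformly at random at
`missing_rate`. SNPs are laid out on `n_chromosomes` (default 22) at fixed
spacing (default 20 kb).

**Directional selection shift.** A locus selected on branch `b` with shift
`δ` has its post-drift frequency moved by `δ` away from the nearer fixation
boundary: `p + δ` if `p ≤ 0.5`, else `p − δ`, clipped to `[0.01, 0.99]`.
The direction rule makes "shifted by δ" mean the frequency actually moves
by δ wherever the unit interval allows; a clamp-only shift would silently
attenuate δ near the boundaries (a root frequency of 0.93 would yield an
effective shift of 0.06 under clamping).

Limits: sites are exchangeable and unlinked given the tree (no LD is
simulated — LD-pruning tests use hand-constructed correlated columns), there
is no mutation model or ascertainment scheme, drift is frequency-independent
within a branch, and selection is a one-step deterministic shift rather than
a trajectory. These are deliberate: each omitted mechanism would add
parameters without sharpening any property the test suite checks.

**Named fixtures** (problem sizes are this package's own benchmark choices):

- `four_pop_clade`: ((W,X),Y),O with per-branch F defaults 0.02–0.04; the
  null configuration for f4 calibration.
- `admixed_target`: the same clade plus a 30% admixture edge C→X; the
  expected positive-z arrangement is `f4(X, W; C, O)` (gene flow C→X makes
  `E[f4(W, X; C, O)] = −α·Var(drift_C) < 0`, so the detection statistic uses
  the reversed first pair).
- `six_pop_ladder`: a caterpillar tree for NJ topology recovery.
- `selection_scan`: target/ingroup siblings with pairwise differentiation
  FST ≈ 0.02 between them (F = 0.01 per branch — the differentiation
  between closely related populations is conventionally reported as the
  pairwise FST, and that is the reading under which top-quantile recovery of
  δ = 0.35 shifts is a robust property rather than a seed-dependent one),
  an outgroup at roughly double that, 100k SNPs, 50 shifted loci, 50
  samples per population.
- `tiny_qc`: a hand-constructed 12-sample × 30-SNP dataset with exactly one
  violation of each QC rule (one high-missingness sample, one monomorphic
  SNP, one per-population-missingness failure, one HWE failure, one
  duplicate pair, one perfect-LD pair) and a manifest of exact survivor
  counts. Background columns are drawn from HWE-safe genotype multisets and
  re-checked with independent numpy computations so that no *unintended*
  column pair exceeds the pruning r² or kinship thresholds; the fixture's
  config prunes at r² > 0.95 because at ten samples chance correlations
  routinely exceed the production 0.4 cutoff, and the fixture's purpose is
  to isolate the pruning rule, not to emulate genome-scale LD.

## Pipeline

`run_pipeline` executes merge → QC → LD prune → f3/NJ → f4 → PCA → PBS →
IBD from a single `RunConfig` (YAML-loadable). Every artifact has a
deterministic name; `run_manifest.json` records per-stage input/output
SHA-256 checksums, sample/SNP counts, parameters and wall-clock times. A
stage is skipped when its input checksums, parameters and outputs all match
the previous manifest. Reruns are byte-identical apart from the manifest's
timing fields. LD pruning feeds only PCA: pruning before a selection scan
would thin the outlier tail the scan ranks, and f-statistics are
block-jackknifed, which already accounts for LD-scale autocorrelation.
The NJ stage requires at least three f3 populations and is skipped (not an
error) below that.

## Numerical choices

- HWE exact probabilities via `scipy.special.gammaln`, normalized in log
  space before exponentiation.
- FST/PBS and f-statistics in float64 throughout; genotypes held as int8.
- Jackknife with `n_blocks` weights normalized per statistic over the blocks
  that contain usable SNPs; empty blocks are dropped rather than
  zero-weighted.
- Deterministic RNG: every stochastic routine takes an explicit seed and
  uses `numpy.random.default_rng`; identical seeds give identical outputs
  across runs and platforms supported by NumPy's stream guarantees.
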