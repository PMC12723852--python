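# gmspop

Genome-wide SNP population-genetics toolkit: genotype I/O and merging,
quality control, f-statistics with block-jackknife errors, PBS selection
scans, IBD sharing summaries, PCA with projection of held-out samples, a
Balding–Nichols simulator, and an end-to-end reproducible pipeline.

## Scientific problem

Population-history studies of closely related human groups routinely ask
three questions from genome-wide SNP genotypes:

1. **Structure and relatedness** — how do populations cluster, and which
   pairs share recent ancestry? Answered here with outgroup-f3 statistics,
   f3-derived neighbor-joining trees, PCA with least-squares projection of
   low-coverage samples, and identity-by-descent (IBD) segment sharing.
2. **Admixture** — did gene flow occur between two lineages after their
   split? Answered with the f4 statistic: `f4(W, X; Y, O)` has expectation
   zero when `(W, X)` and `(Y, O)` are clades, and a block-jackknife Z-score
   `|z| > 3` rejects treeness.
3. **Local adaptation** — which loci were driven to unusual frequency on one
   branch? Answered with the population branch statistic
   `PBS = (T_AB + T_AC − T_BC)/2`, `T = −ln(1 − FST)`, ranked genome-wide
   and called at a top quantile, with a two-comparison design
   (`region_specific`) to separate regional from older shared signals.

All estimators operate on diploid 0/1/2 genotype calls with missing data,
and every genome-wide statistic carries a weighted block-jackknife standard
error so that chromosomes-scale autocorrelation does not understate
uncertainty.

## Model and notation

- Genotypes are counts of allele 1 (`0/1/2`, `9` = missing) in an
  `n_samples × n_snps` matrix with sample and SNP metadata
  (EIGENSTRAT `.geno/.snp/.ind` and PLINK text `.ped/.map` are supported).
- Per-population allele frequencies `p̂` and observed allele counts `n`
  (twice the non-missing sample count) feed all estimators.
- Hudson FST per SNP: `1 − (h1 + h2)/D` with within-population
  heterozygosities `h_i = p_i(1−p_i) n_i/(n_i−1)` and between-population
  diversity `D = p1(1−p2) + p2(1−p1)`.
- Outgroup f3: `f3(X, Y; O) = E[(o − x)(o − y)]` with a finite-sample apex
  correction `o(1−o)/(n_O − 1)`; `1 − f3` distances feed neighbor joining.
- f4: `f4(W, X; Y, O) = E[(w − x)(y − o)]`.
- The simulator draws root frequencies uniformly and evolves each branch by
  a Balding–Nichols Beta step with per-branch drift `F`
  (`Var = F · p(1−p)`), supports admixture edges and directional selection
  shifts, and samples diploid genotypes binomially.

See `docs/methods.md` for derivations, parameter defaults, and design
decisions.

## Running the tests

```sh
python -m pytest -q tests/                 # full suite (~2.5 min)
python -m pytest -q tests/test_acceptance.py   # the 12 acceptance criteria
```

## Worked example

Simulate three populations (two close neighbors plus an outgroup) with ten
loci shifted by δ = 0.35 on the `Regional` branch, run QC, estimate an
outgroup-f3, and scan for selection:

```sh
cat > tree.yaml <<'YAML'
parents:
  root: null
  anc: root
  Regional: anc
  Neighbor: anc
  Outgroup: root
drift:
  anc: 0.01
  Regional: 0.01
  Neighbor: 0.01
  Outgroup: 0.02
leaf_sizes:
  Regional: 50
  Neighbor: 50
  Outgroup: 50
YAML

cat > sim.yaml <<'YAML'
n_snps: 20000
seed: 7
missing_rate: 0.01
selected_loci:
  - [Regional, 10, 0.35]
YAML

gmspop simulate --tree tree.yaml --config sim.yaml --out demo
gmspop qc demo demo_clean --report qc_report.tsv
printf "Regional\nNeighbor\n" > pops.txt
gmspop f3 demo_clean --target-list pops.txt --outgroup Outgroup
gmspop pbs demo_clean --target Regional --ingroup Neighbor \
    --outgroup Outgroup --top-q 0.001 --out pbs.tsv
```

Output (seed 7 is deterministic; you will see these exact numbers):

```text
150 samples x 20000 SNPs; truth: demo.truth.tsv
samples 150->150, snps 20000->19200
kind	pops	estimate	se	z	n_blocks	n_snps
f3_outgroup	Regional,Neighbor,Outgroup	0.0053894442	9.1351757e-05	58.9966	88	19200
20 outliers, threshold 0.17829
```

All ten planted loci are among the 20 top-0.1% PBS outliers
(`demo.truth.tsv` lists them; compare against the `outlier_flag` column of
`pbs.tsv`).

The same analyses run as a single reproducible pipeline from YAML:

```sh
gmspop run pipeline.yaml     # merge -> QC -> prune -> f3/f4/NJ/PCA/PBS/IBD
```

Re-running with unchanged inputs skips completed stages (checksum-based) and
reproduces byte-identical outputs; `run_manifest.json` records per-stage
checksums, counts, parameters and timings.

## Package layout

| Module | Contents |
|---|---|
| `gmspop.genotype_io` | EIGENSTRAT / PLINK-text read/write, orientation-aware comparison, dataset merging |
| `gmspop.quality_control` | missingness/MAF/HWE filters, KING-robust kinship, first-degree removal, LD pruning |
| `gmspop.fstats` | allele frequencies, outgroup-f3, f4, weighted block jackknife, 1−f3 NJ tree |
| `gmspop.selection_scan` | Hudson & Weir–Cockerham FST, PBS, outlier calling, two-comparison set algebra, annotation |
| `gmspop.ibd_summary` | IBD segment parsing and per-population-pair length-binned sharing |
| `gmspop.pca_project` | PCA on reference samples, least-squares projection with missing data |
| `gmspop.synthetic_data` | Balding–Nichols tree simulator, named fixtures, tiny hand-constructed QC dataset |
| `gmspop.pipeline` | YAML-configured end-to-end runs with manifests and stage skipping |
| `gmspop.cli` | `gmspop` command-line interface over all of the above |
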