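"""Synthetic genotype data under Balding-Nichols drift with admixture.

Generates diploid biallelic genotype matrices whose statistical structure
matches what the analysis stack assumes: an ancestral allele frequency per SNP
drifts down a population tree (child frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F)
per branch with drift parameter F), admixture edges blend a source node's
frequency into a destination lineage, branch-specific selection shifts the
frequencies of marked loci by delta away from the nearer fixation boundary
(p + delta if p <= 0.5, else p - delta, clipped to [0.01, 0.99]), leaf
genotypes are Binomial(2, p) draws, and calls
are masked missing-at-random. Every statistic in the pipeline (FST, f3, f4,
PBS, PCA structure) is a functional of population allele frequencies, so
frequency-level simulation gives exact ground truth; no linkage is generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, write_genotypes

_ALLELES = ("A", "G")  # fixed biallelic coding for simulated SNPs


@dataclass
class PopTree:
    """Rooted population tree with per-branch drift and admixture edges.

    ``parents`` maps each node to its parent (root maps to None); ``drift``
    gives the Balding-Nichols F of the branch above each non-root node;
    ``leaf_sizes`` assigns diploid sample counts to leaves; each admixture
    edge ``(source, dest, alpha)`` replaces dest's inherited frequency with
    ``alpha * p_source + (1 - alpha) * p_parent(dest)`` before dest's own
    branch drift is applied.
    """

    parents: dict[str, str | None]
    drift: dict[str, float] = field(default_factory=dict)
    leaf_sizes: dict[str, int] = field(default_factory=dict)
    admixture_edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parents.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        for node, parent in self.parents.items():
            if parent is not None and parent not in self.parents:
                raise ValueError(f"parent {parent!r} of {node!r} is not a node")
        for node, f in self.drift.items():
            if not 0 <= f < 1:
                raise ValueError(f"drift F for {node!r} must be in [0, 1)")
        order = self.topological_order()
        if len(order) != len(self.parents):
            raise ValueError("tree contains a cycle")
        for src, dest, alpha in self.admixture_edges:
            if not 0 < alpha < 1:
                raise ValueError("admixture alpha must be in (0, 1)")
            if src in self.ancestors(dest) or dest in self.ancestors(src) \
                    or src == dest:
                raise ValueError(
                    f"admixture edge {src}->{dest} connects non-contemporaneous nodes"
                )
        for leaf, size in self.leaf_sizes.items():
            if self.children(leaf):
                raise ValueError(f"{leaf!r} has children; sample sizes go on leaves")
            if size < 1:
                raise ValueError(f"leaf {leaf!r} needs a positive sample size")

    @property
    def root(self) -> str:
        return next(n for n, p in self.parents.items() if p is None)

    def children(self, node: str) -> list[str]:
        return [n for n, p in self.parents.items() if p == node]

    def ancestors(self, node: str) -> set[str]:
        out = set()
        p = self.parents[node]
        while p is not None:
            out.add(p)
            p = self.parents[p]
        return out

    def leaves(self) -> list[str]:
        return [n for n in self.parents if not self.children(n)]

    def topological_order(self) -> list[str]:
        order = [self.root]
        seen = {self.root}
        frontier = [self.root]
        while frontier:
            nxt = []
            for node in frontier:
                for child in self.children(node):
                    if child not in seen:
                        order.append(child)
                        seen.add(child)
                        nxt.append(child)
            frontier = nxt
        return order


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset."""

    n_snps: int = 20_000
    maf_low: float = 0.05
    maf_high: float = 0.95
    selected_loci: list = field(default_factory=list)  # (branch, count, delta)
    missing_rate: float = 0.0
    seed: int = 0
    n_chromosomes: int = 22
    snp_spacing_bp: int = 20_000

    def __post_init__(self) -> None:
        total_selected = sum(c for _, c, _ in self.selected_loci)
        if total_selected > self.n_snps:
            raise ValueError("more selected loci than SNPs")
        for _, _, delta in self.selected_loci:
            if not 0 < delta < 1:
                raise ValueError("selection shift delta must be in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SimTruth:
    """Generator-side ground truth for parameter-recovery tests."""

    tree: PopTree
    node_freqs: dict[str, np.ndarray]
    selected: dict[str, dict]  # snp_id -> {"branch": node, "delta": float}
    seed: int


def _drift(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """One Balding-Nichols drift step: Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    if F == 0:
        return p.copy()
    p = np.clip(p, 1e-6, 1 - 1e-6)
    scale = (1 - F) / F
    return rng.beta(p * scale, (1 - p) * scale)


def simulate(config: SimConfig, tree: PopTree) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate a genotype matrix and its ground truth from one seed."""
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    snp_ids = np.array([f"snp{j:07d}" for j in range(m)])

    # assign selected loci to random disjoint columns, per branch
    selected: dict[str, dict] = {}
    shift_node: dict[str, np.ndarray] = {}
    total_selected = sum(c for _, c, _ in config.selected_loci)
    chosen = rng.choice(m, size=total_selected, replace=False)
    cursor = 0
    for branch, count, delta in config.selected_loci:
        if branch not in tree.parents:
            raise ValueError(f"selected branch {branch!r} is not a tree node")
        idx = chosen[cursor:cursor + count]
        cursor += count
        shift_node.setdefault(branch, np.zeros(m))
        shift_node[branch][idx] = delta
        for j in idx:
            selected[snp_ids[j]] = {"branch": branch, "delta": float(delta)}

    p0 = rng.uniform(config.maf_low, config.maf_high, size=m)
    node_freqs: dict[str, np.ndarray] = {tree.root: p0}
    admix_into = {dest: (src, alpha) for src, dest, alpha in tree.admixture_edges}
    for node in tree.topological_order():
        if node == tree.root:
            base = p0
        else:
            base = node_freqs[tree.parents[node]]
            if node in admix_into:
                src, alpha = admix_into[node]
                if src not in node_freqs:
                    raise ValueError(
                        f"admixture source {src!r} must precede {node!r} in "
                        "topological order"
                    )
                base = alpha * node_freqs[src] + (1 - alpha) * base
            base = _drift(rng, base, tree.drift.get(node, 0.0))
            if node in shift_node:
                # selection shifts away from the nearer fixation boundary so
                # the marked effect size is delta regardless of the starting
                # frequency (a clamp-only shift would silently attenuate
                # high-frequency loci)
                delta = shift_node[node]
                shifted = np.where(base <= 0.5, base + delta, base - delta)
                base = np.where(delta > 0,
                                np.clip(shifted, 0.01, 0.99), base)
        node_freqs[node] = base

    # leaf genotypes
    leaves = [leaf for leaf in tree.leaves() if leaf in tree.leaf_sizes]
    sample_rows = []
    blocks = []
    for leaf in leaves:
        n = tree.leaf_sizes[leaf]
        g = rng.binomial(2, node_freqs[leaf], size=(n, m)).astype(np.int8)
        blocks.append(g)
        sample_rows += [
            {"sample_id": f"{leaf}_{i:03d}", "population": leaf} for i in range(n)
        ]
    calls = np.vstack(blocks) if blocks else np.empty((0, m), dtype=np.int8)
    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = MISSING

    per_chrom = -(-m // config.n_chromosomes)  # ceil
    chrom = np.array([str(1 + j // per_chrom) for j in range(m)])
    local = np.arange(m) % per_chrom
    pos_bp = (local + 1) * config.snp_spacing_bp
    snps = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos_cm": pos_bp / 1e6,
            "pos_bp": pos_bp,
            "allele1": _ALLELES[0],
            "allele2": _ALLELES[1],
        }
    )
    G = GenotypeMatrix(
        samples=pd.DataFrame(sample_rows, columns=["sample_id", "population"]),
        snps=snps,
        calls=calls,
    )
    truth = SimTruth(tree=tree, node_freqs=node_freqs, selected=selected,
                     seed=config.seed)
    return G, truth


# ---------------------------------------------------------------------------
# Named fixtures
# ---------------------------------------------------------------------------

def four_pop_clade_tree(
    n_per_pop: int = 25, f_internal: float = 0.02, f_leaf: float = 0.02
) -> PopTree:
    """(((W, X), Y), O): a clean clade for null f4 and cladality tests."""
    return PopTree(
        parents={
            "root": None, "anc_WXY": "root", "anc_WX": "anc_WXY",
            "W": "anc_WX", "X": "anc_WX", "Y": "anc_WXY", "O": "root",
        },
        drift={
            "anc_WXY": f_internal, "anc_WX": f_internal,
            "W": f_leaf, "X": f_leaf, "Y": f_leaf, "O": 0.1,
        },
        leaf_sizes={"W": n_per_pop, "X": n_per_pop, "Y": n_per_pop,
                    "O": n_per_pop},
    )


def admixed_target_tree(n_per_pop: int = 25, alpha: float = 0.3) -> PopTree:
    """Like the clade tree plus a gene-flow edge C -> X with proportion alpha."""
    return PopTree(
        parents={
            "root": None, "anc_WXY": "root", "anc_WX": "anc_WXY",
            "W": "anc_WX", "X": "anc_WX", "Y": "anc_WXY",
            "anc_CO": "root", "C": "anc_CO", "O": "anc_CO",
        },
        drift={
            "anc_WXY": 0.02, "anc_WX": 0.02, "W": 0.02, "X": 0.02,
            "Y": 0.02, "anc_CO": 0.05, "C": 0.02, "O": 0.05,
        },
        leaf_sizes={"W": n_per_pop, "X": n_per_pop, "Y": n_per_pop,
                    "C": n_per_pop, "O": n_per_pop},
        admixture_edges=[("C", "X", alpha)],
    )


def six_pop_ladder_tree(n_per_pop: int = 20, f: float = 0.02) -> PopTree:
    """Six populations on a ladder (caterpillar) plus an outgroup for f3.

    Induced unrooted topology among P1..P6 has internal edges {P1,P2},
    {P1,P2,P3} and {P5,P6}.
    """
    return PopTree(
        parents={
            "root": None, "O": "root", "n5": "root",
            "P6": "n5", "n4": "n5", "P5": "n4", "n3": "n4",
            "P4": "n3", "n2": "n3", "P3": "n2", "n1": "n2",
            "P1": "n1", "P2": "n1",
        },
        drift={
            "O": 0.1, "n5": f, "P6": f, "n4": f, "P5": f, "n3": f,
            "P4": f, "n2": f, "P3": f, "n1": f, "P1": f, "P2": f,
        },
        leaf_sizes={p: n_per_pop for p in ("P1", "P2", "P3", "P4", "P5", "P6", "O")},
    )


def selection_scan_tree(n_per_pop: int = 50, f: float = 0.02) -> PopTree:
    """Target/ingroup/outgroup triple for PBS power tests.

    ``f`` is the pairwise differentiation (FST scale) between target and
    ingroup, so each of their branches carries F = f/2; the outgroup sits at
    roughly pairwise 2f from both.
    """
    return PopTree(
        parents={
            "root": None, "anc_AB": "root",
            "target": "anc_AB", "ingroup": "anc_AB", "outgroup": "root",
        },
        drift={"anc_AB": f / 2, "target": f / 2, "ingroup": f / 2,
               "outgroup": f},
        leaf_sizes={"target": n_per_pop, "ingroup": n_per_pop,
                    "outgroup": n_per_pop},
    )


def fixture_config(name: str, seed: int = 0):
    """Study conditions of a named fixture: (SimConfig, PopTree, manifest).

    The manifest records the generator-side expectations downstream tests
    assert (survivor counts, expected-sign statistics, marked loci).
    """
    if name == "four_pop_clade":
        tree = four_pop_clade_tree()
        config = SimConfig(n_snps=20_000, seed=seed)
        manifest = {"expected": "abs(z) of f4(W,X;Y,O) < 3 in most replicates",
                    "quadruple": ("W", "X", "Y", "O")}
        return config, tree, manifest
    if name == "admixed_target":
        tree = admixed_target_tree(alpha=0.3)
        config = SimConfig(n_snps=50_000, seed=seed)
        # gene flow C -> X pulls x toward c, so (x - w) correlates positively
        # with (c - o): the positive-z arrangement is f4(X, W; C, O)
        manifest = {"expected": "z of f4(X,W;C,O) > 3",
                    "quadruple": ("X", "W", "C", "O"), "alpha": 0.3}
        return config, tree, manifest
    if name == "selection_scan":
        tree = selection_scan_tree(n_per_pop=50, f=0.02)
        config = SimConfig(
            n_snps=100_000, seed=seed,
            selected_loci=[("target", 50, 0.35)],
        )
        manifest = {"expected": ">=80% of marked loci in the top 1% of PBS",
                    "triple": ("target", "ingroup", "outgroup"),
                    "n_selected": 50, "delta": 0.35}
        return config, tree, manifest
    if name == "tiny_qc":
        raise ValueError("tiny_qc is constructed, not simulated; use make_tiny_qc()")
    raise ValueError(f"unknown fixture {name!r}")


# Per-population genotype multisets (6 diploid calls) whose Hardy-Weinberg
# exact p is >= 0.3 for the full set and for every 5-element subset, so base
# columns can never trip an HWE filter at alpha = 0.05 even after one sample
# is removed (verified by enumerating the conditional distribution by hand).
# Het counts sit at or below the HWE expectation so KING kinship between
# unrelated samples is not biased upward.
_HWE_SAFE_MULTISETS = (
    (0, 0, 1, 1, 1, 2),
    (0, 1, 1, 1, 2, 2),
    (0, 0, 1, 1, 2, 2),
)


def make_tiny_qc() -> tuple[GenotypeMatrix, dict]:
    """Constructed 12-sample x 30-SNP dataset with exactly one violation of
    each QC rule, plus a manifest of the exact expected survivor counts.

    Violations (under the manifest's QcConfig, hwe_alpha = 0.05 so that the
    six-sample populations are HWE-testable):

      * sample ``P1_bad``: 6 of 30 calls missing (20% > 5%) -> removed;
      * SNP ``snp_mono``: monomorphic, pooled MAF 0 < 3.3e-4 -> removed;
      * SNP ``snp_missy``: 2 of 6 calls missing within P2 -> removed;
      * SNP ``snp_hwe``: no heterozygotes in P1 (exact p < 0.05) -> removed;
      * ``P2_dup_a``/``P2_dup_b``: identical calls (kinship 0.5) -> one removed;
      * ``snp_ld_a``/``snp_ld_b``: identical columns (r^2 = 1) -> one pruned.

    Background columns are drawn from HWE-safe genotype multisets and accepted
    only if (checked with direct numpy computations, independent of the filter
    implementations) no unintended pair exceeds r^2 = 0.9 on the matrix LD
    pruning will see (the fixture's config prunes at r^2 > 0.95 -- at ten
    samples, chance correlations routinely exceed the production 0.4 cutoff,
    so the fixture isolates the pruning *rule* with a near-duplicate pair),
    and no unintended within-population pair exceeds KING kinship 0.17 on the
    matrix the kinship filter will see (the filter removes above 0.177). The construction
    is deterministic.
    """
    from .quality_control import QcConfig

    n_samples, m = 12, 30
    pops = ["P1"] * 6 + ["P2"] * 6
    ids = [f"P1_{i}" for i in range(5)] + ["P1_bad"] + \
          [f"P2_{i}" for i in range(4)] + ["P2_dup_a", "P2_dup_b"]
    j_mono, j_missy, j_hwe, j_ld_a, j_ld_b = 0, 1, 2, 3, 4
    base_cols = [j for j in range(m) if j not in (j_mono, j_missy, j_hwe, j_ld_b)]

    def build(attempt: int) -> np.ndarray | None:
        rng = np.random.default_rng([20240601, attempt])
        calls = np.zeros((n_samples, m), dtype=np.int8)
        for j in base_cols:
            for block in (slice(0, 6), slice(6, 12)):
                pattern = list(
                    _HWE_SAFE_MULTISETS[rng.integers(len(_HWE_SAFE_MULTISETS))]
                )
                rng.shuffle(pattern)
                calls[block, j] = pattern
        calls[:, j_mono] = 0
        calls[:, j_missy] = 1
        calls[6, j_missy] = MISSING
        calls[7, j_missy] = MISSING
        calls[:6, j_hwe] = [0, 0, 0, 2, 2, 2]     # homozygote excess in P1
        calls[6:, j_hwe] = [0, 1, 1, 1, 1, 2]     # P2 in equilibrium
        calls[:, j_ld_b] = calls[:, j_ld_a]       # perfect LD pair
        calls[11] = calls[10]                     # duplicate pair in P2
        calls[5, 10:16] = MISSING                 # P1_bad: 6/30 missing

        # -- acceptance checks (independent direct computations) ------------
        # kinship view: 11 samples (P1_bad gone), all within-pop pairs except
        # the intended duplicate must stay below 0.15
        keep_s = [i for i in range(n_samples) if i != 5]
        for pop_block in ([0, 1, 2, 3, 4], [6, 7, 8, 9, 10, 11]):
            for a in range(len(pop_block)):
                for b in range(a + 1, len(pop_block)):
                    i1, i2 = pop_block[a], pop_block[b]
                    if (i1, i2) == (10, 11):
                        continue
                    g1, g2 = calls[i1].astype(int), calls[i2].astype(int)
                    ok = (g1 != MISSING) & (g2 != MISSING)
                    g1, g2 = g1[ok], g2[ok]
                    hh = int(((g1 == 1) & (g2 == 1)).sum())
                    opp = int((np.abs(g1 - g2) == 2).sum())
                    denom = int((g1 == 1).sum() + (g2 == 1).sum())
                    if denom and (hh - 2 * opp) / denom > 0.17:
                        return None
        # LD view: 10 samples (P1_bad and one duplicate gone), columns that
        # survive the locus filters; only the intended pair may exceed 0.32
        keep_s = [i for i in range(n_samples) if i not in (5, 11)]
        ld_cols = [j for j in range(m) if j not in (j_mono, j_missy, j_hwe)]
        sub = calls[np.ix_(keep_s, ld_cols)].astype(float)
        for a in range(len(ld_cols)):
            for b in range(a + 1, len(ld_cols)):
                if (ld_cols[a], ld_cols[b]) == (j_ld_a, j_ld_b):
                    continue
                x, y = sub[:, a], sub[:, b]
                if x.var() == 0 or y.var() == 0:
                    continue
                r = np.corrcoef(x, y)[0, 1]
                if r * r > 0.9:
                    return None
        return calls

    calls = None
    for attempt in range(1000):
        calls = build(attempt)
        if calls is not None:
            break
    if calls is None:
        raise RuntimeError("tiny_qc construction failed")

    snp_names = ["snp_mono", "snp_missy", "snp_hwe", "snp_ld_a", "snp_ld_b"]
    snp_names += [f"snp{j:02d}" for j in range(5, m)]
    snps = pd.DataFrame(
        {
            "snp_id": snp_names,
            "chrom": "1",
            "pos_cm": np.arange(1, m + 1) * 0.02,
            "pos_bp": np.arange(1, m + 1) * 20_000,
            "allele1": "A",
            "allele2": "G",
        }
    )
    samples = pd.DataFrame({"sample_id": ids, "population": pops})
    G = GenotypeMatrix(samples=samples, snps=snps, calls=calls)

    config = QcConfig(hwe_alpha=0.05, hwe_min_pop_size=5, prune_r2=0.95)
    manifest = {
        "config": config,
        "samples_after_missingness": 11,
        "removed_sample_missingness": ["P1_bad"],
        "snps_removed_loci": {"snp_mono", "snp_missy", "snp_hwe"},
        "snps_after_loci": m - 3,
        "samples_after_kinship": 10,
        "removed_kinship_one_of": {"P2_dup_a", "P2_dup_b"},
        "pruned_one_of": {"snp_ld_a", "snp_ld_b"},
        "snps_after_prune": m - 3 - 1,
    }
    return G, manifest


def make_fixture(
    name: str, out_dir: str | Path, seed: int = 0,
    formats: tuple = ("eigenstrat", "plink_text"),
) -> tuple[dict, SimTruth | None]:
    """Write a named dataset to disk in the supported formats with a manifest.

    Returns (paths-and-manifest dict, SimTruth or None for constructed sets).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if name == "tiny_qc":
        G, manifest = make_tiny_qc()
        truth = None
    else:
        config, tree, manifest = fixture_config(name, seed=seed)
        G, truth = simulate(config, tree)
    files = {}
    for fmt in formats:
        files[fmt] = [str(p) for p in write_genotypes(G, fmt, out_dir / name)]
    info = {"name": name, "files": files, "manifest": manifest}
    if truth is not None:
        sel = pd.DataFrame(
            [{"snp_id": k, **v} for k, v in truth.selected.items()]
        )
        sel_path = out_dir / f"{name}.selected.tsv"
        if len(sel):
            sel.to_csv(sel_path, sep="\t", index=False)
            info["selected_loci_tsv"] = str(sel_path)
    return info, truth
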