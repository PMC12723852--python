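"""Allele-frequency f-statistics with block-jackknife inference.

Implements the outgroup-f3 and f4 statistics on per-population allele
frequencies, standard errors by weighted delete-one-block jackknife over
contiguous genomic blocks, the 1 - f3 genetic-distance matrix, and a
Saitou-Nei neighbor-joining tree builder with newick serialization.

For populations X, Y and an outgroup O with per-SNP allele frequencies
x, y, o, the outgroup-f3 statistic is the mean over SNPs of

    (o - x)(o - y) - h_o / n_o,      h_o = o(1 - o) n_o / (n_o - 1),

where the second term removes the upward bias contributed by finite sampling
of the apex population O. The f4 statistic for (W, X; Y, Z) is the mean of
(w - x)(y - z), which needs no such correction. Significance follows the
common |Z| > 3 convention on the jackknife Z-score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

DEFAULT_BLOCK_MB = 5.0


@dataclass
class FreqTable:
    """Per-population, per-SNP allele-1 frequencies and observed allele counts."""

    populations: list[str]
    freq: np.ndarray   # (pops, snps), NaN where no data
    n_obs: np.ndarray  # (pops, snps) observed allele count (2 x non-missing)
    snps: pd.DataFrame = field(repr=False)

    def index_of(self, pop: str) -> int:
        try:
            return self.populations.index(pop)
        except ValueError:
            raise KeyError(f"population {pop!r} not in frequency table") from None


@dataclass
class FStatResult:
    kind: str  # "f3_outgroup" or "f4"
    pops: tuple[str, ...]
    estimate: float
    se_jackknife: float
    z: float
    n_blocks: int
    n_snps_used: int


def allele_frequencies(G: GenotypeMatrix) -> FreqTable:
    """Per-population allele-1 frequency table.

    ``freq = (sum of calls) / (2 x non-missing samples)`` per population per
    SNP; ``n_obs`` is the observed allele count. Cells with no data carry
    ``n_obs = 0`` and NaN frequency.
    """
    labels = G.samples["population"].to_numpy()
    populations = list(pd.unique(labels))
    n_pops = len(populations)
    freq = np.full((n_pops, G.n_snps), np.nan)
    n_obs = np.zeros((n_pops, G.n_snps), dtype=np.int64)
    nonmiss = G.calls != MISSING
    counts = np.where(nonmiss, G.calls, 0)
    for k, pop in enumerate(populations):
        idx = labels == pop
        n_obs[k] = 2 * nonmiss[idx].sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq[k] = np.divide(
                counts[idx].sum(axis=0), n_obs[k],
                out=np.full(G.n_snps, np.nan), where=n_obs[k] > 0,
            )
    return FreqTable(populations=populations, freq=freq, n_obs=n_obs,
                     snps=G.snps.copy())


# ---------------------------------------------------------------------------
# Block assignment
# ---------------------------------------------------------------------------

def assign_blocks(
    snps: pd.DataFrame,
    scheme: str = "fixed_mb",
    block_size: float = DEFAULT_BLOCK_MB,
) -> np.ndarray:
    """Contiguous jackknife block ids per SNP; blocks never span chromosomes.

    ``fixed_mb`` cuts each chromosome into ``block_size``-megabase bins on
    physical position; ``fixed_cm`` uses genetic position; ``fixed_snp_count``
    groups runs of ``block_size`` consecutive SNPs.
    """
    block_id = np.zeros(len(snps), dtype=np.int64)
    next_id = 0
    chroms = snps["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.nonzero(chroms == chrom)[0]
        if scheme == "fixed_snp_count":
            local = np.arange(len(idx)) // int(block_size)
        elif scheme == "fixed_mb":
            pos = snps["pos_bp"].to_numpy()[idx]
            local = (pos // int(block_size * 1e6)).astype(np.int64)
        elif scheme == "fixed_cm":
            pos = snps["pos_cm"].to_numpy()[idx]
            local = (pos // block_size).astype(np.int64)
        else:
            raise ValueError(f"unknown block scheme {scheme!r}")
        # compress to consecutive ids so empty bins don't create empty blocks
        _, local = np.unique(local, return_inverse=True)
        block_id[idx] = local + next_id
        next_id = block_id[idx].max() + 1
    return block_id


# ---------------------------------------------------------------------------
# Weighted block jackknife
# ---------------------------------------------------------------------------

def block_jackknife(
    per_block_sums: np.ndarray, per_block_counts: np.ndarray
) -> tuple[float, float]:
    """Ratio-of-sums estimate with weighted delete-one-block jackknife SE.

    The estimate is (total sum)/(total count). With g blocks of sizes m_j and
    leave-one-out estimates theta_j, the weighted jackknife variance is

        sigma^2 = (1/g) * sum_j (tau_j - theta_J)^2 / (h_j - 1),

    with h_j = n/m_j, tau_j = h_j*theta - (h_j - 1)*theta_j and
    theta_J = g*theta - sum_j (1 - m_j/n) theta_j.
    """
    sums = np.asarray(per_block_sums, dtype=np.float64)
    counts = np.asarray(per_block_counts, dtype=np.float64)
    keep = counts > 0
    sums, counts = sums[keep], counts[keep]
    g = len(sums)
    if g < 2:
        raise ValueError("need at least 2 non-empty blocks")
    n = counts.sum()
    total = sums.sum()
    theta = total / n
    theta_j = (total - sums) / (n - counts)
    h = n / counts
    theta_J = g * theta - ((1 - counts / n) * theta_j).sum()
    tau = h * theta - (h - 1) * theta_j
    var = ((tau - theta_J) ** 2 / (h - 1)).sum() / g
    return float(theta), float(np.sqrt(max(var, 0.0)))


def _jackknife_result(
    kind: str,
    pops: tuple[str, ...],
    terms: np.ndarray,
    used: np.ndarray,
    block_ids: np.ndarray,
) -> FStatResult:
    ids = block_ids[used]
    t = terms[used]
    uniq, inv = np.unique(ids, return_inverse=True)
    sums = np.bincount(inv, weights=t)
    counts = np.bincount(inv).astype(float)
    if len(uniq) >= 2:
        est, se = block_jackknife(sums, counts)
    else:
        est, se = float(t.mean()), 0.0
    z = est / se if se > 0 else 0.0
    return FStatResult(kind=kind, pops=pops, estimate=est, se_jackknife=se,
                       z=z, n_blocks=len(uniq), n_snps_used=int(used.sum()))


# ---------------------------------------------------------------------------
# f3 / f4
# ---------------------------------------------------------------------------

def f3_outgroup(
    F: FreqTable,
    X: str,
    Y: str,
    O: str,
    block_ids: np.ndarray | None = None,
    apex_correction: bool = True,
) -> FStatResult:
    """Outgroup-f3(X, Y; O): shared drift of X and Y relative to outgroup O.

    Uses SNPs with data in all three populations and at least two observed
    alleles in O. The apex-sampling correction h_o/n_o is applied by default.
    """
    ix, iy, io = F.index_of(X), F.index_of(Y), F.index_of(O)
    x, y, o = F.freq[ix], F.freq[iy], F.freq[io]
    used = (F.n_obs[ix] > 0) & (F.n_obs[iy] > 0) & (F.n_obs[io] >= 2)
    if not used.any():
        raise ValueError("no usable SNPs for f3")
    terms = (o - x) * (o - y)
    if apex_correction:
        n_o = F.n_obs[io].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = terms - o * (1 - o) / (n_o - 1)
    if block_ids is None:
        block_ids = assign_blocks(F.snps)
    return _jackknife_result("f3_outgroup", (X, Y, O), terms, used, block_ids)


def f4(
    F: FreqTable,
    W: str,
    X: str,
    Y: str,
    Z: str,
    block_ids: np.ndarray | None = None,
) -> FStatResult:
    """f4(W, X; Y, Z): mean of (w - x)(y - z) over SNPs with data in all four."""
    iw, ix, iy, iz = (F.index_of(p) for p in (W, X, Y, Z))
    used = (
        (F.n_obs[iw] > 0) & (F.n_obs[ix] > 0)
        & (F.n_obs[iy] > 0) & (F.n_obs[iz] > 0)
    )
    if not used.any():
        raise ValueError("no usable SNPs for f4")
    terms = (F.freq[iw] - F.freq[ix]) * (F.freq[iy] - F.freq[iz])
    if block_ids is None:
        block_ids = assign_blocks(F.snps)
    return _jackknife_result("f4", (W, X, Y, Z), terms, used, block_ids)


# ---------------------------------------------------------------------------
# 1 - f3 distances and neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.float64)
        if self.d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        np.fill_diagonal(self.d, 0.0)


def f3_distance_matrix(
    F: FreqTable,
    pop_list: list[str],
    O: str,
    block_ids: np.ndarray | None = None,
) -> DistanceMatrix:
    """Pairwise genetic distances d(X, Y) = 1 - f3(X, Y; O)."""
    if O in pop_list:
        raise ValueError("outgroup must not be in pop_list")
    if block_ids is None:
        block_ids = assign_blocks(F.snps)
    k = len(pop_list)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            est = f3_outgroup(F, pop_list[i], pop_list[j], O, block_ids).estimate
            d[i, j] = d[j, i] = 1.0 - est
    return DistanceMatrix(labels=list(pop_list), d=d)


class TreeNode:
    """Minimal unrooted-tree node for neighbor joining."""

    __slots__ = ("name", "children", "branch_length")

    def __init__(self, name: str | None = None, branch_length: float = 0.0):
        self.name = name
        self.children: list[TreeNode] = []
        self.branch_length = branch_length

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if not node.children:
                return f"{node.name}:{node.branch_length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            name = node.name or ""
            return f"({inner}){name}:{node.branch_length:.6g}"

        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"

    def leaf_bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions, canonicalized for topology
        comparison between unrooted trees: the smaller side is kept; equal
        sizes keep the side containing the smallest leaf name."""
        all_leaves = frozenset(leaf.name for leaf in self.leaves())
        anchor = min(all_leaves)
        parts: set[frozenset] = set()

        def walk(node: TreeNode) -> frozenset:
            if not node.children:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                if len(below) < len(other):
                    parts.add(below)
                elif len(other) < len(below):
                    parts.add(other)
                else:
                    parts.add(below if anchor in below else other)
            return below

        walk(self)
        return parts


def nj_tree(D: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Negative branch lengths are clamped to zero with the deficit moved to the
    sister branch (so the pair's path length is preserved). The returned root
    is the final internal node (degree 3 for >= 3 taxa); serialize with
    ``to_newick``.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [TreeNode(name=lbl) for lbl in D.labels]
    d = D.d.astype(np.float64).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (totals[ai] - totals[aj]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, transferring the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        nodes[i].branch_length = li
        nodes[j].branch_length = lj
        parent.children = [nodes[i], nodes[j]]
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (d[i, active] + d[j, active] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        d[k, active] = new_row
        d[active, k] = new_row
        d[k, k] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [k]

    # join the last three around a single internal node (closed form)
    i, j, k = active
    root = TreeNode()
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for node, length in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.branch_length = max(length, 0.0)
        root.children.append(node)
    return root
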