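"""Sample and locus quality control, kinship filtering, and LD pruning.

The filter chain mirrors the standard array-genotyping workflow: drop samples
with excess missingness, drop loci failing missingness / minor-allele-frequency
/ Hardy-Weinberg filters, remove one member of each first-degree relative pair
(KING-robust kinship), and finally window-based LD pruning for structure
analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: Lower bound of the first-degree kinship range in the KING convention
#: (2**-2.5; duplicates/MZ twins sit near 0.5, first degree near 0.25).
FIRST_DEGREE_MIN = 2 ** -2.5


@dataclass
class QcConfig:
    """Thresholds for the QC chain.

    Defaults follow common array-QC practice: samples with > 5% missing calls
    removed; loci removed at pooled MAF < 3.3e-4, > 5% missingness within any
    population, or Hardy-Weinberg exact p < 5e-5; first-degree relatives at
    KING kinship > 2**-2.5; LD pruning at r^2 > 0.4 in 200-variant windows
    stepping by 25.
    """

    max_sample_missing: float = 0.05
    max_locus_missing_per_pop: float = 0.05
    min_maf: float = 3.3e-4
    hwe_alpha: float = 5e-5
    hwe_min_pop_size: int = 20
    kinship_first_degree_min: float = FIRST_DEGREE_MIN
    prune_window: int = 200
    prune_step: int = 25
    prune_r2: float = 0.4

    def __post_init__(self) -> None:
        for name in ("max_sample_missing", "max_locus_missing_per_pop",
                     "min_maf", "hwe_alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.prune_step > self.prune_window:
            raise ValueError("prune_step must be <= prune_window")


@dataclass
class QcReport:
    """Accounting of what each filter removed and why."""

    samples_removed: list = field(default_factory=list)  # (sample_id, reason)
    snps_removed: list = field(default_factory=list)     # (snp_id, reason)
    samples_before: int = 0
    samples_after: int = 0
    snps_before: int = 0
    snps_after: int = 0

    def check_balance(self) -> None:
        removed_samples = len({s for s, _ in self.samples_removed})
        removed_snps = len({s for s, _ in self.snps_removed})
        assert self.samples_before - removed_samples == self.samples_after
        assert self.snps_before - removed_snps == self.snps_after

    def to_frame(self) -> pd.DataFrame:
        rows = [("sample", i, r) for i, r in self.samples_removed]
        rows += [("snp", i, r) for i, r in self.snps_removed]
        return pd.DataFrame(rows, columns=["axis", "item_id", "reason"])


# ---------------------------------------------------------------------------
# Sample missingness
# ---------------------------------------------------------------------------

def filter_sample_missingness(
    G: GenotypeMatrix, max_rate: float = 0.05
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove samples whose missing-call fraction strictly exceeds ``max_rate``."""
    if not 0 <= max_rate <= 1:
        raise ValueError(f"max_rate must be in [0, 1], got {max_rate}")
    report = QcReport(samples_before=G.n_samples, snps_before=G.n_snps,
                      snps_after=G.n_snps)
    if G.n_snps == 0:
        report.samples_after = G.n_samples
        return G, report
    rates = G.missing_mask().mean(axis=1)
    keep = rates <= max_rate
    for i in np.nonzero(~keep)[0]:
        report.samples_removed.append(
            (G.samples.sample_id.iloc[i], f"missing_rate={rates[i]:.4f}>{max_rate}")
        )
    out = G.subset(sample_idx=np.nonzero(keep)[0])
    report.samples_after = out.n_samples
    report.check_balance()
    return out, report


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test on genotype counts.

    Conditions on the observed allele counts: under HWE the heterozygote count
    follows the (parity-constrained) hypergeometric-type distribution

        P(n_Aa | n, n_A) ∝ 2**n_Aa * n! / (n_AA! n_Aa! n_aa!),

    and the p-value sums the probabilities of all heterozygote counts whose
    probability does not exceed that of the observed configuration.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype observation required")
    n_A = 2 * n_AA + n_Aa  # copies of the A allele

    rare = min(n_A, 2 * n - n_A)
    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    n_aa_all = (rare - hets) // 2
    n_AA_all = n - n_aa_all - hets
    logp = (
        hets * np.log(2.0)
        - gammaln(n_AA_all + 1)
        - gammaln(hets + 1)
        - gammaln(n_aa_all + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hets == n_Aa][0]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


def _hwe_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Brute-force enumeration of the same conditional distribution.

    Independent of :func:`hwe_exact_test` (factorials via integer math);
    intended as a test oracle for small n.
    """
    import math

    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    rare = min(n_A, 2 * n - n_A)
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        aa = (rare - h) // 2
        AA = n - aa - h
        weights[h] = (
            2 ** h * math.factorial(n)
            // (math.factorial(AA) * math.factorial(h) * math.factorial(aa))
        )
    total = sum(weights.values())
    obs = weights[n_Aa]
    return sum(w for w in weights.values() if w <= obs) / total


# ---------------------------------------------------------------------------
# Locus filters
# ---------------------------------------------------------------------------

def _pop_indices(G: GenotypeMatrix) -> dict[str, np.ndarray]:
    pops: dict[str, np.ndarray] = {}
    labels = G.samples["population"].to_numpy()
    for pop in pd.unique(labels):
        pops[pop] = np.nonzero(labels == pop)[0]
    return pops


def filter_loci(G: GenotypeMatrix, config: QcConfig) -> tuple[GenotypeMatrix, QcReport]:
    """Remove loci failing MAF, per-population missingness, or HWE filters.

    A SNP is removed if its pooled minor-allele frequency is strictly below
    ``min_maf``, if its missing fraction strictly exceeds
    ``max_locus_missing_per_pop`` in any population, or if the HWE exact test
    rejects at ``hwe_alpha`` in any population with at least
    ``hwe_min_pop_size`` samples.
    """
    pops = _pop_indices(G)
    for pop, idx in pops.items():
        if len(idx) == 0:
            raise ValueError(f"population {pop!r} has no samples")

    report = QcReport(samples_before=G.n_samples, samples_after=G.n_samples,
                      snps_before=G.n_snps)
    calls = G.calls
    nonmiss = calls != MISSING

    reasons: dict[int, list[str]] = {}

    # pooled MAF
    with np.errstate(invalid="ignore"):
        n_obs = 2 * nonmiss.sum(axis=0)
        counts = np.where(nonmiss, calls, 0).sum(axis=0)
        freq = np.divide(counts, n_obs, out=np.full(G.n_snps, np.nan),
                         where=n_obs > 0)
    maf = np.minimum(freq, 1 - freq)
    for j in np.nonzero(maf < config.min_maf)[0]:
        reasons.setdefault(j, []).append(f"maf={maf[j]:.3e}<{config.min_maf}")

    # per-population missingness
    for pop, idx in pops.items():
        miss = (~nonmiss[idx]).mean(axis=0)
        for j in np.nonzero(miss > config.max_locus_missing_per_pop)[0]:
            reasons.setdefault(int(j), []).append(
                f"missing_{pop}={miss[j]:.3f}>{config.max_locus_missing_per_pop}"
            )

    # HWE within sufficiently large populations (memoized on count triples)
    hwe_cache: dict[tuple[int, int, int], float] = {}
    for pop, idx in pops.items():
        if len(idx) < config.hwe_min_pop_size:
            continue
        sub = calls[idx]
        n2 = (sub == 2).sum(axis=0)
        n1 = (sub == 1).sum(axis=0)
        n0 = (sub == 0).sum(axis=0)
        for j in range(G.n_snps):
            key = (int(n2[j]), int(n1[j]), int(n0[j]))
            if sum(key) == 0:
                continue
            p = hwe_cache.get(key)
            if p is None:
                p = hwe_cache[key] = hwe_exact_test(*key)
            if p < config.hwe_alpha:
                reasons.setdefault(j, []).append(
                    f"hwe_{pop}_p={p:.2e}<{config.hwe_alpha}"
                )

    drop = sorted(reasons)
    for j in drop:
        report.snps_removed.append((G.snps.snp_id.iloc[j], ";".join(reasons[j])))
    keep = np.setdiff1d(np.arange(G.n_snps), drop)
    out = G.subset(snp_idx=keep)
    report.snps_after = out.n_snps
    report.check_balance()
    return out, report


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

def king_kinship(gi: np.ndarray, gj: np.ndarray) -> float:
    """KING-robust between-family kinship from two diploid call vectors.

    phi-hat = (N_het,het − 2 N_opp_hom) / (N_het,i + N_het,j), over loci where
    both calls are non-missing. Duplicates give exactly 0.5; first-degree
    relatives fall near 0.25; unrelated pairs near 0.
    """
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    if gi.shape != gj.shape:
        raise ValueError("call vectors differ in length")
    ok = (gi != MISSING) & (gj != MISSING)
    if not ok.any():
        raise ValueError("no overlapping non-missing loci")
    a, b = gi[ok], gj[ok]
    het_het = int(((a == 1) & (b == 1)).sum())
    opp_hom = int((((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum())
    het_i = int((a == 1).sum())
    het_j = int((b == 1).sum())
    denom = het_i + het_j
    if denom == 0:
        raise ValueError("no heterozygous loci in either sample")
    return (het_het - 2 * opp_hom) / denom


def _king_matrix(calls: np.ndarray) -> np.ndarray:
    """All-pairs KING kinship for a (samples x snps) call block, vectorized."""
    het = (calls == 1).astype(np.float64)
    hom0 = (calls == 0).astype(np.float64)
    hom2 = (calls == 2).astype(np.float64)
    het_het = het @ het.T
    opp = hom0 @ hom2.T
    opp_hom = opp + opp.T
    n_het = het.sum(axis=1)
    denom = n_het[:, None] + n_het[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (het_het - 2 * opp_hom) / denom
    return phi


def remove_first_degree(
    G: GenotypeMatrix, threshold: float = FIRST_DEGREE_MIN
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove one member of each within-population pair with kinship > threshold.

    Greedy cover: repeatedly drop the sample involved in the most flagged
    pairs, breaking ties by higher missingness then lexicographic sample id.
    """
    report = QcReport(samples_before=G.n_samples, snps_before=G.n_snps,
                      snps_after=G.n_snps)
    flagged: list[tuple[int, int]] = []
    for _, idx in _pop_indices(G).items():
        if len(idx) < 2:
            continue
        phi = _king_matrix(G.calls[idx])
        ii, jj = np.nonzero(np.triu(phi > threshold, k=1))
        flagged.extend((int(idx[i]), int(idx[j])) for i, j in zip(ii, jj))

    miss_rate = G.missing_mask().mean(axis=1) if G.n_snps else np.zeros(G.n_samples)
    ids = G.samples["sample_id"].to_numpy()
    removed: set[int] = set()
    pairs = set(flagged)
    while pairs:
        degree: dict[int, int] = {}
        for i, j in pairs:
            degree[i] = degree.get(i, 0) + 1
            degree[j] = degree.get(j, 0) + 1
        # most flagged pairs first; ties broken by higher missingness, then by
        # lexicographically larger sample id (the smaller id is kept)
        victim = max(degree, key=lambda s: (degree[s], miss_rate[s], ids[s]))
        removed.add(victim)
        pairs = {p for p in pairs if victim not in p}

    for i in sorted(removed):
        report.samples_removed.append((ids[i], f"kinship>{threshold:.3f}"))
    keep = np.setdiff1d(np.arange(G.n_samples), sorted(removed))
    out = G.subset(sample_idx=keep)
    report.samples_after = out.n_samples
    report.check_balance()
    return out, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(calls: np.ndarray, a: int, b: int) -> float:
    """Squared Pearson correlation of two dosage columns, pairwise-complete."""
    x = calls[:, a].astype(np.float64)
    y = calls[:, b].astype(np.float64)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    x, y = x[ok], y[ok]
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return 0.0
    c = np.cov(x, y, bias=True)[0, 1]
    return float(c * c / (vx * vy))


def ld_prune(
    G: GenotypeMatrix,
    window: int = 200,
    step: int = 25,
    r2_max: float = 0.4,
) -> list[str]:
    """Windowed LD pruning; returns the ids of retained SNPs.

    Within each placement of a ``window``-variant window (advanced by ``step``
    variants), any retained pair with dosage r^2 > ``r2_max`` loses its
    lower-MAF member (ties remove the later-positioned SNP). Windows never
    span chromosomes.
    """
    if window < 2:
        raise ValueError("window must be >= 2 variants")
    calls = G.calls
    nonmiss = calls != MISSING
    with np.errstate(invalid="ignore"):
        n_obs = 2 * nonmiss.sum(axis=0)
        freq = np.divide(
            np.where(nonmiss, calls, 0).sum(axis=0), n_obs,
            out=np.full(G.n_snps, np.nan), where=n_obs > 0,
        )
    maf = np.minimum(freq, 1 - freq)

    keep = np.ones(G.n_snps, dtype=bool)
    chroms = G.snps["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        cols = np.nonzero(chroms == chrom)[0]
        m = len(cols)
        for start in range(0, max(m - 1, 1), step):
            in_window = cols[start:start + window]
            active = [c for c in in_window if keep[c]]
            changed = True
            while changed:
                changed = False
                for ai in range(len(active)):
                    for bi in range(ai + 1, len(active)):
                        a, b = active[ai], active[bi]
                        if not (keep[a] and keep[b]):
                            continue
                        r2 = _pairwise_r2(calls, a, b)
                        if r2 > r2_max:
                            if maf[a] < maf[b]:
                                victim = a
                            elif maf[b] < maf[a]:
                                victim = b
                            else:  # tie: remove the later position
                                victim = b
                            keep[victim] = False
                            changed = True
                active = [c for c in active if keep[c]]
    return G.snps.snp_id.to_numpy()[keep].tolist()


def run_qc(
    G: GenotypeMatrix, config: QcConfig | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Fixed-order QC chain: samples -> loci -> kinship (no pruning).

    Returns the filtered matrix and a combined report. LD pruning is kept
    separate because it feeds only structure analyses (PCA), not f-statistics
    or selection scans.
    """
    config = config or QcConfig()
    g1, r1 = filter_sample_missingness(G, config.max_sample_missing)
    g2, r2 = filter_loci(g1, config)
    g3, r3 = remove_first_degree(g2, config.kinship_first_degree_min)
    report = QcReport(
        samples_removed=r1.samples_removed + r3.samples_removed,
        snps_removed=r2.snps_removed,
        samples_before=G.n_samples,
        samples_after=g3.n_samples,
        snps_before=G.n_snps,
        snps_after=g3.n_snps,
    )
    report.check_balance()
    return g3, report
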