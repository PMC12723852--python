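"""Per-SNP FST, the population branch statistic (PBS), and outlier analysis.

The PBS for a target population A against an ingroup B and outgroup C is

    PBS_A = (T_AB + T_AC - T_BC) / 2,    T = -log(1 - FST),

i.e. the frequency-differentiation branch length specific to A. Per-SNP FST
uses the Hudson estimator (ratio of unbiased components) by default, with
Weir-Cockerham available for sensitivity checks. Candidate loci are the top
quantile of PBS values; a two-comparison design (an "ancient" scan against a
distant ingroup/outgroup and a "regional" scan against close ones) isolates
region-specific signals as the regional outliers not shared with the ancient
scan, and cross-population sharing is plain set intersection on SNP ids.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fstats import FreqTable, allele_frequencies
from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)

INTERGENIC_KEY = "__intergenic__"
_FST_CLAMP = 1.0 - 1e-9


def hudson_fst(p1, n1, p2, n2):
    """Hudson/Bhatia per-SNP FST from allele frequencies and allele counts.

        [(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)]
        -----------------------------------------------
                 p1(1-p2) + p2(1-p1)

    Undefined (NaN) where the denominator is zero, i.e. both populations fixed
    for the same allele. Accepts scalars or arrays; ``n1``/``n2`` are observed
    allele counts and must be >= 2.
    """
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    n1 = np.asarray(n1, dtype=np.float64)
    n2 = np.asarray(n2, dtype=np.float64)
    if (n1 < 2).any() or (n2 < 2).any():
        raise ValueError("need at least 2 observed alleles per population")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out if out.ndim else float(out)


def weir_cockerham_fst(p1, n1, p2, n2):
    """Weir-Cockerham (1984) two-population per-SNP FST from frequencies.

    Uses the allele-frequency form (no heterozygosity correction term, i.e.
    assuming HWE within populations). Provided for sensitivity checks against
    the Hudson default.
    """
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    n1 = np.asarray(n1, dtype=np.float64) / 2.0  # diploid sample sizes
    n2 = np.asarray(n2, dtype=np.float64) / 2.0
    n_bar = (n1 + n2) / 2
    n_c = (n1 + n2 - (n1 ** 2 + n2 ** 2) / (n1 + n2))  # r - 1 = 1
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / n_bar
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - s2 / 2) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - s2 / 2
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(a + b != 0, a / np.where(a + b != 0, a + b, 1.0), np.nan)
    return out if out.ndim else float(out)


def pbs(fst_ab, fst_ac, fst_bc):
    """PBS from the three pairwise FST values (scalars or arrays).

    Negative FST is floored at 0 and FST is clamped just below 1 so T stays
    finite; any undefined FST (NaN) makes the PBS undefined.
    """
    def t(f):
        f = np.asarray(f, dtype=np.float64)
        f = np.clip(f, 0.0, _FST_CLAMP)
        return -np.log1p(-f)

    fst_ab = np.asarray(fst_ab, dtype=np.float64)
    fst_ac = np.asarray(fst_ac, dtype=np.float64)
    fst_bc = np.asarray(fst_bc, dtype=np.float64)
    out = (t(fst_ab) + t(fst_ac) - t(fst_bc)) / 2.0
    out = np.where(
        np.isnan(fst_ab) | np.isnan(fst_ac) | np.isnan(fst_bc), np.nan, out
    )
    return out if out.ndim else float(out)


@dataclass
class PbsTriple:
    target: str
    ingroup: str
    outgroup: str

    def __post_init__(self) -> None:
        if len({self.target, self.ingroup, self.outgroup}) != 3:
            raise ValueError("PBS triple requires three distinct populations")


@dataclass
class PbsScan:
    """Per-SNP PBS values and the top-quantile outlier call for one triple."""

    triple: PbsTriple
    table: pd.DataFrame = field(repr=False)  # snp_id, chrom, pos_bp, fst_*, pbs
    top_q: float = 0.001
    outlier_threshold: float = float("nan")
    outliers: set = field(default_factory=set)

    @property
    def snp_universe(self) -> frozenset:
        return frozenset(self.table["snp_id"])

    def to_tsv(self, path: str | Path) -> None:
        tab = self.table.copy()
        tab["outlier_flag"] = tab["snp_id"].isin(self.outliers).astype(int)
        tab.to_csv(path, sep="\t", index=False)


def call_outliers(pbs_values: np.ndarray, snp_ids: np.ndarray,
                  top_q: float) -> tuple[set, float]:
    """Top-quantile outliers by rank: ceil(q * m_defined) SNPs, boundary ties
    all included. Returns (outlier id set, threshold PBS value)."""
    defined = ~np.isnan(pbs_values)
    vals = pbs_values[defined]
    ids = np.asarray(snp_ids)[defined]
    m = len(vals)
    if m == 0:
        return set(), float("nan")
    k = max(int(math.ceil(top_q * m)), 1)
    order = np.argsort(vals)[::-1]
    threshold = float(vals[order[min(k, m) - 1]])
    chosen = vals >= threshold
    return set(ids[chosen]), threshold


def pbs_scan(
    G: GenotypeMatrix | FreqTable,
    triple: PbsTriple,
    top_q: float = 0.001,
    estimator: str = "hudson",
) -> PbsScan:
    """Three pairwise per-SNP FSTs, PBS, and top-quantile outlier calling.

    Accepts a genotype matrix (frequencies computed per population) or a
    prebuilt :class:`FreqTable`. SNPs where any of the three FSTs is undefined
    are excluded from the ranking.
    """
    F = G if isinstance(G, FreqTable) else allele_frequencies(G)
    est = {"hudson": hudson_fst, "weir_cockerham": weir_cockerham_fst}[estimator]
    ia = F.index_of(triple.target)
    ib = F.index_of(triple.ingroup)
    ic = F.index_of(triple.outgroup)
    for name, i in (("target", ia), ("ingroup", ib), ("outgroup", ic)):
        if (F.n_obs[i] >= 4).sum() == 0:
            raise ValueError(f"{name} population has fewer than 2 samples")

    usable = (F.n_obs[ia] >= 2) & (F.n_obs[ib] >= 2) & (F.n_obs[ic] >= 2)

    def pair(i, j):
        out = np.full(F.freq.shape[1], np.nan)
        out[usable] = est(
            F.freq[i][usable], F.n_obs[i][usable],
            F.freq[j][usable], F.n_obs[j][usable],
        )
        return out

    fst_ab = pair(ia, ib)
    fst_ac = pair(ia, ic)
    fst_bc = pair(ib, ic)
    values = pbs(fst_ab, fst_ac, fst_bc)

    table = pd.DataFrame(
        {
            "snp_id": F.snps["snp_id"].to_numpy(),
            "chrom": F.snps["chrom"].to_numpy(),
            "pos_bp": F.snps["pos_bp"].to_numpy(),
            "fst_ab": fst_ab,
            "fst_ac": fst_ac,
            "fst_bc": fst_bc,
            "pbs": values,
        }
    )
    outliers, threshold = call_outliers(values, table["snp_id"].to_numpy(), top_q)
    return PbsScan(triple=triple, table=table, top_q=top_q,
                   outlier_threshold=threshold, outliers=outliers)


# ---------------------------------------------------------------------------
# Two-comparison framework and annotation
# ---------------------------------------------------------------------------

def region_specific(regional: PbsScan, ancient: PbsScan) -> set:
    """Regional outliers not shared with the ancient comparison (set difference)."""
    if regional.snp_universe != ancient.snp_universe:
        raise ValueError("scans cover different SNP universes")
    return set(regional.outliers) - set(ancient.outliers)


def shared_outliers(a: set, b: set) -> set:
    """Candidate loci shared between two targets (set intersection)."""
    return set(a) & set(b)


def read_annotation(path: str | Path) -> dict[str, list[str]]:
    """snp_id -> gene list from a TSV with columns snp_id, gene
    (semicolon-separated for multi-gene). Malformed rows are skipped."""
    mapping: dict[str, list[str]] = {}
    skipped = 0
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("snp_id"):
            fh.seek(0)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not parts[0]:
                skipped += 1
                continue
            genes = [g for g in parts[1].split(";") if g]
            mapping[parts[0]] = genes
    if skipped:
        logger.warning("annotation: skipped %d malformed rows", skipped)
    return mapping


def annotate_hits(
    snps: set, annotation: dict[str, list[str]] | str | Path
) -> dict[str, list[str]]:
    """Group candidate SNPs by annotated gene.

    SNPs with no gene entry are collected under :data:`INTERGENIC_KEY`.
    """
    if not isinstance(annotation, dict):
        annotation = read_annotation(annotation)
    hits: dict[str, list[str]] = {}
    for snp in sorted(snps):
        genes = annotation.get(snp) or [INTERGENIC_KEY]
        for gene in genes:
            hits.setdefault(gene, []).append(snp)
    return hits
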