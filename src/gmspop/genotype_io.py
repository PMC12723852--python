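"""Genotype dataset I/O: EIGENSTRAT and PLINK text formats, plus merging.

A :class:`GenotypeMatrix` holds diploid biallelic calls coded as the count of
``allele1`` (0, 1, 2) with a reserved sentinel for missing calls. Two on-disk
representations are supported:

* EIGENSTRAT triple (``.geno``/``.snp``/``.ind``): one ``.geno`` row per SNP,
  one character per sample in ``{0,1,2,9}`` (9 = missing).
* PLINK text (``.ped``/``.map``): six leading columns per sample, then one
  allele pair per SNP; ``0 0`` is the missing genotype.

Merging intersects SNPs on ``(chrom, pos_bp)`` and harmonizes allele
orientation, recoding swapped-allele calls as ``2 - g``, attempting a strand
complement before declaring a site irreconcilable, and dropping
strand-ambiguous A/T and C/G sites that would need a complement flip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reserved integer for a missing diploid call inside ``GenotypeMatrix.calls``.
MISSING = -9

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "0": "0"}

SNP_COLUMNS = ["snp_id", "chrom", "pos_cm", "pos_bp", "allele1", "allele2"]


def _chrom_sort_key(chrom: str) -> tuple:
    """Numeric chromosomes in numeric order, then non-numeric lexicographic."""
    c = str(chrom)
    return (0, int(c), "") if c.isdigit() else (1, 0, c)
SAMPLE_COLUMNS = ["sample_id", "population"]


class GenotypeFormatError(ValueError):
    """Raised when an on-disk genotype file violates its format."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs diploid calls with SNP and sample metadata.

    Attributes
    ----------
    samples : pandas.DataFrame
        One row per sample; columns ``sample_id`` and ``population`` (plus
        optional free-text metadata columns).
    snps : pandas.DataFrame
        One row per SNP; columns ``snp_id, chrom, pos_cm, pos_bp,
        allele1, allele2``. Sorted by ``(chrom, pos_bp)``.
    calls : numpy.ndarray
        ``(n_samples, n_snps)`` int8 matrix; each entry is the count of
        ``allele1`` in ``{0, 1, 2}`` or :data:`MISSING`.
    """

    samples: pd.DataFrame
    snps: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def validate(self) -> None:
        if self.calls.shape != (self.n_samples, self.n_snps):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match metadata "
                f"({self.n_samples} samples, {self.n_snps} SNPs)"
            )
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(self.calls[~ok])
            raise ValueError(f"invalid call values {bad.tolist()}")
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples["sample_id"][self.samples["sample_id"].duplicated()]
            raise ValueError(f"duplicate sample ids: {sorted(set(dup))}")
        if self.n_snps and self.snps["snp_id"].duplicated().any():
            dup = self.snps["snp_id"][self.snps["snp_id"].duplicated()]
            raise ValueError(f"duplicate snp ids: {sorted(set(dup))}")

    def sorted_by_position(self) -> "GenotypeMatrix":
        """Return a copy with SNPs sorted by (chrom, pos_bp).

        Chromosome labels are compared numerically when they are integers
        ("2" before "10"); non-numeric labels (e.g. "X") sort after numeric
        ones, lexicographically.
        """
        keys = [
            (_chrom_sort_key(c), p)
            for c, p in zip(self.snps["chrom"], self.snps["pos_bp"])
        ]
        order = np.array(sorted(range(self.n_snps), key=keys.__getitem__),
                         dtype=int)
        return GenotypeMatrix(
            samples=self.samples.copy(),
            snps=self.snps.iloc[order],
            calls=self.calls[:, order],
        )

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        """Row/column subset by positional indices (None keeps the axis)."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            samples=self.samples.iloc[si],
            snps=self.snps.iloc[vi],
            calls=self.calls[np.ix_(si, vi)],
        )

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples[SAMPLE_COLUMNS].reset_index(drop=True).equals(
                other.samples[SAMPLE_COLUMNS].reset_index(drop=True)
            )
            and self.snps[SNP_COLUMNS].reset_index(drop=True).equals(
                other.snps[SNP_COLUMNS].reset_index(drop=True)
            )
            and np.array_equal(self.calls, other.calls)
        )

    def equals_up_to_orientation(self, other: "GenotypeMatrix") -> bool:
        """Equality allowing per-SNP allele1/allele2 swaps (calls recoded 2-g).

        PLINK text files record no allele order, so a matrix read back from
        them is only defined up to this orientation.
        """
        if not self.samples[SAMPLE_COLUMNS].reset_index(drop=True).equals(
            other.samples[SAMPLE_COLUMNS].reset_index(drop=True)
        ):
            return False
        a = self.snps[SNP_COLUMNS].reset_index(drop=True)
        b = other.snps[SNP_COLUMNS].reset_index(drop=True)
        if len(a) != len(b):
            return False
        for j in range(len(a)):
            ra, rb = a.iloc[j], b.iloc[j]
            if [ra.snp_id, ra.chrom, ra.pos_bp] != [rb.snp_id, rb.chrom, rb.pos_bp]:
                return False
            ca, cb = self.calls[:, j], other.calls[:, j]
            if (ra.allele1, ra.allele2) == (rb.allele1, rb.allele2):
                if not np.array_equal(ca, cb):
                    return False
            elif (ra.allele1, ra.allele2) == (rb.allele2, rb.allele1):
                recoded = cb.copy()
                nm = recoded != MISSING
                recoded[nm] = 2 - recoded[nm]
                if not np.array_equal(ca, recoded):
                    return False
            elif "0" in (rb.allele1, rb.allele2) or "0" in (ra.allele1, ra.allele2):
                # a monomorphic or all-missing site may carry a '0'
                # placeholder on either side; orient via the shared allele
                if "0" in (rb.allele1, rb.allele2):
                    known = rb.allele1 if rb.allele2 == "0" else rb.allele2
                    flip = known == ra.allele2  # cb counts ra's allele2
                    ok_allele = known in (ra.allele1, ra.allele2, "0")
                else:
                    known = ra.allele1 if ra.allele2 == "0" else ra.allele2
                    flip = known == rb.allele2
                    ok_allele = known in (rb.allele1, rb.allele2, "0")
                if not ok_allele:
                    return False
                recoded = cb.copy()
                if flip:
                    nm = recoded != MISSING
                    recoded[nm] = 2 - recoded[nm]
                if known == "0":  # both sides all-missing
                    if not ((ca == MISSING).all() and (cb == MISSING).all()):
                        return False
                elif not np.array_equal(ca, recoded):
                    return False
            else:
                return False
        return True


# ---------------------------------------------------------------------------
# EIGENSTRAT
# ---------------------------------------------------------------------------

def _read_eigenstrat(prefix: Path) -> GenotypeMatrix:
    snp_path = prefix.with_suffix(".snp")
    ind_path = prefix.with_suffix(".ind")
    geno_path = prefix.with_suffix(".geno")

    snps = pd.read_csv(
        snp_path,
        sep=r"\s+",
        header=None,
        names=["snp_id", "chrom", "pos_cm", "pos_bp", "allele1", "allele2"],
        dtype={"snp_id": str, "chrom": str, "allele1": str, "allele2": str},
    )
    inds = pd.read_csv(
        ind_path,
        sep=r"\s+",
        header=None,
        names=["sample_id", "sex", "population"],
        dtype=str,
    )
    samples = inds[["sample_id", "population"]].copy()

    n_samples, n_snps = len(samples), len(snps)
    calls = np.full((n_samples, n_snps), MISSING, dtype=np.int8)
    with open(geno_path) as fh:
        row = -1
        for row, line in enumerate(fh):
            line = line.rstrip("\n")
            if row >= n_snps:
                raise GenotypeFormatError(
                    f"{geno_path}: more geno rows than .snp entries "
                    f"(line {row + 1})"
                )
            if len(line) != n_samples:
                raise GenotypeFormatError(
                    f"{geno_path} line {row + 1}: {len(line)} characters for "
                    f"{n_samples} samples"
                )
            codes = np.frombuffer(line.encode("ascii"), dtype=np.uint8) - ord("0")
            bad = ~np.isin(codes, (0, 1, 2, 9))
            if bad.any():
                raise GenotypeFormatError(
                    f"{geno_path} line {row + 1}: invalid genotype character"
                )
            col = codes.astype(np.int8)
            col[col == 9] = MISSING
            calls[:, row] = col
    if row + 1 != n_snps:
        raise GenotypeFormatError(
            f"{geno_path}: {row + 1} rows for {n_snps} .snp entries"
        )
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls).sorted_by_position()


def _write_eigenstrat(G: GenotypeMatrix, prefix: Path) -> list[Path]:
    prefix.parent.mkdir(parents=True, exist_ok=True)
    snp_path = prefix.with_suffix(".snp")
    ind_path = prefix.with_suffix(".ind")
    geno_path = prefix.with_suffix(".geno")

    with open(snp_path, "w") as fh:
        for rec in G.snps.itertuples(index=False):
            fh.write(
                f"{rec.snp_id}\t{rec.chrom}\t{rec.pos_cm:g}\t{rec.pos_bp}"
                f"\t{rec.allele1}\t{rec.allele2}\n"
            )
    with open(ind_path, "w") as fh:
        for rec in G.samples.itertuples(index=False):
            fh.write(f"{rec.sample_id}\tU\t{rec.population}\n")
    codes = G.calls.T.astype(np.int16)  # SNP-major
    codes[codes == MISSING] = 9
    with open(geno_path, "w") as fh:
        for row in codes:
            fh.write("".join(map(str, row)) + "\n")
    return [geno_path, snp_path, ind_path]


# ---------------------------------------------------------------------------
# PLINK text
# ---------------------------------------------------------------------------

_VALID_ALLELES = frozenset("ACGT0")


def _read_plink_text(prefix: Path) -> GenotypeMatrix:
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")

    snp_map = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "pos_cm", "pos_bp"],
        dtype={"chrom": str, "snp_id": str},
    )
    n_snps = len(snp_map)

    sample_ids: list[str] = []
    populations: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise GenotypeFormatError(
                    f"{ped_path} line {lineno}: {len(fields)} fields, "
                    f"expected {6 + 2 * n_snps}"
                )
            populations.append(fields[0])  # family id doubles as population
            sample_ids.append(fields[1])
            allele_rows.append(fields[6:])

    n_samples = len(sample_ids)
    alleles = (
        np.array(allele_rows, dtype=object).reshape(n_samples, n_snps, 2)
        if n_samples
        else np.empty((0, n_snps, 2), dtype=object)
    )
    bad_tokens = {t for t in alleles.ravel() if t not in _VALID_ALLELES}
    if bad_tokens:
        raise GenotypeFormatError(
            f"{ped_path}: invalid allele tokens {sorted(bad_tokens)}"
        )

    # allele1 is the first allele of the first heterozygous genotype; if no
    # heterozygote exists it is the first non-missing allele encountered.
    # (The .ped/.map pair records no allele order of its own; this convention
    # makes write->read the identity whenever a heterozygote is present.)
    a1 = np.empty(n_snps, dtype="U1")
    a2 = np.empty(n_snps, dtype="U1")
    calls = np.full((n_samples, n_snps), MISSING, dtype=np.int8)
    for j in range(n_snps):
        col = alleles[:, j, :]
        observed = col[col != "0"]
        uniq = sorted(set(observed))
        if len(uniq) > 2:
            raise GenotypeFormatError(
                f"{ped_path}: SNP {snp_map.snp_id.iloc[j]} has "
                f"{len(uniq)} alleles {uniq}"
            )
        half_missing = (col[:, 0] != "0") != (col[:, 1] != "0")
        if half_missing.any():
            raise GenotypeFormatError(
                f"{ped_path}: SNP {snp_map.snp_id.iloc[j]} has a half-missing "
                "genotype"
            )
        if len(uniq) == 0:
            a1[j], a2[j] = "0", "0"
        elif len(uniq) == 1:
            a1[j], a2[j] = uniq[0], "0"
        else:
            het = (col[:, 0] != col[:, 1]) & (col[:, 0] != "0") & (col[:, 1] != "0")
            if het.any():
                first = col[np.argmax(het), 0]
            else:
                nonmiss_rows = np.nonzero(col[:, 0] != "0")[0]
                first = col[nonmiss_rows[0], 0]
            a1[j] = first
            a2[j] = uniq[0] if uniq[1] == first else uniq[1]
        nonmiss = (col[:, 0] != "0") & (col[:, 1] != "0")
        calls[nonmiss, j] = (col[nonmiss] == a1[j]).sum(axis=1)

    snps = pd.DataFrame(
        {
            "snp_id": snp_map["snp_id"],
            "chrom": snp_map["chrom"],
            "pos_cm": snp_map["pos_cm"].astype(float),
            "pos_bp": snp_map["pos_bp"].astype(int),
            "allele1": a1,
            "allele2": a2,
        }
    )
    samples = pd.DataFrame({"sample_id": sample_ids, "population": populations})
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls).sorted_by_position()


def _write_plink_text(G: GenotypeMatrix, prefix: Path) -> list[Path]:
    prefix.parent.mkdir(parents=True, exist_ok=True)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")

    # unknown allele codes are representable only where the call never needs
    # that allele on disk
    a1_arr = G.snps["allele1"].to_numpy()
    a2_arr = G.snps["allele2"].to_numpy()
    for j in range(G.n_snps):
        col = G.calls[:, j]
        if a1_arr[j] == "0" and np.isin(col, (1, 2)).any():
            raise GenotypeFormatError(
                f"SNP {G.snps.snp_id.iloc[j]}: calls require allele1 but it is '0'"
            )
        if a2_arr[j] == "0" and np.isin(col, (0, 1)).any():
            raise GenotypeFormatError(
                f"SNP {G.snps.snp_id.iloc[j]}: calls require allele2 but it is '0'"
            )

    with open(map_path, "w") as fh:
        for rec in G.snps.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.snp_id}\t{rec.pos_cm:g}\t{rec.pos_bp}\n")

    a1 = G.snps["allele1"].to_numpy(dtype="U1")
    a2 = G.snps["allele2"].to_numpy(dtype="U1")
    with open(ped_path, "w") as fh:
        for i, rec in enumerate(G.samples.itertuples(index=False)):
            row = G.calls[i]
            pairs = np.empty((G.n_snps, 2), dtype="U1")
            pairs[row == 2] = np.stack([a1, a1], axis=1)[row == 2]
            pairs[row == 1] = np.stack([a1, a2], axis=1)[row == 1]
            pairs[row == 0] = np.stack([a2, a2], axis=1)[row == 0]
            pairs[row == MISSING] = ["0", "0"]
            geno = " ".join(" ".join(p) for p in pairs)
            fh.write(
                f"{rec.population} {rec.sample_id} 0 0 0 -9 {geno}\n"
                if G.n_snps
                else f"{rec.population} {rec.sample_id} 0 0 0 -9\n"
            )
    return [ped_path, map_path]


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_genotypes(prefix: str | Path, format: str) -> GenotypeMatrix:
    """Read a genotype dataset from disk.

    Parameters
    ----------
    prefix : path
        Common path prefix of the file set (extension ignored if present).
    format : {"eigenstrat", "plink_text"}
    """
    prefix = Path(prefix)
    if format == "eigenstrat":
        return _read_eigenstrat(prefix)
    if format == "plink_text":
        return _read_plink_text(prefix)
    raise ValueError(f"unknown format {format!r}")


def write_genotypes(G: GenotypeMatrix, format: str, prefix: str | Path) -> list[Path]:
    """Write ``G`` to disk; returns the list of files written."""
    prefix = Path(prefix)
    if format == "eigenstrat":
        return _write_eigenstrat(G, prefix)
    if format == "plink_text":
        return _write_plink_text(G, prefix)
    raise ValueError(f"unknown format {format!r}")


def _orient(a1a: str, a2a: str, a1b: str, a2b: str) -> str | None:
    """How B's calls map onto A's allele convention at one site.

    Returns ``"same"``, ``"swap"``, or ``None`` (irreconcilable). A strand
    complement is attempted before giving up, but A/T and C/G sites that would
    need the flip are ambiguous and dropped.
    """
    if (a1b, a2b) == (a1a, a2a):
        return "same"
    if (a1b, a2b) == (a2a, a1a):
        return "swap"
    ambiguous = {frozenset("AT"), frozenset("CG")}
    c1, c2 = _COMPLEMENT.get(a1b), _COMPLEMENT.get(a2b)
    if c1 is None or c2 is None:
        return None
    if (c1, c2) == (a1a, a2a) or (c1, c2) == (a2a, a1a):
        if frozenset((a1a, a2a)) in ambiguous:
            return None  # strand-ambiguous site needing a flip
        return "same" if (c1, c2) == (a1a, a2a) else "swap"
    return None


def merge_datasets(A: GenotypeMatrix, B: GenotypeMatrix) -> GenotypeMatrix:
    """Merge two datasets on the SNP intersection keyed by (chrom, pos_bp).

    Samples are concatenated (ids must be disjoint); B's calls are recoded
    ``g -> 2 - g`` where its alleles are swapped relative to A, and sites with
    irreconcilable or strand-ambiguous alleles are dropped.
    """
    overlap = set(A.samples.sample_id) & set(B.samples.sample_id)
    if overlap:
        raise ValueError(f"duplicate sample ids across inputs: {sorted(overlap)}")

    def keyed(snps: pd.DataFrame) -> dict[tuple, int]:
        out: dict[tuple, int] = {}
        for i, rec in enumerate(snps.itertuples(index=False)):
            key = (rec.chrom, rec.pos_bp)
            if key in out:
                logger.warning("duplicate SNP at %s:%s, keeping first", *key)
                continue
            out[key] = i
        return out

    a_key = keyed(A.snps)
    b_key = keyed(B.snps)
    a_idx, b_idx, flip = [], [], []
    n_irreconcilable = 0
    for key, ia in a_key.items():
        ib = b_key.get(key)
        if ib is None:
            continue
        ra, rb = A.snps.iloc[ia], B.snps.iloc[ib]
        how = _orient(ra.allele1, ra.allele2, rb.allele1, rb.allele2)
        if how is None:
            n_irreconcilable += 1
            continue
        a_idx.append(ia)
        b_idx.append(ib)
        flip.append(how == "swap")
    if n_irreconcilable:
        logger.info("merge dropped %d irreconcilable-allele SNPs", n_irreconcilable)

    a_idx = np.array(a_idx, dtype=int)
    b_idx = np.array(b_idx, dtype=int)
    flip = np.array(flip, dtype=bool)

    calls_a = A.calls[:, a_idx]
    calls_b = B.calls[:, b_idx].copy()
    if flip.any():
        sub = calls_b[:, flip]
        nonmiss = sub != MISSING
        sub[nonmiss] = 2 - sub[nonmiss]
        calls_b[:, flip] = sub

    samples = pd.concat(
        [A.samples[SAMPLE_COLUMNS], B.samples[SAMPLE_COLUMNS]], ignore_index=True
    )
    snps = A.snps.iloc[a_idx]
    calls = np.vstack([calls_a, calls_b]) if len(samples) else np.empty(
        (0, len(a_idx)), dtype=np.int8
    )
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls).sorted_by_position()
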