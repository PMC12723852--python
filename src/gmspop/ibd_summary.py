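"""Identity-by-descent sharing summaries from detected segment tables.

Reads the 9-column tab-delimited output of haplotype-based IBD detectors
(id1, hap1, id2, hap2, chrom, start_bp, end_bp, lod, length_cm) and computes,
for every (population, population) pair and segment-length bin, the average
total IBD in centimorgans per individual pair. Segment lengths in the 1-5 cM
bin index sharing on the order of 0.5-1.5 kya; segments above 5 cM index
sharing within roughly the last 500 years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default length bins, half-open on the left: (1, 5] and (5, inf) cM.
DEFAULT_BINS = ((1.0, 5.0), (5.0, float("inf")))


class IbdFormatError(ValueError):
    pass


@dataclass
class IbdSegment:
    id1: str
    hap1: int
    id2: str
    hap2: int
    chrom: str
    start_bp: int
    end_bp: int
    lod: float
    length_cm: float

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValueError(
                f"segment start {self.start_bp} must precede end {self.end_bp}"
            )
        if self.id1 == self.id2:
            raise ValueError(f"self-segment for sample {self.id1}")
        if self.length_cm <= 0:
            raise ValueError("segment length must be positive")


@dataclass
class IbdSummary:
    """Mean total IBD (cM) per population pair per length bin."""

    bins: tuple
    table: pd.DataFrame  # popA, popB, bin, mean_total_cm, n_pairs, n_segments

    def mean_total(self, popA: str, popB: str, bin_index: int) -> float:
        a, b = sorted((popA, popB))
        low, high = self.bins[bin_index]
        label = _bin_label(low, high)
        row = self.table[
            (self.table.popA == a) & (self.table.popB == b)
            & (self.table["bin"] == label)
        ]
        return float(row.mean_total_cm.iloc[0]) if len(row) else 0.0


def _bin_label(low: float, high: float) -> str:
    return f"({low:g},{high:g}]" if np.isfinite(high) else f"({low:g},inf)"


def read_ibd(path: str | Path, min_length_cm: float = 1.0) -> list[IbdSegment]:
    """Parse a 9-column IBD segment table, dropping sub-threshold segments."""
    segments: list[IbdSegment] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise IbdFormatError(
                    f"{path} line {lineno}: {len(parts)} columns, expected 9"
                )
            try:
                seg = IbdSegment(
                    id1=parts[0], hap1=int(parts[1]),
                    id2=parts[2], hap2=int(parts[3]),
                    chrom=parts[4], start_bp=int(parts[5]),
                    end_bp=int(parts[6]), lod=float(parts[7]),
                    length_cm=float(parts[8]),
                )
            except ValueError as exc:
                raise IbdFormatError(f"{path} line {lineno}: {exc}") from exc
            if seg.length_cm < min_length_cm:
                dropped += 1
                continue
            segments.append(seg)
    if dropped:
        logger.info("read_ibd: dropped %d segments below %g cM",
                    dropped, min_length_cm)
    return segments


def summarize_ibd(
    segments: list[IbdSegment],
    popmap: dict[str, str],
    bins: tuple = DEFAULT_BINS,
) -> IbdSummary:
    """Average total IBD per population pair, stratified by length bin.

    For distinct populations P and Q the denominator is |P| * |Q| (all
    cross-pairs, sharing or not); within a population it is |P|(|P|-1)/2.
    Haplotype-level segments between the same individual pair are summed
    before averaging, so the statistic is per individual pair.
    """
    for seg in segments:
        for sid in (seg.id1, seg.id2):
            if sid not in popmap:
                raise KeyError(f"sample {sid!r} missing from population map")

    pop_sizes: dict[str, int] = {}
    for pop in popmap.values():
        pop_sizes[pop] = pop_sizes.get(pop, 0) + 1
    pops = sorted(pop_sizes)

    def n_pairs(a: str, b: str) -> int:
        if a == b:
            s = pop_sizes[a]
            return s * (s - 1) // 2
        return pop_sizes[a] * pop_sizes[b]

    # accumulate totals and segment counts per (popA, popB, bin)
    totals: dict[tuple, float] = {}
    counts: dict[tuple, int] = {}
    for seg in segments:
        pa, pb = sorted((popmap[seg.id1], popmap[seg.id2]))
        for low, high in bins:
            if low < seg.length_cm <= high:
                key = (pa, pb, (low, high))
                totals[key] = totals.get(key, 0.0) + seg.length_cm
                counts[key] = counts.get(key, 0) + 1

    rows = []
    for i, a in enumerate(pops):
        for b in pops[i:]:
            denom = n_pairs(a, b)
            for low, high in bins:
                key = (a, b, (low, high))
                total = totals.get(key, 0.0)
                rows.append(
                    {
                        "popA": a,
                        "popB": b,
                        "bin": _bin_label(low, high),
                        "mean_total_cm": total / denom if denom else 0.0,
                        "n_pairs": denom,
                        "n_segments": counts.get(key, 0),
                    }
                )
    return IbdSummary(bins=tuple(bins), table=pd.DataFrame(rows))
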