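"""Gene models and genomic interval sets.

A gene is represented by the union of the exons of all of its transcripts,
on a single strand of a single chromosome.  Coordinates are 0-based,
half-open throughout the package (BED convention); 1-based inputs such as
MAF rows are converted at parse time.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "IntervalSet",
    "union_exons",
    "read_refflat",
    "read_bed12",
]


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping or book-ended intervals."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for start, end in ivs:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclasses.dataclass
class GeneModel:
    """A stranded gene as a union of exon intervals.

    Parameters
    ----------
    gene_id : str
        Gene identifier.
    chrom : str
        Chromosome name.
    strand : {"+", "-"}
        Direction of transcription.  The coding (non-transcribed) strand of
        a "+" gene is the reference strand itself.
    exons : list of (start, end)
        0-based half-open intervals on the reference + strand.  Normalized
        to sorted, pairwise-disjoint form on construction.
    dual_strand_flag : bool
        True when the locus is also transcribed off the opposite strand;
        such genes are excluded from strand-resolved analyses.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    dual_strand_flag: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: empty exon list")
        for start, end in self.exons:
            if start >= end:
                raise ValueError(
                    f"gene {self.gene_id}: malformed exon [{start}, {end})"
                )
        self.exons = _merge_intervals(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def flipped(self) -> "GeneModel":
        """The same gene on the opposite strand (used in symmetry checks)."""
        other = "-" if self.strand == "+" else "+"
        return GeneModel(self.gene_id, self.chrom, other, list(self.exons),
                         self.dual_strand_flag)


class IntervalSet:
    """Chromosome-keyed sets of disjoint 0-based half-open intervals.

    Intervals are normalized (sorted, overlaps merged) per chromosome, so
    membership and overlap queries can use binary search.
    """

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int]]] | None = None):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        if intervals:
            for chrom, ivs in intervals.items():
                merged = _merge_intervals(
                    [(int(s), int(e)) for s, e in ivs if int(s) < int(e)]
                )
                if merged:
                    self._starts[chrom] = np.array([s for s, _ in merged], dtype=np.int64)
                    self._ends[chrom] = np.array([e for _, e in merged], dtype=np.int64)

    @classmethod
    def from_bed(cls, path) -> "IntervalSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
        grouped: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in df.itertuples(index=False):
            grouped.setdefault(str(chrom), []).append((int(start), int(end)))
        return cls(grouped)

    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        if chrom not in self._starts:
            return []
        return list(zip(self._starts[chrom].tolist(), self._ends[chrom].tolist()))

    def __len__(self) -> int:
        return sum(len(v) for v in self._starts.values())

    def contains(self, chrom: str, pos) -> np.ndarray:
        """Vectorized membership test for 0-based positions."""
        pos = np.asarray(pos, dtype=np.int64)
        if chrom not in self._starts:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(self._starts[chrom], pos, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(pos.shape, dtype=bool)
        hit[ok] = pos[ok] < self._ends[chrom][idx[ok]]
        return hit

    def mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of length end-start: True where covered."""
        out = np.zeros(end - start, dtype=bool)
        if chrom not in self._starts:
            return out
        starts, ends = self._starts[chrom], self._ends[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        for s, e in zip(starts[lo:hi], ends[lo:hi]):
            out[max(s - start, 0): max(min(e, end) - start, 0)] = True
        return out

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms():
                for s, e in self.intervals(chrom):
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def union_exons(transcripts: Sequence[GeneModel]) -> list[GeneModel]:
    """Collapse per-transcript records into one GeneModel per gene_id.

    All transcripts of a gene must share a chromosome; exons are merged to a
    sorted disjoint union.  A gene whose transcripts disagree on strand is
    flagged dual-strand (the reported strand is the first one seen) so that
    strand-resolved analyses can drop it.
    """
    by_gene: dict[str, list[GeneModel]] = {}
    order: list[str] = []
    for t in transcripts:
        if t.gene_id not in by_gene:
            order.append(t.gene_id)
        by_gene.setdefault(t.gene_id, []).append(t)

    out: list[GeneModel] = []
    for gid in order:
        recs = by_gene[gid]
        chroms = {r.chrom for r in recs}
        if len(chroms) > 1:
            raise ValueError(f"gene {gid}: transcripts on multiple chromosomes {sorted(chroms)}")
        strands = {r.strand for r in recs}
        exons = [iv for r in recs for iv in r.exons]
        dual = len(strands) > 1 or any(r.dual_strand_flag for r in recs)
        out.append(GeneModel(gid, recs[0].chrom, recs[0].strand, exons, dual))
    return out


def read_refflat(path) -> list[GeneModel]:
    """Read a refFlat-style TSV of transcripts.

    Expected columns (no header): geneName, chrom, strand, exonStarts,
    exonEnds — the last two as comma-separated 0-based coordinate lists.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene", "chrom", "strand", "exonStarts", "exonEnds"],
                     dtype=str)
    records = []
    for gene, chrom, strand, ss, ee in df.itertuples(index=False):
        starts = [int(x) for x in str(ss).rstrip(",").split(",")]
        ends = [int(x) for x in str(ee).rstrip(",").split(",")]
        if len(starts) != len(ends):
            raise ValueError(f"gene {gene}: exonStarts/exonEnds length mismatch")
        records.append(GeneModel(gene, chrom, strand, list(zip(starts, ends))))
    return records


def read_bed12(path) -> list[GeneModel]:
    """Read transcripts from BED12 (name column used as gene id)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 12:
        raise ValueError("BED12 requires 12 columns")
    records = []
    for row in df.itertuples(index=False):
        chrom, tx_start, name, strand = row[0], int(row[1]), row[3], row[5]
        sizes = [int(x) for x in str(row[10]).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row[11]).rstrip(",").split(",")]
        exons = [(tx_start + o, tx_start + o + sz) for o, sz in zip(offsets, sizes)]
        records.append(GeneModel(name, chrom, strand, exons))
    return records
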