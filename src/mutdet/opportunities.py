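"""Per-gene mutational-opportunity counting from the reference sequence.

For every gene we count, over the exon union, the sites at which each
mutation class could occur:

* ``L_cpg`` — exonic nucleotides that are the C or the G of a CG
  dinucleotide on the reference + strand and lie outside CpG islands.
  Both positions of the dinucleotide must be exonic; the exposure counts
  nucleotides (so one clean CG contributes 2).  CpG islands are excluded
  because island CpGs are largely unmethylated and do not share the
  deamination-driven transition process.
* ``L_all`` — all exonic nucleotides (exposure for non-CpG-Ti mutations).
* strand-resolved base counts — e.g. the number of A residues on the
  non-transcribed (coding) strand, the exposure for A>G mutations on the
  NTS.

Positions whose reference base is ambiguous (N or any non-ACGT code) are
excluded from every count.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .genes import GeneModel, IntervalSet

__all__ = ["OpportunityCounts", "compute_opportunities", "opportunity_table"]

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclasses.dataclass
class OpportunityCounts:
    """Sequence-derived exposures for one gene."""

    gene_id: str
    L_cpg: int
    L_all: int
    gc_fraction: float
    base_counts_nts: dict[str, int]  # A/C/G/T residues on the coding strand
    base_counts_ts: dict[str, int]   # and on the template strand

    @property
    def exonic_length(self) -> int:
        return self.L_all

    @property
    def L_A_nts(self) -> int:
        return self.base_counts_nts["A"]

    @property
    def L_A_ts(self) -> int:
        return self.base_counts_ts["A"]


def _fetch_span(genome, chrom: str, start: int, end: int) -> str:
    """Fetch [start, end) from a dict of strings or a pyfaidx Fasta."""
    seq = genome[chrom][start:end]
    return str(seq).upper()


def _contig_length(genome, chrom: str) -> int:
    contig = genome[chrom]
    return len(contig)


def compute_opportunities(
    gene: GeneModel,
    genome: Mapping[str, str],
    islands: IntervalSet | None = None,
) -> OpportunityCounts:
    """Count mutational opportunities for one gene.

    Parameters
    ----------
    gene : GeneModel
    genome : mapping of chrom -> sequence (plain strings or pyfaidx.Fasta)
    islands : IntervalSet, optional
        CpG-island intervals; positions inside an island are removed from
        the CpG-Ti exposure only.
    """
    if islands is None:
        islands = IntervalSet()
    chrom_len = _contig_length(genome, gene.chrom)
    if gene.end > chrom_len:
        raise ValueError(
            f"gene {gene.gene_id}: exon end {gene.end} beyond contig "
            f"{gene.chrom} length {chrom_len}"
        )
    start, end = gene.start, gene.end
    # one extra base so a CG whose G sits at the last exonic position is seen
    fetch_end = min(end + 1, chrom_len)
    seq = np.frombuffer(_fetch_span(genome, gene.chrom, start, fetch_end).encode(), dtype="S1")

    span = end - start
    exonic = np.zeros(fetch_end - start, dtype=bool)
    for s, e in gene.exons:
        exonic[s - start: e - start] = True

    is_base = {b: seq == b.encode() for b in _BASES}
    unambiguous = is_base["A"] | is_base["C"] | is_base["G"] | is_base["T"]
    valid = exonic & unambiguous  # counts use exonic, non-ambiguous positions

    L_all = int(valid[:span].sum())
    n_plus = {b: int((is_base[b] & valid)[:span].sum()) for b in _BASES}
    gc_fraction = (n_plus["G"] + n_plus["C"]) / L_all if L_all else float("nan")

    # CG dinucleotides on the + strand; both members must be valid exonic
    cg = np.zeros(len(seq), dtype=bool)
    if len(seq) >= 2:
        cg[:-1] = is_base["C"][:-1] & is_base["G"][1:]
    pair_ok = np.zeros(len(seq), dtype=bool)
    pair_ok[:-1] = cg[:-1] & valid[:-1] & valid[1:]
    in_cpg = np.zeros(len(seq), dtype=bool)
    in_cpg[:-1] |= pair_ok[:-1]          # the C
    in_cpg[1:] |= pair_ok[:-1]           # the G
    island_mask = islands.mask(gene.chrom, start, fetch_end)
    L_cpg = int((in_cpg & valid & ~island_mask)[:span].sum())

    if gene.strand == "+":
        nts = dict(n_plus)
    else:
        nts = {b: n_plus[_COMPLEMENT[b]] for b in _BASES}
    ts = {b: nts[_COMPLEMENT[b]] for b in _BASES}

    return OpportunityCounts(
        gene_id=gene.gene_id,
        L_cpg=L_cpg,
        L_all=L_all,
        gc_fraction=gc_fraction,
        base_counts_nts=nts,
        base_counts_ts=ts,
    )


def opportunity_table(
    genes,
    genome,
    islands: IntervalSet | None = None,
) -> pd.DataFrame:
    """Opportunities for many genes as a DataFrame indexed by gene_id.

    Columns: L_cpg, L_all, gc_fraction, and nts_/ts_ base counts in stable
    order, so the table round-trips through TSV unchanged.
    """
    rows = []
    for gene in genes:
        opp = compute_opportunities(gene, genome, islands)
        row = {
            "gene_id": opp.gene_id,
            "L_cpg": opp.L_cpg,
            "L_all": opp.L_all,
            "gc_fraction": opp.gc_fraction,
        }
        for b in _BASES:
            row[f"nts_{b}"] = opp.base_counts_nts[b]
        for b in _BASES:
            row[f"ts_{b}"] = opp.base_counts_ts[b]
        rows.append(row)
    df = pd.DataFrame(rows).set_index("gene_id")
    return df
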