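"""Mutation-call parsing, sample QC and strand-aware classification.

Point mutations are collapsed to six purine-reference types
(A>C, A>G, A>T, G>A, G>C, G>T) and assigned to the non-transcribed
strand (NTS, the coding strand) or the transcribed strand (TS) of each
retained gene containing them.  CpG transitions (C>T / G>A in a CG
context, outside CpG islands) are flagged separately because methylated
cytosine deamination is a distinct mutational source.

Samples with an outlying total mutation count ("hypermutators", usually
mismatch-repair-deficient tumours) are removed before rate modelling.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genes import GeneModel, IntervalSet

logger = logging.getLogger(__name__)

__all__ = [
    "MutationRecord",
    "COLLAPSED_TYPES",
    "parse_mutations",
    "filter_hypermutators",
    "classify_mutations",
    "ClassificationReport",
    "count_by_gene",
]

COLLAPSED_TYPES = ["A>C", "A>G", "A>T", "G>A", "G>C", "G>T"]
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

RECORD_COLUMNS = ["chrom", "pos", "ref", "alt", "sample_id", "dataset"]

# accepted aliases for each canonical column, tried in order
_MAF_ALIASES = {
    "chrom": ["chrom", "Chromosome", "chr"],
    "pos": ["pos", "Start_Position", "Start_position", "position"],
    "ref": ["ref", "Reference_Allele"],
    "alt": ["alt", "Tumor_Seq_Allele2", "Alternate_Allele"],
    "sample_id": ["sample_id", "sample", "Tumor_Sample_Barcode"],
    "dataset": ["dataset", "cohort", "study"],
}


@dataclasses.dataclass
class MutationRecord:
    """One single-nucleotide substitution call (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    dataset: str = ""


def _records_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df[RECORD_COLUMNS].copy()
    out["pos"] = out["pos"].astype(np.int64)
    for c in ("chrom", "ref", "alt", "sample_id", "dataset"):
        out[c] = out[c].astype(str)
    return out.reset_index(drop=True)


def parse_mutations(path, format: str = "maf_tsv", dataset: str | None = None,
                    column_map: dict | None = None):
    """Parse SNV calls from a MAF-like TSV or a minimal VCF.

    Returns
    -------
    (DataFrame, dict)
        Records with columns chrom, pos (1-based), ref, alt, sample_id,
        dataset; and a counter dict with ``n_rows``, ``n_snv``,
        ``n_skipped_non_snv``, ``n_skipped_bad_allele``.
    """
    if format == "maf_tsv":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        colmap = {}
        for canon, aliases in _MAF_ALIASES.items():
            if column_map and canon in column_map:
                aliases = [column_map[canon]]
            found = next((a for a in aliases if a in df.columns), None)
            if found is None:
                if canon == "dataset" and dataset is not None:
                    continue
                raise ValueError(f"missing column for {canon!r} (tried {aliases})")
            colmap[canon] = found
        out = pd.DataFrame({canon: df[col] for canon, col in colmap.items()})
        if "dataset" not in out.columns:
            out["dataset"] = dataset
    elif format == "vcf_min":
        rows = []
        with open(path) as fh:
            header = None
            for line in fh:
                if line.startswith("##"):
                    continue
                if line.startswith("#"):
                    header = line.lstrip("#").rstrip("\n").split("\t")
                    continue
                rows.append(line.rstrip("\n").split("\t"))
        if header is None:
            raise ValueError("missing column header line in VCF")
        vdf = pd.DataFrame(rows, columns=header)
        for req in ("CHROM", "POS", "REF", "ALT"):
            if req not in vdf.columns:
                raise ValueError(f"missing column {req!r} in VCF")
        sample_cols = header[header.index("FORMAT") + 1:] if "FORMAT" in header else []
        if sample_cols:
            frames = []
            for s in sample_cols:
                carrier = vdf[s].str.split(":").str[0].str.contains("1", regex=False)
                sub = vdf.loc[carrier, ["CHROM", "POS", "REF", "ALT"]].copy()
                sub["sample_id"] = s
                frames.append(sub)
            vdf = pd.concat(frames, ignore_index=True) if frames else vdf.iloc[0:0]
        else:
            vdf = vdf[["CHROM", "POS", "REF", "ALT"]].copy()
            vdf["sample_id"] = "sample0"
        out = vdf.rename(columns={"CHROM": "chrom", "POS": "pos",
                                  "REF": "ref", "ALT": "alt"})
        out["dataset"] = dataset if dataset is not None else ""
    else:
        raise ValueError(f"unknown format {format!r}")

    n_rows = len(out)
    is_single = (out["ref"].str.len() == 1) & (out["alt"].str.len() == 1)
    n_non_snv = int((~is_single).sum())
    out = out[is_single]
    good = out["ref"].isin(list("ACGT")) & out["alt"].isin(list("ACGT")) \
        & (out["ref"] != out["alt"])
    n_bad = int((~good).sum())
    out = out[good]
    counters = {
        "n_rows": n_rows,
        "n_snv": len(out),
        "n_skipped_non_snv": n_non_snv,
        "n_skipped_bad_allele": n_bad,
    }
    if n_non_snv or n_bad:
        logger.info("parse_mutations: skipped %d non-SNV, %d bad-allele rows",
                    n_non_snv, n_bad)
    return _records_frame(out), counters


def _tukey_fence(counts: np.ndarray) -> float:
    q1, q3 = np.percentile(counts, [25, 75])
    return float(q3 + 1.5 * (q3 - q1))


def filter_hypermutators(records: pd.DataFrame, method: str = "fence",
                         alpha: float = 0.05):
    """Remove samples with outlying mutation counts.

    ``method="fence"`` (default) removes samples whose count exceeds
    Tukey's upper fence Q3 + 1.5*IQR.  ``method="esd"`` runs a
    generalized extreme studentized deviate test (one-sided, upper) at
    level ``alpha`` instead.

    Returns (kept records, QC table with sample_id, mutation_count,
    fence_value, removed).
    """
    counts = records.groupby("sample_id").size().sort_index()
    if len(counts) < 4:
        warnings.warn("fewer than 4 samples: hypermutator filter skipped")
        qc = pd.DataFrame({
            "sample_id": counts.index,
            "mutation_count": counts.to_numpy(),
            "fence_value": np.nan,
            "removed": False,
        })
        return records.copy(), qc

    vals = counts.to_numpy(dtype=float)
    if method == "fence":
        fence = _tukey_fence(vals)
        removed = vals > fence
    elif method == "esd":
        removed = _esd_outliers(vals, alpha=alpha)
        fence = float(vals[~removed].max()) if (~removed).any() else float("nan")
    else:
        raise ValueError(f"unknown method {method!r}")

    qc = pd.DataFrame({
        "sample_id": counts.index,
        "mutation_count": counts.to_numpy(),
        "fence_value": fence,
        "removed": removed,
    })
    bad = set(counts.index[removed])
    kept = records[~records["sample_id"].isin(bad)].reset_index(drop=True)
    if bad:
        logger.info("filter_hypermutators: removed %d/%d samples (%.1f%%)",
                    len(bad), len(counts), 100 * len(bad) / len(counts))
    return kept, qc


def _esd_outliers(values: np.ndarray, alpha: float = 0.05,
                  max_outliers: int | None = None) -> np.ndarray:
    """Generalized ESD test, upper tail only."""
    n = len(values)
    if max_outliers is None:
        max_outliers = max(1, n // 10)
    removed = np.zeros(n, dtype=bool)
    active = np.ones(n, dtype=bool)
    flagged: list[int] = []
    n_signif = 0
    for i in range(1, max_outliers + 1):
        vals = values[active]
        if vals.std(ddof=1) == 0:
            break
        resid = (vals - vals.mean()) / vals.std(ddof=1)
        j_local = int(np.argmax(resid))
        stat = resid[j_local]
        idx = np.flatnonzero(active)[j_local]
        flagged.append(idx)
        active[idx] = False
        m = n - i
        p = 1 - alpha / (n - i + 1)
        t = stats.t.ppf(p, m - 1)
        crit = (m * t) / np.sqrt((m - 1 + t ** 2) * (m + 1))
        if stat > crit:
            n_signif = i
    for idx in flagged[:n_signif]:
        removed[idx] = True
    return removed


def _multi_arange(lo: np.ndarray, hi: np.ndarray):
    """Concatenated aranges [lo[i], hi[i]) plus the repeat index of each."""
    counts = hi - lo
    keep = counts > 0
    lo, counts = lo[keep], counts[keep]
    src = np.flatnonzero(keep)
    if len(lo) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    ends = counts.cumsum()
    out = np.ones(ends[-1], dtype=np.int64)
    out[0] = lo[0]
    out[ends[:-1]] = lo[1:] - (lo[:-1] + counts[:-1] - 1)
    return out.cumsum(), np.repeat(src, counts)


@dataclasses.dataclass
class ClassificationReport:
    """Accounting of every input record's fate (conservation identity)."""

    n_input: int = 0
    n_ref_mismatch: int = 0
    n_assigned: int = 0        # distinct records placed in >= 1 gene
    n_no_gene: int = 0
    n_assignments: int = 0     # record x gene pairs (multi-overlap counted)
    n_genes_dual_strand: int = 0

    def conserved(self) -> bool:
        return self.n_input == self.n_ref_mismatch + self.n_assigned + self.n_no_gene


def classify_mutations(
    records: pd.DataFrame,
    genes: Sequence[GeneModel],
    genome,
    islands: IntervalSet | None = None,
) -> tuple[pd.DataFrame, ClassificationReport]:
    """Assign mutations to genes and collapse to strand-resolved types.

    A mutation is assigned to every retained (single-strand) gene whose
    exon union contains it.  The collapsed type is expressed with a purine
    (A or G) reference; ``strand_class`` records whether that purine lies
    on the coding strand (NTS) or the template strand (TS).  Records whose
    stated reference base disagrees with the genome are dropped and
    counted.

    Returns a DataFrame with one row per (record, gene) assignment and a
    :class:`ClassificationReport`.
    """
    if islands is None:
        islands = IntervalSet()
    report = ClassificationReport(n_input=len(records))

    retained = [g for g in genes if not g.dual_strand_flag]
    report.n_genes_dual_strand = len(genes) - len(retained)

    # per-chrom exon index over retained genes
    exon_index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    gene_ids = np.array([g.gene_id for g in retained], dtype=object)
    gene_strand_plus = np.array([g.strand == "+" for g in retained])
    per_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for gi, g in enumerate(retained):
        for s, e in g.exons:
            per_chrom.setdefault(g.chrom, []).append((s, e, gi))
    for chrom, triples in per_chrom.items():
        arr = np.array(triples, dtype=np.int64)
        exon_index[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])

    out_frames: list[pd.DataFrame] = []
    assigned_rows: list[np.ndarray] = []
    mismatch_total = 0

    for chrom, sub in records.groupby("chrom", sort=False):
        pos0 = sub["pos"].to_numpy(np.int64) - 1
        try:
            seq = genome[chrom]
        except KeyError:
            report.n_no_gene += len(sub)
            continue
        seq_str = seq if isinstance(seq, str) else str(seq[:])
        arr = np.frombuffer(seq_str.upper().encode(), dtype="S1")
        chrom_len = len(arr)
        inb = (pos0 >= 0) & (pos0 < chrom_len)
        ref = sub["ref"].to_numpy(dtype=object)
        base = np.full(len(sub), "N", dtype=object)
        left = np.full(len(sub), "N", dtype=object)
        right = np.full(len(sub), "N", dtype=object)
        safe = np.where(inb, pos0, 0)
        base[inb] = arr[safe].astype("U1")[inb]
        has_left = inb & (pos0 > 0)
        left[has_left] = arr[np.where(has_left, pos0 - 1, 0)].astype("U1")[has_left]
        has_right = inb & (pos0 + 1 < chrom_len)
        right[has_right] = arr[np.where(has_right, pos0 + 1, 0)].astype("U1")[has_right]
        mismatch = (base != ref) | ~inb
        mismatch_total += int(mismatch.sum())

        ok = ~mismatch
        if chrom not in exon_index:
            report.n_no_gene += int(ok.sum())
            continue
        sub_ok = sub[ok].reset_index(drop=True)
        pos_ok = pos0[ok]
        ctx_cpg = ((sub_ok["ref"] == "C").to_numpy() & (right[ok] == "G")) | \
                  ((sub_ok["ref"] == "G").to_numpy() & (left[ok] == "C"))
        in_isl = islands.contains(chrom, pos_ok)

        order = np.argsort(pos_ok, kind="stable")
        pos_sorted = pos_ok[order]
        ex_start, ex_end, ex_gene = exon_index[chrom]
        lo = np.searchsorted(pos_sorted, ex_start, side="left")
        hi = np.searchsorted(pos_sorted, ex_end, side="left")
        sorted_idx, exon_of = _multi_arange(lo, hi)
        rows = order[sorted_idx]          # row index into sub_ok per assignment
        gidx = ex_gene[exon_of]           # gene index per assignment

        n_rec_assigned = len(np.unique(rows))
        report.n_assigned += n_rec_assigned
        report.n_no_gene += len(sub_ok) - n_rec_assigned
        report.n_assignments += len(rows)
        if len(rows) == 0:
            continue

        a_ref = sub_ok["ref"].to_numpy(dtype=object)[rows]
        a_alt = sub_ok["alt"].to_numpy(dtype=object)[rows]
        plus = gene_strand_plus[gidx]
        nts_ref = np.where(plus, a_ref, [ _COMP[b] for b in a_ref ])
        nts_alt = np.where(plus, a_alt, [ _COMP[b] for b in a_alt ])
        purine_on_nts = np.isin(nts_ref, ["A", "G"])
        coll_ref = np.where(purine_on_nts, nts_ref, [ _COMP[b] for b in nts_ref ])
        coll_alt = np.where(purine_on_nts, nts_alt, [ _COMP[b] for b in nts_alt ])
        collapsed = np.char.add(np.char.add(coll_ref.astype(str), ">"),
                                coll_alt.astype(str))
        strand_class = np.where(purine_on_nts, "NTS", "TS")
        cpg_ti = (collapsed == "G>A") & ctx_cpg[rows] & ~in_isl[rows]

        out_frames.append(pd.DataFrame({
            "gene_id": gene_ids[gidx],
            "collapsed_type": collapsed,
            "strand_class": strand_class,
            "cpg_ti": cpg_ti,
            "in_island": in_isl[rows],
            "chrom": chrom,
            "pos": sub_ok["pos"].to_numpy()[rows],
            "ref": a_ref,
            "alt": a_alt,
            "sample_id": sub_ok["sample_id"].to_numpy()[rows],
            "dataset": sub_ok["dataset"].to_numpy()[rows],
        }))

    report.n_ref_mismatch = mismatch_total
    if mismatch_total:
        logger.info("classify_mutations: dropped %d records with reference mismatch",
                    mismatch_total)
    if out_frames:
        classified = pd.concat(out_frames, ignore_index=True)
    else:
        classified = pd.DataFrame(columns=[
            "gene_id", "collapsed_type", "strand_class", "cpg_ti", "in_island",
            "chrom", "pos", "ref", "alt", "sample_id", "dataset"])
    return classified, report


def count_by_gene(classified: pd.DataFrame, gene_ids: Sequence[str],
                  mutation_class: str = "other",
                  collapsed_type: str | None = None,
                  strand_class: str | None = None) -> pd.Series:
    """Per-gene mutation counts for a model outcome.

    ``mutation_class``: "cpg_ti" (CpG transitions outside islands),
    "other" (everything else), or "all".  Alternatively select a single
    ``collapsed_type`` and optionally a ``strand_class`` for the
    strand-resolved models.
    """
    sel = classified
    if collapsed_type is not None:
        sel = sel[sel["collapsed_type"] == collapsed_type]
        if strand_class is not None:
            sel = sel[sel["strand_class"] == strand_class]
    elif mutation_class == "cpg_ti":
        sel = sel[sel["cpg_ti"]]
    elif mutation_class == "other":
        sel = sel[~sel["cpg_ti"]]
    elif mutation_class != "all":
        raise ValueError(f"unknown mutation_class {mutation_class!r}")
    counts = sel.groupby("gene_id").size()
    return counts.reindex(gene_ids, fill_value=0).astype(np.int64)
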