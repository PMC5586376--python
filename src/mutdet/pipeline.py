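"""End-to-end orchestration: features -> mutations -> fits -> asymmetry.

Each stage reads plain-text inputs (FASTA, refFlat TSV, BED/bedGraph,
TSV) and writes TSV/JSON outputs with stable column order and fixed float
formatting, so a rerun under the same configuration and seed is
bit-identical.  A QC report records every dropped sample, gene and
mutation so the conservation identities can be audited.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import asymmetry as asym
from . import features as feat
from . import mutations as mut
from .genes import IntervalSet, read_refflat, union_exons
from .model import ModelSpec, fit_nb_glm
from .opportunities import opportunity_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_features", "stage_classify",
           "stage_fit", "stage_asymmetry"]

_FLOAT_FMT = "%.10g"

TRACK_NAMES = ("replication_timing", "H3K9me3", "H3K27me3")


@dataclasses.dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    genome: str
    genes: str
    expression: str
    mutations: str
    outdir: str
    islands: str | None = None
    tracks: dict | None = None          # name -> bedGraph path
    dataset: str = ""
    mutation_classes: tuple[str, ...] = ("cpg_ti", "other")
    strand_types: tuple[str, ...] = ("A>G",)
    quantiles: int = 4
    bootstrap: int = 100
    seed: int = 0
    hypermutator_method: str = "fence"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("mutation_classes", "strand_types"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        missing = [p for p in [self.genome, self.genes, self.expression,
                               self.mutations, self.islands,
                               *(self.tracks or {}).values()]
                   if p is not None and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


def _load_genome(path):
    import pyfaidx
    return pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)


def _write_tsv(df: pd.DataFrame, path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _load_inputs(cfg: RunConfig):
    cfg.validate()
    genes = union_exons(read_refflat(cfg.genes))
    genome = _load_genome(cfg.genome)
    islands = IntervalSet.from_bed(cfg.islands) if cfg.islands else IntervalSet()
    return genes, genome, islands


def stage_features(cfg: RunConfig) -> dict:
    """Opportunity counts and raw per-gene covariates."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    genes, genome, islands = _load_inputs(cfg)

    opp = opportunity_table(genes, genome, islands)
    _write_tsv(opp, out / "opportunities.tsv", index=True)

    expr = pd.read_csv(cfg.expression, sep="\t", index_col=0).iloc[:, 0]
    cov = pd.DataFrame({"expression": expr})
    for name, path in (cfg.tracks or {}).items():
        track = feat.read_bedgraph(path)
        cov[name] = feat.average_track(genes, track, name)
    cov.index.name = "gene_id"
    _write_tsv(cov, out / "covariates.tsv", index=True)
    return {"opportunities": str(out / "opportunities.tsv"),
            "covariates": str(out / "covariates.tsv"),
            "n_genes": len(genes)}


def stage_classify(cfg: RunConfig) -> dict:
    """Parse, QC-filter and classify mutations."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    genes, genome, islands = _load_inputs(cfg)

    records, parse_counters = mut.parse_mutations(
        cfg.mutations, format="maf_tsv", dataset=cfg.dataset or None)
    kept, qc = mut.filter_hypermutators(records, method=cfg.hypermutator_method)
    _write_tsv(qc, out / "qc_samples.tsv")

    classified, report = mut.classify_mutations(kept, genes, genome, islands)
    _write_tsv(classified, out / "classified.tsv")

    gene_ids = [g.gene_id for g in genes if not g.dual_strand_flag]
    counts = pd.DataFrame({
        "n_cpg_ti": mut.count_by_gene(classified, gene_ids, "cpg_ti"),
        "n_other": mut.count_by_gene(classified, gene_ids, "other"),
        "n_all": mut.count_by_gene(classified, gene_ids, "all"),
        "n_AG_nts": mut.count_by_gene(classified, gene_ids,
                                      collapsed_type="A>G", strand_class="NTS"),
        "n_AG_ts": mut.count_by_gene(classified, gene_ids,
                                     collapsed_type="A>G", strand_class="TS"),
        "n_AT_nts": mut.count_by_gene(classified, gene_ids,
                                      collapsed_type="A>T", strand_class="NTS"),
        "n_AT_ts": mut.count_by_gene(classified, gene_ids,
                                     collapsed_type="A>T", strand_class="TS"),
    })
    counts.index.name = "gene_id"
    _write_tsv(counts, out / "counts_by_gene.tsv", index=True)

    qc_report = {
        "parse": parse_counters,
        "samples_removed": int(qc["removed"].sum()),
        "samples_total": int(len(qc)),
        "classification": dataclasses.asdict(report),
        "conservation_ok": bool(report.conserved()),
    }
    with open(out / "qc_report.json", "w") as fh:
        json.dump(qc_report, fh, indent=2)
    return qc_report


def _build_features(cfg: RunConfig, mutation_class: str) -> feat.FeatureMatrix:
    out = Path(cfg.outdir)
    opp = pd.read_csv(out / "opportunities.tsv", sep="\t", index_col=0)
    cov = pd.read_csv(out / "covariates.tsv", sep="\t", index_col=0)
    predictors = ["expression", *(cfg.tracks or {}).keys(), "gc_content"]
    return feat.build_feature_matrix(cov, opp, mutation_class=mutation_class,
                                     predictors=predictors)


def stage_fit(cfg: RunConfig) -> dict:
    """Separate NB fits per configured mutation class."""
    out = Path(cfg.outdir)
    classified = pd.read_csv(out / "classified.tsv", sep="\t")
    results = {}
    for mclass in cfg.mutation_classes:
        fm = _build_features(cfg, mclass)
        counts = mut.count_by_gene(classified, fm.gene_ids, mclass)
        spec = ModelSpec(mutation_class=mclass,
                         predictors=list(fm.X.columns))
        res = fit_nb_glm(counts, fm, spec)
        res.to_tsv(out / f"fit_{mclass}.tsv")
        res.to_json(out / f"fit_{mclass}.json")
        results[mclass] = res
        if not res.converged:
            logger.warning("fit for class %s did not converge", mclass)
    return results


def stage_asymmetry(cfg: RunConfig) -> dict:
    """Strand spectrum, per-type asymmetry and expression-quantile tables."""
    out = Path(cfg.outdir)
    classified = pd.read_csv(out / "classified.tsv", sep="\t")
    opp = pd.read_csv(out / "opportunities.tsv", sep="\t", index_col=0)
    cov = pd.read_csv(out / "covariates.tsv", sep="\t", index_col=0)

    spectrum, asymmetry = asym.compute_strand_spectrum(
        classified, opp, B=cfg.bootstrap, seed=cfg.seed, dataset=cfg.dataset)
    _write_tsv(spectrum, out / "spectrum.tsv")
    _write_tsv(asymmetry, out / "asymmetry.tsv")

    expr = cov["expression"].reindex(opp.index)
    results = {"spectrum": spectrum, "asymmetry": asymmetry}
    for t in cfg.strand_types:
        quant = asym.asymmetry_by_quantile(
            classified, opp, expr.fillna(0.0), k=cfg.quantiles,
            B=cfg.bootstrap, seed=cfg.seed, collapsed_type=t)
        safe = t.replace(">", "")
        _write_tsv(quant, out / f"quantile_{safe}.tsv")
        results[f"quantile_{safe}"] = quant
    return results


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage in order; returns a bundle of stage summaries."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    bundle = {}
    bundle["features"] = stage_features(cfg)
    bundle["classify"] = stage_classify(cfg)
    bundle["fit"] = stage_fit(cfg)
    bundle["asymmetry"] = stage_asymmetry(cfg)
    return bundle
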