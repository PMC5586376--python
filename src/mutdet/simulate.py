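"""Fully in-silico inputs with the statistical structure the analysis assumes.

The generator produces a random reference with embedded CpG-rich island
segments, stranded multi-exon genes (a small fraction transcribed off both
strands), correlated per-gene covariates on realistic scales, overdispersed
per-gene mutation counts driven by those covariates, and strand-placed A>G
/ A>T mutations with a configurable NTS/TS odds that may depend on
expression.  Every stage is deterministic given the configuration seed, and
every emitted file is in a format the real pipeline readers consume
unmodified (FASTA, refFlat-style TSV, BED, bedGraph, MAF-like TSV).

Default conditions mirror the germline study setting: ~19,000 genes after
filtering, human-like 41% GC, 1.7% dual-strand loci, an A>G NTS/TS ratio
of 1.66, and NB dispersion theta = 2 for per-gene counts.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genes import GeneModel, IntervalSet
from .features import FeatureMatrix

__all__ = [
    "SimulationConfig",
    "simulate_reference",
    "simulate_covariates",
    "simulate_counts",
    "simulate_strand_mutations",
    "write_fixture",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclasses.dataclass
class SimulationConfig:
    """All knobs of the generator; defaults encode the study conditions."""

    seed: int = 0
    n_genes: int = 19000
    chrom_name: str = "chr1"
    # reference sequence
    gc_fraction: float = 0.41
    islands_per_mb: float = 9.0
    island_length: tuple[int, int] = (400, 1500)
    island_gc: float = 0.65
    island_cpg_boost: float = 0.10
    exons_per_gene: tuple[int, int] = (2, 20)
    exon_length: tuple[int, int] = (60, 300)
    intron_length: tuple[int, int] = (100, 400)
    intergenic_length: tuple[int, int] = (200, 800)
    dual_strand_fraction: float = 0.017
    # covariates
    covariate_names: tuple[str, ...] = (
        "expression", "replication_timing", "H3K9me3", "H3K27me3")
    covariate_correlation: tuple[tuple[float, ...], ...] | None = None
    expression_meanlog: float = 1.5
    expression_sdlog: float = 1.5
    zero_inflation: float = 0.2
    # per-gene count model (generative twin of the NB regression)
    beta0: float = math.log(5e-4)
    beta: tuple[float, ...] = (0.1, 0.0, 0.0, -0.1, 0.1)
    theta: float = 2.0
    # strand-placed mutations
    ag_rate: float = 3e-4
    at_rate: float = 1e-4
    background_rate: float = 3e-4
    asymmetry_ratio: float = 1.66
    asymmetry_expression_slope: float = 0.0
    expression_rate_slope: float = 0.2
    strand_theta: float = 2.0
    # samples
    n_samples: int = 200
    hypermutator_fraction: float = 0.0
    hypermutator_multiplier: float = 10.0
    dataset: str = "germline"

    def correlation_matrix(self) -> np.ndarray:
        if self.covariate_correlation is not None:
            m = np.asarray(self.covariate_correlation, dtype=float)
        else:
            # modest, biologically signed defaults: expressed genes replicate
            # early and carry fewer repressive marks
            m = np.array([
                [1.0, 0.3, -0.2, -0.3],
                [0.3, 1.0, -0.2, -0.1],
                [-0.2, -0.2, 1.0, 0.2],
                [-0.3, -0.1, 0.2, 1.0],
            ])
        k = len(self.covariate_names)
        if m.shape != (k, k):
            raise ValueError("correlation matrix shape does not match covariates")
        return m


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


def simulate_reference(config: SimulationConfig):
    """Random genome + gene models + CpG-island intervals.

    Returns (genome dict, list of GeneModel, IntervalSet).  Deterministic
    under ``config.seed``.
    """
    rng = _rng(config, 1)
    if not (0 < config.gc_fraction < 1) or not (0 < config.island_gc < 1):
        raise ValueError("GC fractions must lie in (0, 1)")
    if config.islands_per_mb < 0:
        raise ValueError("island density must be >= 0")

    genes: list[GeneModel] = []
    pos = 0
    digits = max(5, len(str(config.n_genes)))
    for i in range(config.n_genes):
        pos += int(rng.integers(*config.intergenic_length))
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exons = []
        for j in range(n_ex):
            if j:
                pos += int(rng.integers(*config.intron_length))
            ln = int(rng.integers(*config.exon_length))
            exons.append((pos, pos + ln))
            pos += ln
        strand = "+" if rng.random() < 0.5 else "-"
        dual = bool(rng.random() < config.dual_strand_fraction)
        genes.append(GeneModel(f"G{i:0{digits}d}", config.chrom_name, strand,
                               exons, dual))
    total = pos + int(rng.integers(*config.intergenic_length))

    gc = config.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(_BASES, size=total, p=p)

    n_islands = int(rng.poisson(config.islands_per_mb * total / 1e6))
    island_ivs = []
    gci = config.island_gc
    p_isl = np.array([(1 - gci) / 2, gci / 2, gci / 2, (1 - gci) / 2])
    for _ in range(n_islands):
        ln = int(rng.integers(*config.island_length))
        s = int(rng.integers(0, max(total - ln, 1)))
        e = min(s + ln, total)
        island_ivs.append((s, e))
        block = rng.choice(_BASES, size=e - s, p=p_isl)
        # plant explicit CG dinucleotides on top of the GC-rich background
        hits = np.flatnonzero(rng.random(e - s - 1) < config.island_cpg_boost)
        block[hits] = b"C"
        block[hits + 1] = b"G"
        seq[s:e] = block
    islands = IntervalSet({config.chrom_name: island_ivs} if island_ivs else {})

    genome = {config.chrom_name: seq.tobytes().decode()}
    return genome, genes, islands


def simulate_covariates(config: SimulationConfig, genes) -> pd.DataFrame:
    """Correlated per-gene covariates on plausible raw scales.

    Latent scores are multivariate normal with the configured correlation;
    expression is mapped to RPKM by exponentiation with a point mass at
    zero for the lowest latent quantile, replication timing to a
    Repli-Seq-like scale (mean 50, SD 15, higher = earlier), and histone
    marks to positive log-normal enrichments.
    """
    rng = _rng(config, 2)
    corr = config.correlation_matrix()
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariate correlation matrix is not positive-definite") from exc
    n = len(genes)
    z = rng.standard_normal((n, len(config.covariate_names))) @ chol.T
    df = pd.DataFrame(index=pd.Index([g.gene_id for g in genes], name="gene_id"))
    latent = dict(zip(config.covariate_names, z.T))

    ze = latent["expression"]
    rpkm = np.exp(config.expression_meanlog + config.expression_sdlog * ze)
    if config.zero_inflation > 0:
        cut = np.quantile(ze, config.zero_inflation)
        rpkm = np.where(ze < cut, 0.0, rpkm)
    df["expression"] = rpkm
    df["replication_timing"] = 50 + 15 * latent["replication_timing"]
    df["H3K9me3"] = np.exp(0.5 * latent["H3K9me3"])
    df["H3K27me3"] = np.exp(0.5 * latent["H3K27me3"])
    return df


def _nb_draw(rng, mean, theta):
    mean = np.asarray(mean, dtype=float)
    if np.any(mean > 1e9):
        raise ValueError("NB mean overflow; lower beta0 or the rate")
    if not np.isfinite(theta):
        return rng.poisson(mean)
    lam = rng.gamma(theta, mean / theta)
    return rng.poisson(lam)


def simulate_counts(config: SimulationConfig, features: FeatureMatrix,
                    mutation_class: str = "other") -> pd.Series:
    """Per-gene NB counts from the generative twin of the rate model.

    mean_i = L_i * exp(beta0 + x_i . beta) with the class-appropriate
    exposure L and standardized features x.
    """
    rng = _rng(config, 3)
    off_col = "L_cpg" if mutation_class == "cpg_ti" else "L_all"
    L = features.offsets[off_col].to_numpy(dtype=float)
    X = features.X.to_numpy()
    beta = np.asarray(config.beta, dtype=float)[: X.shape[1]]
    mu = L * np.exp(config.beta0 + X @ beta)
    counts = _nb_draw(rng, mu, config.theta)
    return pd.Series(counts, index=features.X.index, name="count")


def _exonic_base_positions(gene: GeneModel, chrom_seq: str, base: str) -> np.ndarray:
    """0-based exonic positions whose + strand base equals ``base``."""
    chunks = []
    for s, e in gene.exons:
        seg = np.frombuffer(chrom_seq[s:e].encode(), dtype="S1")
        chunks.append(np.flatnonzero(seg == base.encode()) + s)
    return np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)


def simulate_strand_mutations(
    config: SimulationConfig,
    genes,
    genome,
    expression_z: pd.Series | None = None,
) -> pd.DataFrame:
    """Strand-placed mutation records emitted as a MAF-like table.

    Per gene, A>G (and A>T) totals are NB draws whose mean scales with the
    strand opportunities (and optionally with expression); each mutation
    lands on the NTS with odds rho(x) weighted by the per-strand A counts.
    A uniform background over exonic sites adds the remaining types.
    Hypermutator samples receive a ``hypermutator_multiplier``-fold share
    of records.
    """
    if config.asymmetry_ratio <= 0:
        raise ValueError("asymmetry ratio must be > 0")
    rng = _rng(config, 4)

    rows_chrom: list[np.ndarray] = []
    rows_pos: list[np.ndarray] = []
    rows_ref: list[np.ndarray] = []
    rows_alt: list[np.ndarray] = []

    def emit(pos_arr, ref, alt, chrom):
        rows_chrom.append(np.full(len(pos_arr), chrom, dtype=object))
        rows_pos.append(pos_arr + 1)  # 1-based out
        rows_ref.append(np.full(len(pos_arr), ref, dtype=object))
        rows_alt.append(np.full(len(pos_arr), alt, dtype=object))

    for gene in genes:
        chrom_seq = genome[gene.chrom]
        plus_A = _exonic_base_positions(gene, chrom_seq, "A")
        plus_T = _exonic_base_positions(gene, chrom_seq, "T")
        if gene.strand == "+":
            nts_A, ts_A = plus_A, plus_T       # TS A sites read T on + strand
        else:
            nts_A, ts_A = plus_T, plus_A
        L_n, L_t = len(nts_A), len(ts_A)
        if L_n + L_t == 0:
            continue
        x = 0.0
        if expression_z is not None:
            x = float(expression_z.get(gene.gene_id, 0.0))
        rho = max(config.asymmetry_ratio + config.asymmetry_expression_slope * x,
                  0.05)
        rate_mod = math.exp(config.expression_rate_slope * x)

        for per_site_rate, alt_nts, alt_ts in (
            (config.ag_rate, "G", "C"),   # A>G: + strand A>G on NTS-A, T>C on TS-A
            (config.at_rate, "T", "A"),
        ):
            if per_site_rate <= 0:
                continue
            mean = per_site_rate * rate_mod * (L_n + L_t)
            n_i = int(_nb_draw(rng, np.array([mean]), config.strand_theta)[0])
            if n_i == 0:
                continue
            p_nts = rho * L_n / (rho * L_n + L_t) if (rho * L_n + L_t) > 0 else 0.0
            k_n = int(rng.binomial(n_i, p_nts))
            k_t = n_i - k_n
            if k_n and L_n:
                sites = nts_A[rng.integers(0, L_n, k_n)]
                if gene.strand == "+":
                    emit(sites, "A", alt_nts, gene.chrom)
                else:
                    emit(sites, "T", {"G": "C", "T": "A"}[alt_nts], gene.chrom)
            if k_t and L_t:
                sites = ts_A[rng.integers(0, L_t, k_t)]
                if gene.strand == "+":
                    emit(sites, "T", {"C": "C", "A": "A"}[alt_ts], gene.chrom)
                else:
                    emit(sites, "A", {"C": "G", "A": "T"}[alt_ts], gene.chrom)

    # uniform background over exonic sites, any substitution
    if config.background_rate > 0:
        for chrom in sorted({g.chrom for g in genes}):
            chrom_seq = genome[chrom]
            arr = np.frombuffer(chrom_seq.encode(), dtype="S1")
            exonic = IntervalSet({chrom: [iv for g in genes if g.chrom == chrom
                                          for iv in g.exons]})
            positions = np.flatnonzero(exonic.mask(chrom, 0, len(arr)))
            if len(positions) == 0:
                continue
            k = int(rng.poisson(config.background_rate * len(positions)))
            if k == 0:
                continue
            sites = positions[rng.integers(0, len(positions), k)]
            refs = arr[sites].astype("U1")
            good = np.isin(refs, list("ACGT"))
            sites, refs = sites[good], refs[good]
            alt_choice = rng.integers(0, 3, len(sites))
            alts = np.empty(len(sites), dtype=object)
            # A>G and A>T (and their complements) belong exclusively to the
            # strand-placed process above; the background covers the rest
            allowed = {"A": ["C"], "T": ["G"],
                       "C": ["A", "G", "T"], "G": ["A", "C", "T"]}
            for b in "ACGT":
                m = refs == b
                opts = allowed[b]
                alts[m] = np.array(opts, dtype=object)[alt_choice[m] % len(opts)]
            emit(sites, None, None, chrom)
            rows_ref[-1] = refs.astype(object)
            rows_alt[-1] = alts

    if rows_pos:
        df = pd.DataFrame({
            "chrom": np.concatenate(rows_chrom),
            "pos": np.concatenate(rows_pos).astype(np.int64),
            "ref": np.concatenate(rows_ref),
            "alt": np.concatenate(rows_alt),
        })
    else:
        df = pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])

    # sample assignment with optional planted hypermutators
    n_hyper = int(round(config.hypermutator_fraction * config.n_samples))
    weights = np.ones(config.n_samples)
    weights[:n_hyper] = config.hypermutator_multiplier
    weights /= weights.sum()
    digits = max(4, len(str(config.n_samples)))
    sample_ids = np.array([f"S{i:0{digits}d}" for i in range(config.n_samples)],
                          dtype=object)
    df["sample_id"] = sample_ids[rng.choice(config.n_samples, size=len(df), p=weights)]
    df["dataset"] = config.dataset
    df = df.sort_values(["chrom", "pos", "sample_id", "ref", "alt"],
                        kind="mergesort").reset_index(drop=True)
    return df


def hypermutator_sample_ids(config: SimulationConfig) -> list[str]:
    """The sample ids planted as hypermutators by the generator."""
    n_hyper = int(round(config.hypermutator_fraction * config.n_samples))
    digits = max(4, len(str(config.n_samples)))
    return [f"S{i:0{digits}d}" for i in range(n_hyper)]


# ---------------------------------------------------------------------------
# file emission

def _write_fasta(genome: dict, path: Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            s = genome[chrom]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def _write_refflat(genes, path: Path, rng: np.random.Generator) -> None:
    """Transcript records: every gene gets 1-2 transcripts (a random exon
    subset as the second) and dual-strand genes an opposite-strand one."""
    with open(path, "w") as fh:
        for g in genes:
            ss = ",".join(str(s) for s, _ in g.exons) + ","
            ee = ",".join(str(e) for _, e in g.exons) + ","
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{ss}\t{ee}\n")
            if len(g.exons) > 2 and rng.random() < 0.3:
                k = int(rng.integers(1, len(g.exons)))
                sub = g.exons[:k + 1]
                ss2 = ",".join(str(s) for s, _ in sub) + ","
                ee2 = ",".join(str(e) for _, e in sub) + ","
                fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{ss2}\t{ee2}\n")
            if g.dual_strand_flag:
                other = "-" if g.strand == "+" else "+"
                fh.write(f"{g.gene_id}\t{g.chrom}\t{other}\t{ss}\t{ee}\n")


def _write_bedgraph(genes, values: pd.Series, path: Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            v = values.get(g.gene_id, np.nan)
            if not np.isnan(v):
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{v:.6g}\n")


def write_fixture(config: SimulationConfig, outdir) -> dict:
    """Generate and write a complete input bundle; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, islands = simulate_reference(config)
    covariates = simulate_covariates(config, genes)

    expr = covariates["expression"]
    logexpr = np.log(expr + (expr[expr > 0].min() / 2 if (expr > 0).any() else 0.5))
    expr_z = pd.Series(
        (logexpr - logexpr.mean()) / logexpr.std(ddof=0), index=covariates.index)
    mutations = simulate_strand_mutations(config, genes, genome, expression_z=expr_z)

    files = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.refflat",
        "islands": outdir / "islands.bed",
        "expression": outdir / "expression.tsv",
        "replication_timing": outdir / "replication_timing.bedgraph",
        "H3K9me3": outdir / "H3K9me3.bedgraph",
        "H3K27me3": outdir / "H3K27me3.bedgraph",
        "mutations": outdir / "mutations.tsv",
        "manifest": outdir / "manifest.yaml",
    }
    _write_fasta(genome, files["genome"])
    _write_refflat(genes, files["genes"], _rng(config, 5))
    islands.to_bed(files["islands"])
    covariates["expression"].rename("value").to_csv(
        files["expression"], sep="\t", float_format="%.6g")
    for name in ("replication_timing", "H3K9me3", "H3K27me3"):
        _write_bedgraph(genes, covariates[name], files[name])
    mutations.to_csv(files["mutations"], sep="\t", index=False)
    with open(files["manifest"], "w") as fh:
        yaml.safe_dump({"config": dataclasses.asdict(config)}, fh,
                       default_flow_style=False, sort_keys=True)
    return {k: str(v) for k, v in files.items()}
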