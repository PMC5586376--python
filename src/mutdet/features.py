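"""Covariate tracks, per-gene averaging, and the standardized design matrix.

Covariates enter the rate models as z-scores so effect sizes are comparable
within a model.  Expression (RPKM) is first offset by half of the smallest
nonzero value and log-transformed; all other covariates are z-scored on
their raw scale.  Genes missing any covariate, or with zero exposure for
the requested mutation class, are dropped (with a recorded reason) before
standardization.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genes import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "Track",
    "read_bedgraph",
    "average_track_over_gene",
    "average_track",
    "log_transform_expression",
    "FeatureMatrix",
    "build_feature_matrix",
    "EXPRESSION",
    "DEFAULT_PREDICTORS",
]

EXPRESSION = "expression"
DEFAULT_PREDICTORS = ["expression", "replication_timing", "H3K9me3", "H3K27me3", "gc_content"]

_CLASS_OFFSETS = {"cpg_ti": "L_cpg", "other": "L_all", "all": "L_all"}


class Track:
    """A windowed numeric genome track (bedGraph semantics)."""

    def __init__(self, windows: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # per chrom: (starts, ends, values) sorted by start
        self._data = {}
        for chrom, (starts, ends, values) in windows.items():
            order = np.argsort(starts, kind="stable")
            self._data[chrom] = (
                np.asarray(starts, dtype=np.int64)[order],
                np.asarray(ends, dtype=np.int64)[order],
                np.asarray(values, dtype=float)[order],
            )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Track":
        grouped = {}
        for chrom, sub in df.groupby(df.columns[0], sort=False):
            grouped[str(chrom)] = (
                sub.iloc[:, 1].to_numpy(),
                sub.iloc[:, 2].to_numpy(),
                sub.iloc[:, 3].to_numpy(),
            )
        return cls(grouped)

    def overlapping_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Values of all windows intersecting [start, end)."""
        if chrom not in self._data:
            return np.empty(0)
        starts, ends, values = self._data[chrom]
        hi = np.searchsorted(starts, end, side="left")
        # windows may overlap each other; bound the scan with a running max of ends
        cummax = np.maximum.accumulate(ends[:hi]) if hi else ends[:0]
        lo = int(np.searchsorted(cummax, start, side="right"))
        sel = ends[lo:hi] > start
        return values[lo:hi][sel]


def read_bedgraph(path) -> Track:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    return Track.from_frame(df)


def average_track_over_gene(gene: GeneModel, track: Track) -> float:
    """Unweighted mean of track windows overlapping the gene span.

    The span runs from the first exon start to the last exon end (introns
    included); each overlapping window contributes one data point
    regardless of the extent of overlap.  Returns NaN when nothing
    overlaps, which later excludes the gene from model fits.
    """
    vals = track.overlapping_values(gene.chrom, gene.start, gene.end)
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def average_track(genes: Sequence[GeneModel], track: Track, name: str = "value") -> pd.Series:
    out = pd.Series(
        [average_track_over_gene(g, track) for g in genes],
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
        name=name,
    )
    return out


def log_transform_expression(rpkm: pd.Series) -> pd.Series:
    """log(RPKM + half of the smallest nonzero RPKM).

    The pseudocount keeps zero-expression genes in the analysis while
    preserving the ordering of low expressers.
    """
    vals = rpkm.astype(float)
    nonzero = vals[vals > 0]
    if nonzero.empty:
        raise ValueError("expression column has no nonzero values")
    pseudo = nonzero.min() / 2.0
    return np.log(vals + pseudo)


@dataclasses.dataclass
class FeatureMatrix:
    """Standardized per-gene design matrix with exposures.

    Attributes
    ----------
    X : DataFrame
        z-scored predictor columns, indexed by gene_id.
    raw_values : DataFrame
        The same columns before standardization (expression already
        log-transformed).
    offsets : DataFrame
        Per-gene exposure columns (L_cpg, L_all, nts_A, ts_A, ...).
    standardization : DataFrame
        mean/sd used per column, for reuse on new data.
    dropped : DataFrame
        gene_id and reason for every excluded gene.
    """

    X: pd.DataFrame
    raw_values: pd.DataFrame
    offsets: pd.DataFrame
    standardization: pd.DataFrame
    dropped: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.X.index)


def build_feature_matrix(
    covariates: pd.DataFrame,
    opportunities: pd.DataFrame,
    mutation_class: str = "other",
    predictors: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Assemble the standardized design matrix for one dataset.

    Parameters
    ----------
    covariates : DataFrame indexed by gene_id
        Raw covariate columns; must include ``expression`` (RPKM scale) if
        expression is among the predictors.  ``gc_content``, if requested
        and absent, is taken from the opportunity table's gc_fraction.
    opportunities : DataFrame indexed by gene_id
        Output of :func:`mutdet.opportunities.opportunity_table`.
    mutation_class : {"cpg_ti", "other", "all"}
        Chooses the exposure whose zero entries disqualify a gene
        (L_cpg for CpG transitions, L_all otherwise).
    """
    if mutation_class not in _CLASS_OFFSETS:
        raise ValueError(f"unknown mutation_class {mutation_class!r}")
    predictors = list(predictors) if predictors is not None else list(DEFAULT_PREDICTORS)

    cov = covariates.copy()
    if "gc_content" in predictors and "gc_content" not in cov.columns:
        cov = cov.join(opportunities["gc_fraction"].rename("gc_content"), how="left")
    missing_cols = [p for p in predictors if p not in cov.columns]
    if missing_cols:
        raise ValueError(f"missing covariate columns: {missing_cols}")
    cov = cov[predictors]

    common = cov.index.intersection(opportunities.index)
    dropped: list[tuple[str, str]] = []
    for gid in cov.index.difference(opportunities.index):
        dropped.append((gid, "no opportunity counts"))

    cov = cov.loc[common]
    offs = opportunities.loc[common]

    offset_col = _CLASS_OFFSETS[mutation_class]
    incomplete = cov.isna().any(axis=1)
    zero_exp = offs[offset_col] <= 0
    for gid in cov.index[incomplete]:
        dropped.append((gid, "missing covariate"))
    for gid in cov.index[~incomplete & zero_exp]:
        dropped.append((gid, f"zero exposure ({offset_col})"))
    keep = ~incomplete & ~zero_exp
    cov, offs = cov.loc[keep], offs.loc[keep]
    if len(cov) < 2:
        raise ValueError("fewer than 2 genes with complete covariates")
    if dropped:
        logger.info("build_feature_matrix: dropped %d genes", len(dropped))

    raw = cov.astype(float).copy()
    if EXPRESSION in raw.columns:
        raw[EXPRESSION] = log_transform_expression(raw[EXPRESSION])

    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=0)
    zero_var = sds[sds == 0].index.tolist()
    if zero_var:
        raise ValueError(f"zero variance in covariate column(s): {zero_var}")
    X = (raw - means) / sds

    return FeatureMatrix(
        X=X,
        raw_values=raw,
        offsets=offs,
        standardization=pd.DataFrame({"mean": means, "sd": sds}),
        dropped=pd.DataFrame(dropped, columns=["gene_id", "reason"]),
    )
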