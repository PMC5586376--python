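"""Model specifications and fit wrappers for the mutation-rate regressions.

Two layouts are supported:

* separate fits — one NB regression per dataset and mutation class, with
  the class-appropriate exposure offset;
* combined fits — two groups (tissues, or mutation classes) stacked into
  one design with a 0/1 contrast variable interacting with every
  predictor, so the interaction coefficients estimate effect-size
  differences between groups and their Wald p-values test them.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import DEFAULT_PREDICTORS, FeatureMatrix
from .nbglm import NegativeBinomialGLM

__all__ = ["ModelSpec", "NBFitResult", "fit_nb_glm", "fit_combined_model"]

_CLASS_OFFSETS = {"cpg_ti": "L_cpg", "other": "L_all", "all": "L_all"}


@dataclasses.dataclass
class ModelSpec:
    """Declarative description of one regression.

    ``offset_source`` defaults to the exposure implied by the mutation
    class: the CpG-site count for CpG transitions, all exonic nucleotides
    otherwise; strand-resolved fits override it with a per-strand base
    count column (e.g. ``nts_A``).
    """

    mutation_class: str = "other"
    predictors: Sequence[str] = tuple(DEFAULT_PREDICTORS)
    contrast: str | None = None
    reference_level: str | None = None
    offset_source: str | None = None

    def offset_column(self) -> str:
        if self.offset_source is not None:
            return self.offset_source
        if self.mutation_class not in _CLASS_OFFSETS:
            raise ValueError(f"unknown mutation_class {self.mutation_class!r}")
        return _CLASS_OFFSETS[self.mutation_class]


@dataclasses.dataclass
class NBFitResult:
    """Coefficient table plus dispersion and convergence diagnostics."""

    table: pd.DataFrame          # term, estimate, se, z, p
    theta: float
    theta_se: float
    loglik: float
    n_iter: int
    converged: bool
    n_genes: int
    spec: ModelSpec | None = None

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.set_index("term").loc[term]

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "estimate"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def to_json(self, path=None):
        payload = {
            "terms": self.table.to_dict(orient="records"),
            "theta": self.theta,
            "theta_se": self.theta_se,
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "n_genes": self.n_genes,
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _result_from_estimator(est: NegativeBinomialGLM, n_genes: int,
                           spec: ModelSpec | None) -> NBFitResult:
    table = pd.DataFrame({
        "term": est.term_names_,
        "estimate": est.params_,
        "se": est.bse_,
        "z": est.zvalues_,
        "p": est.pvalues_,
    })
    return NBFitResult(
        table=table,
        theta=est.theta_,
        theta_se=est.theta_se_,
        loglik=est.loglik_,
        n_iter=est.n_iter_,
        converged=est.converged_,
        n_genes=n_genes,
        spec=spec,
    )


def _align(counts: pd.Series, features: FeatureMatrix, spec: ModelSpec):
    X = features.X[list(spec.predictors)]
    counts = counts.reindex(X.index)
    if counts.isna().any():
        raise ValueError("counts missing for some feature-matrix genes")
    off_col = spec.offset_column()
    L = features.offsets[off_col].to_numpy(dtype=float)
    if np.any(L <= 0):
        raise ValueError(f"non-positive exposure in offset column {off_col!r}")
    return X, counts.to_numpy(dtype=float), np.log(L)


def fit_nb_glm(counts: pd.Series, features: FeatureMatrix,
               spec: ModelSpec | None = None, theta: float | None = None) -> NBFitResult:
    """Fit one NB rate model: counts ~ predictors, offset log(L)."""
    spec = spec or ModelSpec()
    X, y, log_L = _align(counts, features, spec)
    est = NegativeBinomialGLM(theta=theta)
    est.fit(X.to_numpy(), y, offset=log_L, feature_names=list(X.columns))
    return _result_from_estimator(est, len(y), spec)


def fit_combined_model(
    counts_by_group: Mapping[str, pd.Series],
    features_by_group: Mapping[str, FeatureMatrix],
    spec: ModelSpec | None = None,
    theta: float | None = None,
) -> NBFitResult:
    """Fit the two-group contrast model.

    The reference group (``spec.reference_level``, default: first key)
    contributes main effects beta_1..beta_k; the other group adds a main
    contrast term C and interaction terms C:predictor estimating how each
    effect differs from the reference.  Each group keeps its own covariate
    standardization, as produced by its FeatureMatrix.
    """
    spec = spec or ModelSpec(contrast="group")
    levels = list(counts_by_group)
    if len(levels) != 2:
        raise ValueError(f"contrast requires exactly 2 levels, got {levels}")
    ref = spec.reference_level if spec.reference_level is not None else levels[0]
    if ref not in levels:
        raise ValueError(f"reference level {ref!r} not among {levels}")
    other = next(l for l in levels if l != ref)

    blocks, ys, offs = [], [], []
    preds = list(spec.predictors)
    for level, is_other in ((ref, 0.0), (other, 1.0)):
        feats = features_by_group[level]
        X, y, log_L = _align(counts_by_group[level], feats, spec)
        Xv = X.to_numpy()
        c = np.full((len(y), 1), is_other)
        blocks.append(np.hstack([Xv, c, c * Xv]))
        ys.append(y)
        offs.append(log_L)
    design = np.vstack(blocks)
    y = np.concatenate(ys)
    log_L = np.concatenate(offs)
    names = preds + [f"C[{other}]"] + [f"C[{other}]:{p}" for p in preds]

    est = NegativeBinomialGLM(theta=theta)
    est.fit(design, y, offset=log_L, feature_names=names)
    return _result_from_estimator(est, len(y), spec)
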