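"""Strand-resolved mutation spectra, asymmetry ratios and their inference.

For each collapsed type the mutation rate on the non-transcribed strand
(NTS) and transcribed strand (TS) is the total count divided by the total
number of sites at which that change could occur on that strand.  The
asymmetry ratio rate_NTS / rate_TS exceeds 1 when transcription-coupled
repair (or strand-biased damage) spares the transcribed strand.

Confidence intervals come from a bootstrap over individual mutation
records (opportunities held fixed): resampling N records with replacement
and recounting categories is distributionally identical to drawing the
category counts from a multinomial with the observed proportions, which
is how it is computed.  A gene-level bootstrap (resampling genes with
their counts and opportunities) is available as an alternative unit.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMatrix
from .model import ModelSpec, NBFitResult, fit_nb_glm
from .mutations import COLLAPSED_TYPES, count_by_gene

__all__ = [
    "strand_opportunity",
    "compute_strand_spectrum",
    "chisq_homogeneity",
    "asymmetry_by_quantile",
    "fit_per_strand_model",
]

_PCT = (2.5, 97.5)


def _type_ref_base(collapsed_type: str) -> str:
    return collapsed_type[0]  # "A" or "G"


def strand_opportunity(opportunities: pd.DataFrame, collapsed_type: str,
                       strand_class: str) -> float:
    """Total sites at which this change could arise on this strand."""
    base = _type_ref_base(collapsed_type)
    col = ("nts_" if strand_class == "NTS" else "ts_") + base
    return float(opportunities[col].sum())


def _percentiles(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = np.nanpercentile(arr, _PCT, axis=0)
    return lo, hi


def compute_strand_spectrum(
    classified: pd.DataFrame,
    opportunities: pd.DataFrame,
    B: int = 100,
    seed: int | None = None,
    unit: str = "mutation",
    dataset: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The 12-type strand-resolved spectrum with bootstrap 95% CIs.

    Returns ``(spectrum, asymmetry)``: per (type, strand) rates with CIs,
    and per-type NTS/TS ratios with CIs and a chi-squared test of the
    observed strand counts against opportunity-proportional expectations.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)

    cells = [(t, s) for t in COLLAPSED_TYPES for s in ("NTS", "TS")]
    obs = classified.groupby(["collapsed_type", "strand_class"]).size()
    counts = np.array([obs.get(c, 0) for c in cells], dtype=float)
    opp = np.array([strand_opportunity(opportunities, t, s) for t, s in cells])

    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(opp > 0, counts / opp, np.nan)

    N = int(counts.sum())
    if unit == "mutation":
        if N > 0:
            boot = rng.multinomial(N, counts / N, size=B).astype(float)
        else:
            boot = np.zeros((B, len(cells)))
        boot_opp = np.broadcast_to(opp, boot.shape)
    elif unit == "gene":
        genes = opportunities.index
        per_gene = (
            classified.groupby(["gene_id", "collapsed_type", "strand_class"])
            .size().unstack(["collapsed_type", "strand_class"], fill_value=0)
        )
        cnt_mat = np.zeros((len(genes), len(cells)))
        for j, c in enumerate(cells):
            if c in per_gene.columns:
                cnt_mat[:, j] = per_gene[c].reindex(genes, fill_value=0).to_numpy()
        opp_mat = np.column_stack([
            opportunities[("nts_" if s == "NTS" else "ts_") + _type_ref_base(t)].to_numpy(float)
            for t, s in cells])
        boot = np.empty((B, len(cells)))
        boot_opp = np.empty((B, len(cells)))
        for b in range(B):
            idx = rng.integers(0, len(genes), len(genes))
            boot[b] = cnt_mat[idx].sum(axis=0)
            boot_opp[b] = opp_mat[idx].sum(axis=0)
    else:
        raise ValueError(f"unknown bootstrap unit {unit!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        boot_rates = np.where(boot_opp > 0, boot / boot_opp, np.nan)
    rate_lo, rate_hi = _percentiles(boot_rates)

    spectrum = pd.DataFrame({
        "dataset": dataset,
        "collapsed_type": [t for t, _ in cells],
        "strand_class": [s for _, s in cells],
        "count": counts.astype(int),
        "opportunity": opp,
        "rate": rates,
        "ci_lo": rate_lo,
        "ci_hi": rate_hi,
    })

    rows = []
    for t in COLLAPSED_TYPES:
        i_n, i_t = cells.index((t, "NTS")), cells.index((t, "TS"))
        r_n, r_t = rates[i_n], rates[i_t]
        if np.isnan(r_n) or np.isnan(r_t):
            ratio, lo, hi, inf_flag = np.nan, np.nan, np.nan, False
        elif r_t == 0:
            ratio, lo, hi, inf_flag = np.inf, np.nan, np.nan, True
        else:
            ratio = r_n / r_t
            with np.errstate(divide="ignore", invalid="ignore"):
                br = boot_rates[:, i_n] / boot_rates[:, i_t]
            br = br[np.isfinite(br)]
            if len(br) >= 2:
                lo, hi = np.percentile(br, _PCT)
            else:
                lo = hi = np.nan
            inf_flag = False
        n_pair = counts[i_n] + counts[i_t]
        o_n, o_t = opp[i_n], opp[i_t]
        if n_pair > 0 and o_n + o_t > 0 and o_n > 0 and o_t > 0:
            e = n_pair * np.array([o_n, o_t]) / (o_n + o_t)
            chi2 = float(np.sum((np.array([counts[i_n], counts[i_t]]) - e) ** 2 / e))
            p = float(stats.chi2.sf(chi2, 1))
        else:
            chi2, p = np.nan, np.nan
        rows.append({
            "dataset": dataset, "collapsed_type": t, "ratio": ratio,
            "ci_lo": lo, "ci_hi": hi, "ratio_infinite": inf_flag,
            "chi2": chi2, "p": p,
            "count_nts": int(counts[i_n]), "count_ts": int(counts[i_t]),
            "opp_nts": o_n, "opp_ts": o_t,
        })
    asymmetry = pd.DataFrame(rows)
    return spectrum, asymmetry


def chisq_homogeneity(tables: pd.DataFrame | Mapping[str, Mapping[str, float]],
                      simulate_p: bool = False, n_sim: int = 10000,
                      seed: int | None = None):
    """Test whether strand asymmetry differs across datasets.

    ``tables``: one row per dataset with columns ``count_nts``,
    ``count_ts``, ``opp_nts``, ``opp_ts`` (as produced by
    :func:`compute_strand_spectrum` for one type).  Expected counts give
    each dataset the pooled per-strand rates scaled by its own
    opportunities; with equal opportunities this is the textbook Pearson
    chi-squared on the k x 2 table.  df = k - 1.

    Returns (statistic, df, p).  When any expected cell is below 5 a
    warning is raised and ``simulate_p=True`` computes a Monte-Carlo p
    instead of the asymptotic one.
    """
    df_t = pd.DataFrame(tables).T if isinstance(tables, Mapping) else pd.DataFrame(tables)
    k = len(df_t)
    if k < 2:
        raise ValueError("need >= 2 datasets")
    n_n = df_t["count_nts"].to_numpy(float)
    n_t = df_t["count_ts"].to_numpy(float)
    o_n = df_t["opp_nts"].to_numpy(float)
    o_t = df_t["opp_ts"].to_numpy(float)

    def statistic(nn, nt):
        r_n = nn.sum() / o_n.sum()
        r_t = nt.sum() / o_t.sum()
        tot = nn + nt
        p_i = (o_n * r_n) / (o_n * r_n + o_t * r_t)
        e_n = tot * p_i
        e_t = tot * (1 - p_i)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = (nn - e_n) ** 2 / e_n + (nt - e_t) ** 2 / e_t
        return float(np.nansum(terms)), e_n, e_t

    stat, e_n, e_t = statistic(n_n, n_t)
    dof = k - 1
    small = (np.concatenate([e_n, e_t]) < 5).any()
    if small:
        warnings.warn("expected cell count < 5; consider simulate_p=True")
    if simulate_p:
        rng = np.random.default_rng(seed)
        tot = (n_n + n_t).astype(int)
        r_n = n_n.sum() / o_n.sum()
        r_t = n_t.sum() / o_t.sum()
        p_i = (o_n * r_n) / (o_n * r_n + o_t * r_t)
        exceed = 0
        for _ in range(n_sim):
            sim_n = rng.binomial(tot, p_i)
            s, _, _ = statistic(sim_n.astype(float), (tot - sim_n).astype(float))
            if s >= stat - 1e-12:
                exceed += 1
        p = (exceed + 1) / (n_sim + 1)
    else:
        p = float(stats.chi2.sf(stat, dof))
    return stat, dof, p


def asymmetry_by_quantile(
    classified: pd.DataFrame,
    opportunities: pd.DataFrame,
    expression: pd.Series,
    k: int = 4,
    B: int = 100,
    seed: int | None = None,
    collapsed_type: str = "A>G",
) -> pd.DataFrame:
    """Per-expression-quantile strand asymmetry and pooled rate.

    Genes are ranked by expression (ties broken by gene id) and split
    into ``k`` near-equal bins (earlier bins at most one gene larger).
    Within each bin the NTS/TS ratio and the pooled two-strand rate are
    computed with bootstrap CIs (mutation-level resampling).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    base = _type_ref_base(collapsed_type)

    genes = opportunities.index
    expr = expression.reindex(genes)
    if expr.isna().any():
        raise ValueError("expression missing for some genes")
    order = expr.sort_index().sort_values(kind="mergesort").index
    bins = np.array_split(np.asarray(order, dtype=object), k)
    bin_of = {g: i for i, bb in enumerate(bins) for g in bb}

    sel = classified[classified["collapsed_type"] == collapsed_type]
    sel = sel[sel["gene_id"].isin(bin_of)]
    cat_bin = sel["gene_id"].map(bin_of).to_numpy(dtype=int) if len(sel) else np.empty(0, int)
    cat_nts = (sel["strand_class"] == "NTS").to_numpy() if len(sel) else np.empty(0, bool)
    cat = cat_bin * 2 + (~cat_nts).astype(int)  # 2q = NTS, 2q+1 = TS
    counts = np.bincount(cat, minlength=2 * k).astype(float)

    opp_n = np.array([opportunities.loc[bb, f"nts_{base}"].sum() for bb in bins], float)
    opp_t = np.array([opportunities.loc[bb, f"ts_{base}"].sum() for bb in bins], float)

    N = int(counts.sum())
    if N > 0:
        boot = rng.multinomial(N, counts / N, size=B).astype(float)
    else:
        boot = np.zeros((B, 2 * k))

    rows = []
    for q in range(k):
        nn, nt = counts[2 * q], counts[2 * q + 1]
        on, ot = opp_n[q], opp_t[q]
        if on <= 0 or ot <= 0:
            rows.append({"quantile": q + 1, "n_genes": len(bins[q]),
                         "count_nts": int(nn), "count_ts": int(nt),
                         "opp_nts": on, "opp_ts": ot,
                         "ratio": np.nan, "ratio_lo": np.nan, "ratio_hi": np.nan,
                         "rate": np.nan, "rate_lo": np.nan, "rate_hi": np.nan})
            continue
        ratio = (nn / on) / (nt / ot) if nt > 0 else np.inf
        rate = (nn + nt) / (on + ot)
        with np.errstate(divide="ignore", invalid="ignore"):
            br = (boot[:, 2 * q] / on) / (boot[:, 2 * q + 1] / ot)
            brate = (boot[:, 2 * q] + boot[:, 2 * q + 1]) / (on + ot)
        fin = br[np.isfinite(br)]
        r_lo, r_hi = (np.percentile(fin, _PCT) if len(fin) >= 2 else (np.nan, np.nan))
        p_lo, p_hi = np.percentile(brate, _PCT)
        rows.append({"quantile": q + 1, "n_genes": len(bins[q]),
                     "count_nts": int(nn), "count_ts": int(nt),
                     "opp_nts": on, "opp_ts": ot,
                     "ratio": ratio, "ratio_lo": r_lo, "ratio_hi": r_hi,
                     "rate": rate, "rate_lo": p_lo, "rate_hi": p_hi})
    return pd.DataFrame(rows)


def fit_per_strand_model(
    classified: pd.DataFrame,
    features: FeatureMatrix,
    collapsed_type: str = "A>G",
    strand_class: str = "NTS",
    theta: float | None = None,
) -> NBFitResult:
    """NB regression of one type's counts on one strand.

    The exposure is the per-gene count of the type's reference purine on
    the requested strand (e.g. As on the NTS for A>G NTS fits).  Genes
    with zero strand opportunity are dropped.
    """
    base = _type_ref_base(collapsed_type)
    off_col = ("nts_" if strand_class == "NTS" else "ts_") + base
    keep = features.offsets[off_col] > 0
    feats = dataclasses.replace(
        features,
        X=features.X.loc[keep],
        raw_values=features.raw_values.loc[keep],
        offsets=features.offsets.loc[keep],
    )
    counts = count_by_gene(classified, feats.gene_ids,
                           collapsed_type=collapsed_type,
                           strand_class=strand_class)
    spec = ModelSpec(mutation_class="all",
                     predictors=list(features.X.columns),
                     offset_source=off_col)
    return fit_nb_glm(counts, feats, spec, theta=theta)
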