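"""Strand spectrum, asymmetry ratios, homogeneity test, quantile analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mutdet.asymmetry import (asymmetry_by_quantile, chisq_homogeneity,
                              compute_strand_spectrum, fit_per_strand_model)
from mutdet.features import FeatureMatrix


def make_classified(cells):
    """cells: list of (gene_id, collapsed_type, strand_class, n)."""
    rows = []
    for gid, t, s, n in cells:
        rows += [{"gene_id": gid, "collapsed_type": t, "strand_class": s,
                  "cpg_ti": False, "in_island": False, "chrom": "chr1",
                  "pos": 1, "ref": "A", "alt": "G", "sample_id": "s",
                  "dataset": "d"}] * n
    return pd.DataFrame(rows)


def make_opp(gene_ids, nts_A=1000, ts_A=1000, **kw):
    df = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    for b in "ACGT":
        df[f"nts_{b}"] = kw.get(f"nts_{b}", nts_A if b == "A" else 500)
        df[f"ts_{b}"] = kw.get(f"ts_{b}", ts_A if b == "A" else 500)
    df["L_cpg"], df["L_all"], df["gc_fraction"] = 100, 4000, 0.4
    return df


class TestSpectrum:
    def test_rates_and_ratio_arithmetic(self):
        cl = make_classified([("g1", "A>G", "NTS", 10), ("g1", "A>G", "TS", 5)])
        opp = make_opp(["g1"])
        spec, asym = compute_strand_spectrum(cl, opp, B=50, seed=0)
        s = spec.set_index(["collapsed_type", "strand_class"])
        assert s.loc[("A>G", "NTS"), "rate"] == pytest.approx(0.01)
        assert s.loc[("A>G", "TS"), "rate"] == pytest.approx(0.005)
        row = asym.set_index("collapsed_type").loc["A>G"]
        assert row["ratio"] == pytest.approx(2.0)
        assert row["ci_lo"] <= 2.0 <= row["ci_hi"]

    def test_perfect_symmetry(self):
        cl = make_classified([("g1", "A>G", "NTS", 50), ("g1", "A>G", "TS", 50)])
        spec, asym = compute_strand_spectrum(cl, make_opp(["g1"]), B=50, seed=0)
        row = asym.set_index("collapsed_type").loc["A>G"]
        assert row["ratio"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1.0)

    def test_total_conservation(self):
        cl = make_classified([("g1", "A>G", "NTS", 7), ("g1", "G>T", "TS", 3),
                              ("g2", "A>C", "NTS", 2)])
        spec, _ = compute_strand_spectrum(cl, make_opp(["g1", "g2"]), B=10, seed=1)
        assert spec["count"].sum() == len(cl)

    def test_zero_ts_rate_flagged_infinite(self):
        cl = make_classified([("g1", "A>G", "NTS", 5)])
        _, asym = compute_strand_spectrum(cl, make_opp(["g1"]), B=10, seed=0)
        row = asym.set_index("collapsed_type").loc["A>G"]
        assert np.isinf(row["ratio"]) and row["ratio_infinite"]

    def test_label_swap_inverts_ratios(self):
        cl = make_classified([("g1", "A>G", "NTS", 30), ("g1", "A>G", "TS", 10),
                              ("g1", "G>C", "NTS", 4), ("g1", "G>C", "TS", 9)])
        opp = make_opp(["g1"], nts_A=800, ts_A=1200)
        _, a = compute_strand_spectrum(cl, opp, B=10, seed=0)
        swapped = cl.copy()
        swapped["strand_class"] = swapped["strand_class"].map(
            {"NTS": "TS", "TS": "NTS"})
        opp_sw = opp.rename(columns={f"{p}_{b}": f"{q}_{b}"
                                     for p, q in (("nts", "ts"), ("ts", "nts"))
                                     for b in "ACGT"})
        _, b = compute_strand_spectrum(swapped, opp_sw, B=10, seed=0)
        for t in ("A>G", "G>C"):
            r1 = a.set_index("collapsed_type").loc[t, "ratio"]
            r2 = b.set_index("collapsed_type").loc[t, "ratio"]
            assert r1 == pytest.approx(1 / r2)

    def test_gene_unit_bootstrap_runs(self):
        cl = make_classified([("g1", "A>G", "NTS", 20), ("g2", "A>G", "TS", 10)])
        _, asym = compute_strand_spectrum(cl, make_opp(["g1", "g2"]), B=25,
                                          seed=3, unit="gene")
        assert np.isfinite(asym.set_index("collapsed_type").loc["A>G", "ratio"])


class TestHomogeneity:
    def test_identical_datasets_homogeneous(self):
        t = pd.DataFrame({"count_nts": [20, 20, 20], "count_ts": [10, 10, 10],
                          "opp_nts": [1e4] * 3, "opp_ts": [1e4] * 3})
        stat, dof, p = chisq_homogeneity(t)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert dof == 2 and p == pytest.approx(1.0)

    def test_equal_opportunity_case_is_pearson(self):
        """[[30,10],[20,20]] -> Pearson statistic 16/3, df 1."""
        t = pd.DataFrame({"count_nts": [30, 20], "count_ts": [10, 20],
                          "opp_nts": [1e4, 1e4], "opp_ts": [1e4, 1e4]})
        stat, dof, p = chisq_homogeneity(t)
        expected = stats.chi2_contingency([[30, 10], [20, 20]],
                                          correction=False)
        assert stat == pytest.approx(expected.statistic)
        assert stat == pytest.approx(16 / 3)
        assert dof == 1

    def test_simulated_p_close_to_asymptotic(self):
        t = pd.DataFrame({"count_nts": [60, 40], "count_ts": [40, 60],
                          "opp_nts": [1e4, 1e4], "opp_ts": [1e4, 1e4]})
        _, _, p_asym = chisq_homogeneity(t)
        _, _, p_sim = chisq_homogeneity(t, simulate_p=True, n_sim=4000, seed=0)
        assert p_sim == pytest.approx(p_asym, abs=0.02)

    def test_small_expected_warns(self):
        t = pd.DataFrame({"count_nts": [3, 1], "count_ts": [1, 3],
                          "opp_nts": [100, 100], "opp_ts": [100, 100]})
        with pytest.warns(UserWarning, match="expected cell"):
            chisq_homogeneity(t)

    def test_single_dataset_rejected(self):
        t = pd.DataFrame({"count_nts": [3], "count_ts": [1],
                          "opp_nts": [100], "opp_ts": [100]})
        with pytest.raises(ValueError, match=">= 2"):
            chisq_homogeneity(t)


class TestQuantiles:
    def test_partition_sizes_ten_genes_four_bins(self):
        gids = [f"g{i}" for i in range(10)]
        opp = make_opp(gids)
        expr = pd.Series(np.arange(10, dtype=float), index=gids)
        cl = make_classified([("g0", "A>G", "NTS", 1)])
        q = asymmetry_by_quantile(cl, opp, expr, k=4, B=10, seed=0)
        assert q["n_genes"].tolist() == [3, 3, 2, 2]

    def test_no_gradient_ratios_near_global(self):
        rng = np.random.default_rng(1)
        gids = [f"g{i:03d}" for i in range(200)]
        opp = make_opp(gids, nts_A=500, ts_A=500)
        expr = pd.Series(rng.uniform(0, 100, 200), index=gids)
        cells = []
        for g in gids:
            cells.append((g, "A>G", "NTS", int(rng.poisson(3))))
            cells.append((g, "A>G", "TS", int(rng.poisson(2))))
        cl = make_classified(cells)
        q = asymmetry_by_quantile(cl, opp, expr, k=4, B=100, seed=2)
        global_ratio = 1.5
        inside = [(row.ratio_lo <= global_ratio <= row.ratio_hi)
                  for row in q.itertuples()]
        assert sum(inside) >= 3

    def test_missing_expression_rejected(self):
        gids = ["g0", "g1"]
        opp = make_opp(gids)
        expr = pd.Series([1.0], index=["g0"])
        with pytest.raises(ValueError, match="expression missing"):
            asymmetry_by_quantile(make_classified([]), opp, expr, k=2)


class TestPerStrandModel:
    def _features(self, rng, n=2000):
        idx = pd.Index([f"g{i:04d}" for i in range(n)], name="gene_id")
        X = pd.DataFrame({"expression": rng.standard_normal(n)}, index=idx)
        X = (X - X.mean()) / X.std(ddof=0)
        offs = pd.DataFrame({
            "L_all": 2000, "L_cpg": 100,
            "nts_A": rng.integers(400, 800, n),
            "ts_A": rng.integers(400, 800, n),
        }, index=idx)
        return FeatureMatrix(X=X, raw_values=X.copy(), offsets=offs,
                             standardization=pd.DataFrame(),
                             dropped=pd.DataFrame(columns=["gene_id", "reason"]))

    def _draw(self, rng, fm, col, beta):
        mu = fm.offsets[col].to_numpy() * np.exp(
            -4.0 + beta * fm.X["expression"].to_numpy())
        y = rng.poisson(rng.gamma(2.0, mu / 2.0))
        cells = [(g, "A>G", "NTS" if col == "nts_A" else "TS", int(k))
                 for g, k in zip(fm.X.index, y) if k]
        return cells

    def test_symmetric_simulation_equal_coefficients(self):
        rng = np.random.default_rng(3)
        fm = self._features(rng)
        cl = make_classified(self._draw(rng, fm, "nts_A", 0.2)
                             + self._draw(rng, fm, "ts_A", 0.2))
        r_n = fit_per_strand_model(cl, fm, "A>G", "NTS")
        r_t = fit_per_strand_model(cl, fm, "A>G", "TS")
        diff = r_n.coef("expression") - r_t.coef("expression")
        se = np.hypot(r_n["expression"]["se"], r_t["expression"]["se"])
        assert abs(diff) < 3 * se

    def test_nts_only_effect_recovered(self):
        rng = np.random.default_rng(4)
        fm = self._features(rng)
        cl = make_classified(self._draw(rng, fm, "nts_A", 0.4)
                             + self._draw(rng, fm, "ts_A", 0.0))
        r_n = fit_per_strand_model(cl, fm, "A>G", "NTS")
        r_t = fit_per_strand_model(cl, fm, "A>G", "TS")
        assert r_n.coef("expression") > 0.2
        assert r_n["expression"]["p"] < 1e-4
        assert abs(r_t.coef("expression")) < 3 * r_t["expression"]["se"]

    def test_halved_offsets_shift_only_intercept(self):
        rng = np.random.default_rng(5)
        fm = self._features(rng, n=1000)
        cl = make_classified(self._draw(rng, fm, "nts_A", 0.2))
        r1 = fit_per_strand_model(cl, fm, "A>G", "NTS", theta=2.0)
        import dataclasses
        fm2 = dataclasses.replace(fm, offsets=fm.offsets.assign(
            nts_A=(fm.offsets["nts_A"] // 2).clip(lower=1)))
        r2 = fit_per_strand_model(cl, fm2, "A>G", "NTS", theta=2.0)
        assert r2.coef("expression") == pytest.approx(
            r1.coef("expression"), abs=5e-3)
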