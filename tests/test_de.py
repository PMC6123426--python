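import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lateralyzer import (
    CountMatrix,
    SampleSheet,
    SimulationConfig,
    age_contrast,
    bh_fdr,
    filter_expressed,
    fit_moderated,
    side_contrast,
    simulate_dataset,
    voom_weights,
)
from lateralyzer.datatypes import ExpressionMatrix
from lateralyzer.de import DesignSpec, age_design, side_design, squeeze_var

from oracles import brute_force_bh


def _flip_all_sides(sheet: SampleSheet) -> SampleSheet:
    tab = sheet.table.copy()
    tab["side"] = tab["side"].map({"L": "R", "R": "L"})
    return SampleSheet(tab)


class TestBhFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-15
        )

    def test_single_p(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_equal(self):
        np.testing.assert_allclose(bh_fdr([0.4, 0.4, 0.4]), 0.4)

    def test_rejects_nan(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, np.nan])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])

    def test_q_at_least_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=100)
        assert np.all(bh_fdr(p) >= p)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 40))
        np.testing.assert_allclose(bh_fdr(p), brute_force_bh(list(p)), atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(42)
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestDesigns:
    def test_side_design_columns(self, paired_sheet):
        design = side_design(paired_sheet)
        assert design.contrast == "side_R"
        x = design.matrix
        assert x.shape == (8, 5)
        np.testing.assert_array_equal(x[:, -1], [0, 1] * 4)
        np.testing.assert_array_equal(x[:, :4].sum(axis=1), np.ones(8))

    def test_unpaired_individual_named_in_error(self, paired_sheet):
        broken = SampleSheet(paired_sheet.table.iloc[:-1].reset_index(drop=True))
        with pytest.raises(ValueError, match="E3"):
            side_design(broken)

    def test_age_design_needs_three_ages(self, paired_sheet):
        tab = paired_sheet.table.copy()
        tab["age_pcw"] = [8.0] * 4 + [9.0] * 4
        with pytest.raises(ValueError, match="distinct ages"):
            age_design(SampleSheet(tab))

    def test_age_design_structure_dummies(self, paired_sheet):
        tab = pd.concat(
            [paired_sheet.table, paired_sheet.table.assign(
                structure="s2",
                sample_id=paired_sheet.table["sample_id"] + "_b",
                individual=paired_sheet.table["individual"] + "_b",
            )],
            ignore_index=True,
        )
        design = age_design(SampleSheet(tab), include_structure=True)
        assert "structure_s2" in design.coef_names

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError, match="full rank"):
            DesignSpec(np.ones((4, 2)), ["a", "b"], "b")


def _simulated(delta=0.0, seed=1, **kw):
    config = SimulationConfig(
        n_individuals=6, n_genes=500, asynchrony_delta=delta, seed=seed, **kw
    )
    counts, sheet, truth = simulate_dataset(config)
    return filter_expressed(counts), sheet, truth


class TestVoomWeights:
    def test_flat_trend_equal_weights(self, paired_sheet):
        # every gene has literally the same counts -> identical mean and
        # residual variance -> degenerate flat trend -> equal weights
        row = np.array([90, 110, 100, 95, 105, 98, 102, 100])
        counts = np.tile(row, (80, 1))
        cm = CountMatrix([f"g{i}" for i in range(80)],
                         list(paired_sheet.table["sample_id"]), counts)
        design = side_design(paired_sheet)
        w = voom_weights(cm, design)
        np.testing.assert_allclose(w, w[0, 0])

    def test_low_count_genes_downweighted_ordering(self):
        counts, sheet, _ = _simulated(seed=3)
        design = side_design(sheet)
        w = voom_weights(counts, design)
        mean_count = counts.counts.mean(axis=1)
        lo = mean_count < np.quantile(mean_count, 0.1)
        hi = mean_count > np.quantile(mean_count, 0.9)
        assert w[lo].mean() < w[hi].mean()

    def test_relabeling_invariance(self, paired_sheet):
        rng = np.random.default_rng(1)
        counts = rng.poisson(rng.uniform(5, 500, size=(120, 1)), size=(120, 8))
        ids = list(paired_sheet.table["sample_id"])
        cm = CountMatrix([f"g{i}" for i in range(120)], ids, counts)
        design = side_design(paired_sheet)
        w = voom_weights(cm, design)

        perm = np.array([3, 1, 6, 0, 5, 2, 7, 4])
        cm2 = CountMatrix(cm.gene_ids, [ids[j] for j in perm], counts[:, perm])
        design2 = DesignSpec(design.matrix[perm], design.coef_names, "side_R")
        w2 = voom_weights(cm2, design2)
        np.testing.assert_allclose(w2, w[:, perm], rtol=1e-9)

    def test_saturated_design_rejected(self, paired_sheet):
        cm = CountMatrix(
            ["g"], list(paired_sheet.table["sample_id"]),
            np.ones((1, 8), dtype=int),
        )
        x = np.eye(8)
        design = DesignSpec(x, [f"c{i}" for i in range(8)], "c0")
        with pytest.raises(ValueError, match="df"):
            voom_weights(cm, design)


class TestModeratedT:
    def test_d0_zero_equals_classical_paired_t(self):
        counts, sheet, _ = _simulated(seed=2)
        result = side_contrast(counts, sheet, use_weights=False, d0_override=0.0)
        y = np.log2((counts.counts + 0.5) / (counts.lib_sizes + 1.0)[None, :] * 1e6)
        t_ref, p_ref = stats.ttest_rel(y[:, 1::2], y[:, 0::2], axis=1)
        np.testing.assert_allclose(result.t_values, t_ref, atol=1e-10)
        np.testing.assert_allclose(result.table["p"], p_ref, atol=1e-10)

    def test_d0_zero_equals_classical_weighted_t(self):
        """Generic WLS route against statsmodels, gene by gene."""
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        n, g = 10, 40
        x = np.column_stack([np.ones(n), rng.normal(size=n)])
        design = DesignSpec(x, ["intercept", "slope"], "slope")
        y = rng.normal(size=(g, n))
        w = rng.uniform(0.5, 2.0, size=(g, n))
        expr = ExpressionMatrix([f"g{i}" for i in range(g)],
                                [f"s{j}" for j in range(n)], y)
        result = fit_moderated(expr, w, design, d0_override=0.0)
        for i in range(g):
            fit = sm.WLS(y[i], x, weights=w[i]).fit()
            assert result.table.loc[i, "t"] == pytest.approx(fit.tvalues[1], abs=1e-10)
            assert result.table.loc[i, "logFC"] == pytest.approx(fit.params[1], abs=1e-10)

    def test_d0_infinite_constant_variance(self):
        counts, sheet, _ = _simulated(seed=4)
        result = side_contrast(counts, sheet, d0_override=np.inf)
        # with d0 = inf every gene is tested against the same prior variance:
        # t / logFC ratio differs only through the (equal-design) se factor
        assert result.d0 == np.inf
        s2 = squeeze_var(np.abs(np.random.default_rng(0).normal(size=50)) + 0.1,
                         5.0, np.inf, 0.7)
        np.testing.assert_allclose(s2, 0.7)

    def test_null_pvalue_calibration(self):
        """No side effect: p-values approximately uniform."""
        config = SimulationConfig(
            n_individuals=8, n_genes=2000, asynchrony_delta=0.0,
            side_noise_sd=0.0, dispersion=0.0, lib_size_cv=0.0, seed=12,
        )
        counts, sheet, _ = simulate_dataset(config)
        counts = filter_expressed(counts)
        result = side_contrast(counts, sheet)
        frac = float(np.mean(result.table["p"] <= 0.05))
        n = len(result.table)
        half_width = 1.96 * np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < half_width + 0.01

    def test_zero_variance_gene_gets_prior(self, paired_sheet):
        rng = np.random.default_rng(9)
        counts = rng.poisson(50, size=(50, 8))
        counts[0] = 0  # all-zero gene: zero variance
        cm = CountMatrix([f"g{i}" for i in range(50)],
                         list(paired_sheet.table["sample_id"]), counts)
        result = side_contrast(cm, paired_sheet, use_weights=False)
        assert np.isfinite(result.table["p"]).all()


class TestSideContrast:
    def test_sign_symmetry_bit_exact(self):
        counts, sheet, _ = _simulated(delta=0.3, seed=5)
        res = side_contrast(counts, sheet)
        res_flipped = side_contrast(counts, _flip_all_sides(sheet))
        assert np.array_equal(res_flipped.t_values, -res.t_values)
        assert np.array_equal(
            res_flipped.table["logFC"].to_numpy(), -res.table["logFC"].to_numpy()
        )
        assert np.array_equal(
            res_flipped.table["p"].to_numpy(), res.table["p"].to_numpy()
        )

    def test_one_pair_rejected(self):
        rows = []
        for side in ("L", "R"):
            rows.append(
                {
                    "sample_id": f"only_{side}", "individual": "only",
                    "side": side, "structure": "s1", "age_pcw": 8.0, "sex": "M",
                }
            )
        sheet = SampleSheet(pd.DataFrame(rows))
        cm = CountMatrix(["g1", "g2"], ["only_L", "only_R"],
                         np.array([[10, 12], [30, 31]]))
        with pytest.raises(ValueError, match="pairs"):
            side_contrast(cm, sheet)

    def test_unpaired_individual_hard_error(self, paired_sheet):
        broken = SampleSheet(paired_sheet.table.iloc[:-1].reset_index(drop=True))
        cm = CountMatrix(
            ["g"], list(broken.table["sample_id"]),
            np.arange(7).reshape(1, 7) + 1,
        )
        with pytest.raises(ValueError, match="E3"):
            side_contrast(cm, broken)

    def test_parameter_recovery_slope(self):
        """Regression of side logFC on age slope recovers delta within 20%."""
        config = SimulationConfig(seed=8, asynchrony_delta=0.25)
        counts, sheet, truth = simulate_dataset(config)
        kept = filter_expressed(counts)
        res = side_contrast(kept, sheet)
        slope_map = dict(zip(truth.gene_ids, truth.age_slope))
        a = np.array([slope_map[g] for g in res.gene_ids])
        beta = res.table["logFC"].to_numpy()
        fit = np.polyfit(a, beta, 1)
        assert fit[0] == pytest.approx(0.25, rel=0.2)


class TestAgeContrast:
    def test_strong_age_signal_recovered(self):
        config = SimulationConfig(
            n_individuals=6, n_genes=400, frac_age_genes=0.1, slope_sd=1.0,
            dispersion=0.05, seed=6,
        )
        counts, sheet, truth = simulate_dataset(config)
        kept = filter_expressed(counts)
        res = age_contrast(kept, sheet)
        tmap = dict(zip(res.gene_ids, res.t_values))
        qmap = dict(zip(res.gene_ids, res.table["q"]))
        strong = [
            g for g, a in zip(truth.gene_ids, truth.age_slope)
            if a > 0.9 and g in tmap
        ]
        assert strong
        assert all(tmap[g] > 0 for g in strong)
        assert np.mean([qmap[g] < 0.05 for g in strong]) > 0.8

    def test_flip_invariance(self):
        counts, sheet, _ = _simulated(seed=10)
        res = age_contrast(counts, sheet)
        res_flipped = age_contrast(counts, _flip_all_sides(sheet))
        np.testing.assert_array_equal(res.t_values, res_flipped.t_values)
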