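import numpy as np
import pandas as pd
import pytest

from cidms import epistasis as epi, thermo


class TestLogAdditiveNull:
    def test_wild_type_identity(self):
        assert epi.log_additive_prediction(7.23, 7.23, 7.23) == pytest.approx(7.23)

    def test_arithmetic(self):
        assert epi.log_additive_prediction(8.0, 9.0, 7.23) == pytest.approx(9.77)

    def test_symmetry(self):
        assert epi.log_additive_prediction(8.1, 9.3, 7.2) == (
            epi.log_additive_prediction(9.3, 8.1, 7.2)
        )


class TestEpistasisScore:
    def test_zero_when_matching(self):
        assert epi.epistasis_score(9.0, 9.0) == 0.0

    def test_sign_convention(self):
        # observed one log2 unit LOWER than expected = more repression than
        # expected = positive (suppressive) epistasis
        assert epi.epistasis_score(8.0, 9.0) == pytest.approx(1.0)

    def test_antisymmetry(self):
        assert epi.epistasis_score(8.0, 9.5) == -epi.epistasis_score(9.5, 8.0)


class TestCurves:
    def test_full_curve_plateaus(self, params):
        curve = epi.build_curve("full", params, 100, (-6, 8))
        # the stable plateau sits at the fully folded level, slightly below
        # the wild type (f_N = 0.9913)
        assert curve.low[0] == pytest.approx(params.log2_gfp_wt_low, abs=0.05)
        assert curve.low[-1] == pytest.approx(params.log2_gfp_max, abs=0.01)
        assert curve.high[-1] == pytest.approx(params.log2_gfp_max, abs=0.05)

    def test_grid_uniform(self, params):
        curve = epi.build_curve("full", params)
        assert len(curve.parameter) == 100
        assert np.allclose(np.diff(curve.parameter), curve.parameter[1] - curve.parameter[0])

    def test_folding_only_curve_is_offset_line(self, params):
        model = epi.FoldingOnlyModel(c=-2.07, beta=-2.07 / np.log2(15), alpha=-5.0)
        curve = epi.build_curve("folding_only", params, 50, folding_model=model)
        assert np.allclose(curve.high, curve.low + model.c, atol=1e-10)

    def test_unknown_model_rejected(self, params):
        with pytest.raises(ValueError):
            epi.build_curve("nope", params)


class TestFoldingOnlyFit:
    def test_recovers_known_offset_within_grid_step(self, params, rng):
        c_true = -2.11
        low = rng.uniform(params.log2_gfp_wt_low, params.log2_gfp_max, 200)
        high = low + c_true
        model = epi.fit_folding_only(low, high, params)
        assert abs(model.c - c_true) <= 0.03

    def test_beta_relation(self, params):
        model = epi.fit_folding_only(
            np.array([8.0, 10.0]), np.array([6.0, 8.0]), params
        )
        assert model.beta * np.log2(params.expression_ratio) == pytest.approx(model.c)

    def test_alpha_identity(self, params):
        model = epi.fit_folding_only(
            np.array([8.0, 10.0]), np.array([6.0, 8.0]), params
        )
        expected = params.log2_gfp_wt_low - model.beta * np.log2(
            params.f_n_wt * params.ci_e_low
        )
        assert model.alpha == pytest.approx(expected)

    def test_empty_data_rejected(self, params):
        with pytest.raises(ValueError):
            epi.fit_folding_only(np.array([]), np.array([]), params)


class TestProjection:
    def test_point_on_curve_projects_to_itself(self, params):
        curve = epi.build_curve("full", params, 100)
        point = curve.points[40:41]
        res = epi.project_to_curve(point, curve, params, n_dense=10_000)
        assert res["dist2"][0] < 1e-6
        assert np.allclose(res["projected"][0], point[0], atol=1e-3)

    def test_ssdc_equals_brute_force(self, params, rng):
        curve = epi.build_curve("full", params, 100)
        dense = epi.densify_curve(curve, params, 5_000)
        points = np.column_stack([
            rng.uniform(7.0, 12.0, 30), rng.uniform(4.5, 12.0, 30)
        ])
        res = epi.project_to_points(points, dense.points)
        brute = ((points[:, None, :] - dense.points[None, :, :]) ** 2).sum(-1).min(1)
        assert res[2] == pytest.approx(brute.sum(), rel=1e-12)
        assert res[2] >= 0

    def test_densification_convergence(self, params, rng):
        curve = epi.build_curve("full", params, 100)
        points = np.column_stack([
            rng.uniform(7.3, 11.7, 40), rng.uniform(4.6, 11.4, 40)
        ])
        s1 = epi.project_to_curve(points, curve, params, n_dense=10_000)["ssdc"]
        s2 = epi.project_to_curve(points, curve, params, n_dense=100_000)["ssdc"]
        assert abs(s1 - s2) / s2 < 1e-3


class TestPredictDoubles:
    def singles(self, params, ddgs):
        dgf = params.dgf_wt + np.asarray(ddgs)
        low = thermo.log2_gfp_from_dgf(dgf, "low", params)
        high = thermo.log2_gfp_from_dgf(dgf, "high", params)
        return pd.DataFrame({
            "dgf": dgf,
            "cit_low": thermo.fraction_folded(dgf, params) * params.ci_e_low,
            "low": low, "high": high, "log2_gfp": low,
        }, index=[f"s{i}" for i in range(len(ddgs))])

    def pairs(self):
        return pd.DataFrame({"single_a": ["s0"], "single_b": ["s1"]})

    def test_wild_type_partner_reproduces_single(self, params):
        singles = self.singles(params, [0.0, 3.0])
        for model_id in ("log_additive", "full", "regulation_only"):
            out = epi.predict_doubles(
                singles, self.pairs(), model_id, params, "low",
                folding_model=epi.FoldingOnlyModel(-2.07, -0.53, -5.0),
            )
            assert out["predicted_log2_gfp"].iloc[0] == pytest.approx(
                float(singles.loc["s1", "low"]), abs=1e-6
            ), model_id

    def test_full_model_compositional_oracle(self, params):
        singles = self.singles(params, [1.0, 2.5])
        out = epi.predict_doubles(singles, self.pairs(), "full", params, "high")
        dgf_ab = thermo.additive_ddg(
            singles.loc["s0", "dgf"], singles.loc["s1", "dgf"], params.dgf_wt
        )
        expected = thermo.log2_gfp_from_dgf(dgf_ab, "high", params)
        assert out["predicted_log2_gfp"].iloc[0] == pytest.approx(
            float(expected), abs=1e-10
        )

    def test_log_additive_self_epistasis_zero(self, params):
        singles = self.singles(params, [1.0, 2.0])
        out = epi.predict_doubles(singles, self.pairs(), "log_additive", params, "low")
        expected = epi.log_additive_prediction(
            singles.loc["s0", "low"], singles.loc["s1", "low"],
            thermo.log2_gfp_from_dgf(params.dgf_wt, "low", params),
        )
        assert epi.epistasis_score(
            out["predicted_log2_gfp"].iloc[0], float(expected)
        ) == pytest.approx(0.0, abs=1e-12)

    def test_regulation_negative_concentration_clamped(self, params):
        singles = self.singles(params, [8.0, 8.0])  # both ~null: cit ~ 0
        out = epi.predict_doubles(singles, self.pairs(), "regulation_only", params, "low")
        assert bool(out["clamped"].iloc[0])
        assert out["predicted_log2_gfp"].iloc[0] == pytest.approx(
            params.log2_gfp_max, abs=1e-9
        )


class TestPVE:
    def test_perfect_prediction(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert epi.percent_variance_explained(obs, obs) == 100.0

    def test_mean_predictor_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert epi.percent_variance_explained(obs, np.full(3, 2.0)) == pytest.approx(0.0)

    def test_bad_constant_negative(self):
        obs = np.array([1.0, 2.0, 3.0])
        got = epi.percent_variance_explained(obs, np.full(3, 10.0))
        ss_res = ((obs - 10.0) ** 2).sum()
        assert got == pytest.approx((1 - ss_res / 2.0) * 100)
        assert got < 0


class TestBinnedMedians:
    def make_inputs(self, rng, n_singles=10, n_doubles=200):
        singles = pd.DataFrame(
            {"effect": rng.normal(9, 1.5, n_singles)},
            index=[f"s{i}" for i in range(n_singles)],
        )
        a = rng.integers(0, n_singles, n_doubles)
        b = rng.integers(0, n_singles, n_doubles)
        doubles = pd.DataFrame({
            "single_a": singles.index[a], "single_b": singles.index[b],
            "value": rng.normal(0, 1, n_doubles),
        })
        return singles, doubles

    def test_equal_population_bins(self, rng):
        singles, _ = self.make_inputs(rng, n_singles=23)
        bins = epi.assign_effect_bins(singles, "effect", 5)
        counts = bins.value_counts()
        assert counts.max() - counts.min() <= 1

    def test_constant_doubles(self, rng):
        singles, doubles = self.make_inputs(rng)
        doubles["value"] = 4.2
        grid = epi.binned_median_summary(singles, doubles, "effect", ["value"])
        assert np.allclose(grid["value"], 4.2)

    def test_matches_groupby_oracle(self, rng):
        singles, doubles = self.make_inputs(rng)
        grid = epi.binned_median_summary(singles, doubles, "effect", ["value"], 5)
        bins = epi.assign_effect_bins(singles, "effect", 5)
        ba = bins.loc[doubles["single_a"]].to_numpy()
        bb = bins.loc[doubles["single_b"]].to_numpy()
        key = pd.DataFrame({
            "bin_a": np.minimum(ba, bb), "bin_b": np.maximum(ba, bb),
            "value": doubles["value"].to_numpy(),
        })
        oracle = key.groupby(["bin_a", "bin_b"])["value"].median().reset_index()
        pd.testing.assert_frame_equal(grid, oracle)


class TestEpistasisChangeClasses:
    def test_examples(self):
        assert epi.classify_epistasis_change(0.5, -0.5, 0.1)[0] == "sign_switch_pos_to_neg"
        assert epi.classify_epistasis_change(0.05, -0.05, 0.1)[0] == "stable"
        assert epi.classify_epistasis_change(-0.4, 0.6, 0.1)[0] == "sign_switch_neg_to_pos"
        assert epi.classify_epistasis_change(0.3, 1.2, 0.1)[0] == "magnitude_shift"


class TestModelInvariants:
    def test_epistasis_vanishes_for_tiny_effects(self, params):
        # in the locally linear regime of the curve the log-additive null and
        # the full model coincide
        for condition in ("low", "high"):
            wt = float(thermo.log2_gfp_from_dgf(params.dgf_wt, condition, params))
            a = float(thermo.log2_gfp_from_dgf(params.dgf_wt + 1e-4, condition, params))
            ab = float(thermo.log2_gfp_from_dgf(params.dgf_wt + 2e-4, condition, params))
            logadd = epi.log_additive_prediction(a, a, wt)
            assert epi.epistasis_score(ab, logadd) == pytest.approx(0.0, abs=1e-6)

    def test_same_ddg_pair_different_epistasis_by_condition(self, params):
        ddg = 3.5
        eps = {}
        for condition in ("low", "high"):
            wt = float(thermo.log2_gfp_from_dgf(params.dgf_wt, condition, params))
            single = float(thermo.log2_gfp_from_dgf(params.dgf_wt + ddg, condition, params))
            double = float(
                thermo.log2_gfp_from_dgf(params.dgf_wt + 2 * ddg, condition, params)
            )
            eps[condition] = epi.epistasis_score(
                double, epi.log_additive_prediction(single, single, wt)
            )
        assert abs(eps["low"] - eps["high"]) > 0.5
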