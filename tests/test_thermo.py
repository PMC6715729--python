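import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cidms import thermo
from cidms.thermo import ThermoParams


def boltzmann_oracle(ci2, p):
    """Term-by-term statistical weights, written independently of the module."""
    terms = [
        np.exp(-p.dg_cs[i] / (p.r * p.t)) * ci2 ** p.n_cs[i] for i in range(8)
    ]
    z = sum(terms)
    return np.array([t / z for t in terms])


class TestConfigProbabilities:
    def test_zero_dimer_concentration_gives_empty_operator(self, params):
        f = thermo.config_probabilities(0.0, params)
        assert f[0] == 1.0
        assert np.all(f[1:] == 0.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(min_value=-12, max_value=-4))
    def test_probabilities_normalize(self, log_ci2):
        p = ThermoParams.default()
        f = thermo.config_probabilities(10.0**log_ci2, p)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(f >= 0)

    def test_matches_term_by_term_oracle(self, params):
        ci2 = 1e-8
        got = thermo.config_probabilities(ci2, params)
        assert np.allclose(got, boltzmann_oracle(ci2, params), atol=1e-12)


class TestRepression:
    def test_limits(self, params):
        assert thermo.repression_probability(0.0, params) == 0.0
        assert thermo.repression_probability(1e-3, params) == pytest.approx(1.0, abs=1e-6)

    def test_compositional(self, params):
        ci2 = 3e-9
        f = thermo.config_probabilities(ci2, params)
        assert thermo.repression_probability(ci2, params) == pytest.approx(
            1 - f[0] - f[1], abs=1e-14
        )

    def test_monotone_increasing(self, params):
        grid = np.logspace(-12, -4, 60)
        ps = thermo.repression_probability(grid, params)
        assert np.all(np.diff(ps) > 0)


class TestGfpMaps:
    def test_endpoints(self, params):
        assert thermo.gfp_from_ci2(0.0, params) == pytest.approx(params.gfp_max)
        assert thermo.gfp_from_ci2(1e-3, params) == pytest.approx(
            params.gfp_auto, rel=1e-4
        )

    def test_gfp_ci2_round_trip(self, params):
        ci2 = np.logspace(-11, -5, 40)
        gfp = thermo.gfp_from_ci2(ci2, params)
        back = thermo.ci2_from_gfp(gfp, params)
        assert np.allclose(back, ci2, rtol=1e-6)

    def test_gfp_max_maps_to_zero(self, params):
        assert thermo.ci2_from_gfp(params.gfp_max, params) == 0.0

    def test_out_of_range_rejected(self, params):
        with pytest.raises(ValueError):
            thermo.ci2_from_gfp(params.gfp_auto * 0.9, params)
        with pytest.raises(ValueError):
            thermo.ci2_from_gfp(params.gfp_max * 1.01, params)

    def test_residual_of_inverse(self, params):
        gfp = 0.5 * (params.gfp_auto + params.gfp_max)
        ci2 = thermo.ci2_from_gfp(gfp, params)
        assert thermo.gfp_from_ci2(ci2, params) == pytest.approx(gfp, rel=1e-10)


class TestTotalConcentration:
    def test_zero(self, params):
        assert thermo.citotal_from_ci2(0.0, params) == 0.0
        assert thermo.ci2_from_citotal(0.0, params) == 0.0

    def test_saturation_limit(self, params):
        ci2 = 1e-4
        expected = (
            np.sqrt(ci2 / params.ka) + 2 * ci2 + 2 * 3 * params.or_total
        )
        assert thermo.citotal_from_ci2(ci2, params) == pytest.approx(
            expected, rel=1e-6
        )

    def test_matches_occupancy_oracle(self, params):
        ci2 = 2.5e-8
        f = boltzmann_oracle(ci2, params)
        expected = (
            np.sqrt(ci2 / params.ka)
            + 2 * ci2
            + 2 * params.or_total * np.dot(params.n_cs, f)
        )
        assert thermo.citotal_from_ci2(ci2, params) == pytest.approx(
            expected, rel=1e-12
        )

    def test_round_trip(self, params):
        ci2 = np.logspace(-12, -4, 50)
        cit = thermo.citotal_from_ci2(ci2, params)
        back = thermo.ci2_from_citotal(cit, params)
        assert np.allclose(back, ci2, rtol=1e-8)

    def test_monotone(self, params):
        grid = np.logspace(-12, -4, 80)
        cit = thermo.citotal_from_ci2(grid, params)
        assert np.all(np.diff(cit) > 0)

    def test_negative_rejected(self, params):
        with pytest.raises(ValueError):
            thermo.ci2_from_citotal(-1e-9, params)


class TestFolding:
    def test_symmetry_point(self, params):
        assert thermo.fraction_folded(0.0, params) == pytest.approx(0.5)

    def test_wild_type_fraction_folded(self, params):
        f_n = thermo.fraction_folded(params.dgf_wt, params)
        assert round(float(f_n), 4) == 0.9913
        assert f_n == pytest.approx(114 / 115, abs=1e-12)

    def test_round_trip(self, params):
        x = np.linspace(-10, 10, 41)
        back = thermo.dgf_from_fraction(thermo.fraction_folded(x, params), params)
        assert np.allclose(back, x, atol=1e-10)

    def test_inverse_domain(self, params):
        with pytest.raises(ValueError):
            thermo.dgf_from_fraction(1.0, params)


class TestAdditivity:
    def test_wild_type_identity(self):
        assert thermo.additive_ddg(-2.9, -1.0, -2.9) == pytest.approx(-1.0)

    def test_symmetry(self):
        assert thermo.additive_ddg(-1.5, -2.0, -2.908) == thermo.additive_ddg(
            -2.0, -1.5, -2.908
        )

    def test_arithmetic(self):
        assert thermo.additive_ddg(-1.5, -2.0, -2.908) == pytest.approx(-0.592)


class TestCombinedModel:
    def test_wild_type_low_calibration_identity(self, params):
        got = thermo.log2_gfp_from_dgf(params.dgf_wt, "low", params)
        assert got == pytest.approx(params.log2_gfp_wt_low, abs=1e-6)

    def test_unfolded_limit(self, params):
        assert thermo.gfp_from_dgf(50.0, "low", params) == pytest.approx(
            params.gfp_max, rel=1e-9
        )

    def test_round_trip_inside_detection_range(self, params):
        dgf = np.linspace(-2.5, 2.5, 30)
        gfp = thermo.gfp_from_dgf(dgf, "low", params)
        back = thermo.gfp_from_dgf(thermo.dgf_from_gfp(gfp, "low", params), "low", params)
        assert np.allclose(back, gfp, rtol=1e-6)

    def test_two_code_paths_agree(self, params):
        dgf = np.linspace(-2, 2, 11)
        direct = thermo.gfp_from_dgf(dgf, "high", params)
        composed = thermo.gfp_from_ci2(
            thermo.ci2_from_citotal(
                thermo.fraction_folded(dgf, params) * params.ci_e_high, params
            ),
            params,
        )
        assert np.allclose(direct, composed, rtol=1e-12)

    def test_unknown_condition_rejected(self, params):
        with pytest.raises(ValueError):
            params.ci_e("medium")


class TestCalibration:
    def test_gfp_auto_recovery(self, params):
        gfp_low = float(thermo.gfp_from_dgf(params.dgf_wt, "low", params))
        gfp_high = float(thermo.gfp_from_dgf(params.dgf_wt, "high", params))
        recovered = thermo.calibrate_gfp_auto(
            gfp_low, gfp_high, params.replace(log2_gfp_auto=5.0)
        )
        assert recovered == pytest.approx(params.gfp_auto, abs=1e-4)

    def test_recovered_value_reproduces_ratio(self, params):
        gfp_low = float(thermo.gfp_from_dgf(params.dgf_wt, "low", params))
        gfp_high = float(thermo.gfp_from_dgf(params.dgf_wt, "high", params))
        auto = thermo.calibrate_gfp_auto(gfp_low, gfp_high, params)
        trial = params.replace(log2_gfp_auto=float(np.log2(auto)))
        ratio = thermo.citotal_from_gfp(gfp_high, trial) / thermo.citotal_from_gfp(
            gfp_low, trial
        )
        assert ratio == pytest.approx(params.expression_ratio, rel=1e-6)

    def test_auto_unit_conversion(self):
        assert round(float(np.log2(23.24)), 2) == 4.54

    def test_ci_e_from_fully_folded(self, params):
        gfp = 2.0**8.0
        cit = thermo.citotal_from_gfp(gfp, params)
        assert thermo.compute_ci_e(gfp, 1.0, params) == pytest.approx(cit)

    def test_expression_ratio_consistency(self, params):
        assert params.ci_e_high / params.ci_e_low == pytest.approx(
            params.expression_ratio
        )

    def test_ci_e_compositional_oracle(self, params):
        gfp = 2.0**9.0
        expected = thermo.citotal_from_ci2(
            thermo.ci2_from_gfp(gfp, params), params
        ) / params.f_n_wt
        assert thermo.compute_ci_e(gfp, params.f_n_wt, params) == pytest.approx(
            expected, rel=1e-12
        )


def test_yaml_round_trip(tmp_path, params):
    path = tmp_path / "params.yaml"
    params.to_yaml(path)
    loaded = ThermoParams.from_yaml(path)
    assert np.allclose(loaded.dg_cs, params.dg_cs)
    assert loaded.ci_e_low == pytest.approx(params.ci_e_low)
    assert loaded.log2_gfp_auto == params.log2_gfp_auto


def test_invalid_params_rejected():
    base = ThermoParams.default()
    with pytest.raises(ValueError):
        ThermoParams(dg_cs=np.ones(8), n_cs=base.n_cs, ka=base.ka, or_total=base.or_total)
    with pytest.raises(ValueError):
        base.replace(ka=-1.0)
    with pytest.raises(ValueError):
        base.replace(log2_gfp_auto=12.0)
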