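import numpy as np
import pytest

from cidms import landscapes as ls
from cidms.landscapes import LandscapeSpec


class TestFitnessFunctions:
    def test_increasing_half_saturation(self):
        assert ls.fitness("increasing", 0.1) == pytest.approx(0.5)

    def test_decreasing_at_zero(self):
        assert ls.fitness("decreasing", 0.0) == pytest.approx(1.0)

    def test_optimal_argmax_matches_brute_force(self):
        grid = np.logspace(-3, 3, 20_001)
        brute = grid[np.argmax(ls.fitness("optimal", grid))]
        assert ls.optimal_concentration("optimal") == pytest.approx(brute, rel=1e-3)
        assert ls.optimal_concentration("optimal") == pytest.approx(1.0, rel=1e-4)

    def test_monotonicity_and_unimodality(self):
        grid = np.logspace(-3, 3, 500)
        assert np.all(np.diff(ls.fitness("increasing", grid)) > 0)
        assert np.all(np.diff(ls.fitness("decreasing", grid)) < 0)
        diffs = np.sign(np.diff(ls.fitness("optimal", grid)))
        # single sign change: rises then falls
        assert (np.diff(diffs) != 0).sum() == 1

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            ls.fitness("increasing", -0.5)

    def test_unknown_shape_rejected(self):
        with pytest.raises(ValueError):
            ls.fitness("bowl", 1.0)


class TestLandscapeComposition:
    def spec(self, shape="increasing"):
        return LandscapeSpec(shape=shape, wt_dgf=-1.6,
                             concentration_low=0.25, concentration_high=5.0)

    def test_unfolded_limit(self):
        spec = self.spec()
        assert ls.landscape_fitness(40.0, spec, "high") == pytest.approx(
            ls.fitness("increasing", 0.0), abs=1e-10
        )

    def test_folded_limit(self):
        spec = self.spec()
        assert ls.landscape_fitness(-40.0, spec, "high") == pytest.approx(
            ls.fitness("increasing", 5.0), rel=1e-10
        )

    def test_compositional_oracle(self, params):
        spec = self.spec("optimal")
        dg = 0.7
        f_n = 1.0 / (1.0 + np.exp(dg / (spec.params.r * spec.params.t)))
        expected = ls.fitness("optimal", f_n * 0.25)
        assert ls.landscape_fitness(dg, spec, "low") == pytest.approx(
            float(expected), rel=1e-12
        )


class TestEpistasisGrid:
    def test_zero_effect_row_has_zero_epistasis(self):
        spec = LandscapeSpec(shape="increasing", wt_dgf=-1.6,
                             ddg_range=(0.0, 5.0), n_mutations=11)
        grid = ls.epistasis_grid(spec)
        assert np.allclose(grid["low"]["epistasis"][0, :], 0.0, atol=1e-12)

    def test_symmetry(self):
        grid = ls.epistasis_grid(LandscapeSpec(shape="optimal"))
        for scenario in ("low", "high"):
            e = grid[scenario]["epistasis"]
            assert np.allclose(e, e.T)

    def test_spot_cell_matches_scalar_recomputation(self):
        spec = LandscapeSpec(shape="decreasing")
        grid = ls.epistasis_grid(spec)
        ddg = grid["ddg"]
        i, j = 10, 30
        obs = float(ls.landscape_fitness(spec.wt_dgf + ddg[i] + ddg[j], spec, "low"))
        wa = float(ls.landscape_fitness(spec.wt_dgf + ddg[i], spec, "low"))
        wb = float(ls.landscape_fitness(spec.wt_dgf + ddg[j], spec, "low"))
        wt = float(ls.landscape_fitness(spec.wt_dgf, spec, "low"))
        assert grid["low"]["epistasis"][i, j] == pytest.approx(
            obs - wa * wb / wt, rel=1e-10
        )


class TestSignSwitching:
    def test_identical_matrices_all_stable(self):
        e = np.random.default_rng(0).normal(0, 0.3, (10, 10))
        out = ls.sign_switch_map(e, e, dead_band=0.0)
        assert set(out["counts"]) <= {"stable"}

    def test_monotone_landscapes_magnitude_only(self):
        # sign switches on monotone landscapes are confined to negligible
        # epistasis magnitudes (< 0.03 fitness units); above that dead band
        # only magnitude changes remain
        for shape in ("increasing", "decreasing"):
            spec = LandscapeSpec(shape=shape, wt_dgf=-1.6,
                                 concentration_low=0.25, concentration_high=5.0)
            grid = ls.epistasis_grid(spec)
            out = ls.sign_switch_map(
                grid["low"]["epistasis"], grid["high"]["epistasis"], dead_band=0.03
            )
            assert "sign_switch_pos_to_neg" not in out["counts"], shape
            assert "sign_switch_neg_to_pos" not in out["counts"], shape

    def test_peaked_landscape_switches_sign(self):
        c_low, c_high = ls.paired_concentrations("optimal", -1.6)
        spec = LandscapeSpec(shape="optimal", wt_dgf=-1.6,
                             concentration_low=c_low, concentration_high=c_high)
        grid = ls.epistasis_grid(spec)
        out = ls.sign_switch_map(
            grid["low"]["epistasis"], grid["high"]["epistasis"], dead_band=0.01
        )
        switches = out["counts"].get("sign_switch_pos_to_neg", 0) + out[
            "counts"
        ].get("sign_switch_neg_to_pos", 0)
        assert switches > 0


class TestPairedConcentrations:
    def test_equal_wild_type_fitness_astride_optimum(self):
        c_low, c_high = ls.paired_concentrations("optimal", -1.6)
        spec_kwargs = dict(shape="optimal", wt_dgf=-1.6)
        w_low = ls.landscape_fitness(
            -1.6, LandscapeSpec(concentration_low=c_low, concentration_high=c_high,
                                **spec_kwargs), "low")
        w_high = ls.landscape_fitness(
            -1.6, LandscapeSpec(concentration_low=c_low, concentration_high=c_high,
                                **spec_kwargs), "high")
        assert float(w_low) == pytest.approx(float(w_high), rel=1e-8)
        assert c_low < c_high


class TestInversion:
    def monotone_spec(self):
        return LandscapeSpec(shape="increasing", wt_dgf=-1.6,
                             concentration_low=0.25, concentration_high=5.0)

    def peaked_spec(self):
        c_low, c_high = ls.paired_concentrations("optimal", -1.6)
        return LandscapeSpec(shape="optimal", wt_dgf=-1.6,
                             concentration_low=c_low, concentration_high=c_high)

    def test_monotone_single_root(self):
        spec = self.monotone_spec()
        target = float(ls.landscape_fitness(0.5, spec, "low"))
        roots = ls.invert_fitness(target, spec, "low")
        assert len(roots) == 1
        assert roots[0] == pytest.approx(0.5, abs=1e-6)

    def test_peaked_two_roots_verified_by_forward_evaluation(self):
        spec = self.peaked_spec()
        grid = np.linspace(-8, 8, 2001)
        peak = float(np.max(ls.landscape_fitness(grid, spec, "high")))
        target = 0.97 * peak
        roots = ls.invert_fitness(target, spec, "high")
        assert len(roots) == 2
        for r in roots:
            assert float(ls.landscape_fitness(r, spec, "high")) == pytest.approx(
                target, abs=1e-8
            )

    def test_out_of_range_returns_empty(self):
        spec = self.monotone_spec()
        assert ls.invert_fitness(2.0, spec, "low").size == 0


class TestDoubleOutcomes:
    def test_monotone_single_outcome(self):
        spec = LandscapeSpec(shape="increasing", wt_dgf=-1.6,
                             concentration_low=0.25, concentration_high=5.0)
        wa = float(ls.landscape_fitness(-1.0, spec, "low"))
        wb = float(ls.landscape_fitness(0.0, spec, "low"))
        outcomes = ls.enumerate_double_outcomes(wa, wb, spec, "low")
        assert len(outcomes) == 1

    def test_peaked_up_to_four_outcomes(self):
        c_low, c_high = ls.paired_concentrations("optimal", -1.0)
        spec = LandscapeSpec(shape="optimal", wt_dgf=-1.0,
                             concentration_low=c_low, concentration_high=c_high)
        # ambiguity arises on the 'high' scenario, where the expressed
        # concentration crosses the fitness optimum as stability drops
        grid = np.linspace(-6, 8, 2001)
        w = np.asarray(ls.landscape_fitness(grid, spec, "high"))
        target_a = 0.9 * w.max()
        target_b = 0.85 * w.max()
        ra = ls.invert_fitness(target_a, spec, "high")
        rb = ls.invert_fitness(target_b, spec, "high")
        outcomes = ls.enumerate_double_outcomes(target_a, target_b, spec, "high")
        assert len(ra) == 2 and len(rb) == 2
        assert len(outcomes) <= 4
        assert len(outcomes) >= 2

    def test_count_is_product_before_dedup(self):
        spec = LandscapeSpec(shape="increasing", wt_dgf=-1.6,
                             concentration_low=0.25, concentration_high=5.0)
        wa = float(ls.landscape_fitness(-0.5, spec, "low"))
        ra = ls.invert_fitness(wa, spec, "low")
        outcomes = ls.enumerate_double_outcomes(wa, wa, spec, "low")
        assert len(outcomes) <= len(ra) ** 2
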