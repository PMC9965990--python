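import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ketopbpk.pk import (
    ObservedProfile,
    auc_last,
    cmax_tmax,
    fit_parameters,
    gmfe,
    guest_limits,
    interaction_ratio,
    local_sensitivity,
    mrd,
    nca,
    terminal_half_life,
    within_guest,
    within_twofold,
)


class TestAUC:
    def test_constant_profile(self):
        assert auc_last([0, 2, 5, 10], [1, 1, 1, 1]) == pytest.approx(10.0)

    def test_triangle(self):
        assert auc_last([0, 1, 2], [0, 2, 0]) == pytest.approx(2.0)

    def test_collinear_midpoint_leaves_auc_unchanged(self):
        base = auc_last([0, 2], [0, 4])
        refined = auc_last([0, 1, 2], [0, 2, 4])
        assert refined == pytest.approx(base)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            auc_last([0], [1])


class TestCmaxTmax:
    def test_simple_peak(self):
        assert cmax_tmax([0, 1, 2], [0, 5, 3]) == (5.0, 1.0)

    def test_tie_prefers_earlier_time(self):
        assert cmax_tmax([0, 1, 2, 3], [0, 5, 5, 1]) == (5.0, 1.0)

    def test_all_zero_profile_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert cmax_tmax([0, 1, 2], [0, 0, 0]) == (0.0, 0.0)


class TestTerminalHalfLife:
    def test_pure_exponential(self):
        t = np.linspace(0, 30, 16)
        c = np.exp(-0.1 * t)
        assert terminal_half_life(t, c) == pytest.approx(math.log(2) / 0.1, rel=1e-9)

    def test_recovers_from_proportional_noise(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0, 48, 25)
        c = 100 * np.exp(-0.1 * t) * np.exp(rng.normal(0, 0.05, t.size))
        est = terminal_half_life(t, c, n_terminal_points=10)
        assert est == pytest.approx(math.log(2) / 0.1, rel=0.10)

    def test_rising_profile_rejected(self):
        with pytest.raises(ValueError):
            terminal_half_life([0, 1, 2, 3, 4], [1, 2, 3, 4, 5])

    def test_nca_summary(self):
        t = np.linspace(0, 24, 25)
        c = np.exp(-0.1 * t)
        params = nca(t, c)
        assert params.C_max == 1.0 and params.T_max == 0.0
        assert params.t_half == pytest.approx(math.log(2) / 0.1, rel=1e-6)


class TestMRD:
    def test_perfect_prediction(self):
        assert mrd([1, 10, 100], [1, 10, 100]) == pytest.approx(1.0)

    def test_single_tenfold_pair(self):
        assert mrd([10.0], [100.0]) == pytest.approx(10.0)

    def test_rms_of_symmetric_errors(self):
        assert mrd([10.0, 100.0], [100.0, 10.0]) == pytest.approx(10.0)

    def test_nonpositive_rejected_with_index(self):
        with pytest.raises(ValueError, match="index 1"):
            mrd([1.0, 0.0], [1.0, 1.0])

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance_and_symmetry(self, scale):
        obs = np.array([2.0, 8.0, 30.0])
        pred = np.array([3.0, 6.0, 45.0])
        assert mrd(obs * scale, pred * scale) == pytest.approx(mrd(obs, pred))
        assert mrd(pred, obs) == pytest.approx(mrd(obs, pred))


class TestGMFE:
    def test_perfect(self):
        assert gmfe([(1.0, 1.0), (50.0, 50.0)]) == pytest.approx(1.0)

    def test_twofold_over_and_under(self):
        assert gmfe([(2.0, 1.0), (0.5, 1.0)]) == pytest.approx(2.0)

    def test_single_study(self):
        assert gmfe([(1.37, 1.0)]) == pytest.approx(1.37)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gmfe([])


class TestInteractionRatioAndLimits:
    def test_basic_ratio(self):
        r = interaction_ratio(150.0, 100.0)
        assert r.ratio == pytest.approx(1.5)
        assert interaction_ratio(100.0, 100.0).ratio == 1.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            interaction_ratio(1.0, 0.0)

    def test_guest_band_at_unity(self):
        lo, hi = guest_limits(1.0)
        assert (lo, hi) == (pytest.approx(0.8), pytest.approx(1.25))

    def test_guest_band_approaches_twofold(self):
        lo, hi = guest_limits(1e6)
        assert hi / 1e6 == pytest.approx(2.0, rel=1e-4)

    @pytest.mark.parametrize("r", [1.2, 1.59, 2.5, 7.0])
    def test_guest_band_reciprocal_symmetry(self, r):
        lo, hi = guest_limits(r)
        lo_inv, hi_inv = guest_limits(1.0 / r)
        assert lo_inv == pytest.approx(1.0 / hi)
        assert hi_inv == pytest.approx(1.0 / lo)

    @pytest.mark.parametrize("r", [1.0, 1.3, 1.59, 3.0, 10.0])
    def test_guest_band_inside_twofold_and_contains_observed(self, r):
        lo, hi = guest_limits(r)
        assert r / 2 <= lo <= r <= hi <= r * 2
        assert within_guest(r, r)

    def test_twofold_boundaries(self):
        assert within_twofold(2.0, 1.0)
        assert within_twofold(1.0, 2.0)
        assert within_twofold(1.0, 1.0)
        assert not within_twofold(2.01, 1.0)


def _decay_profile(rate, times, scale=100.0):
    return scale * np.exp(-rate * np.asarray(times))


class TestFitParameters:
    """Generic behaviour on a cheap analytic model (exponential decay)."""

    @staticmethod
    def _observed(rate=0.2, n=3):
        t = np.linspace(0.5, 12, 10)
        return [
            ObservedProfile(study_id=f"s{i}", compound="probe", times=t,
                            concentrations=_decay_profile(rate, t))
            for i in range(n)
        ]

    @staticmethod
    def _predict(params, profile):
        return _decay_profile(params["rate"], profile.times)

    def test_lm_recovers_rate(self):
        fit = fit_parameters({"rate": (0.05, 0.001, 2.0)}, self._observed(), self._predict)
        assert fit.converged
        assert fit.estimates["rate"] == pytest.approx(0.2, rel=1e-4)

    def test_objective_decreases(self):
        fit = fit_parameters({"rate": (0.05, 0.001, 2.0)}, self._observed(), self._predict)
        assert fit.objective <= fit.trace[0][1]

    def test_monte_carlo_bit_reproducible(self):
        kwargs = dict(
            free_params={"rate": (0.05, 0.001, 2.0)},
            observed=self._observed(),
            predict=self._predict,
            method="MonteCarlo",
            seed=42,
            n_samples=40,
        )
        a = fit_parameters(**kwargs)
        b = fit_parameters(**kwargs)
        assert a.estimates == b.estimates
        assert a.objective == b.objective

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            fit_parameters({"rate": (0.1, 0, 1)}, self._observed(), self._predict, method="GA")


class TestLocalSensitivity:
    def test_flat_output_has_zero_sensitivity(self):
        assert local_sensitivity(lambda p: 5.0, 1.0) == 0.0

    def test_power_law_exact(self):
        # Output = p^2 has S = 2 in the small-perturbation limit
        s = local_sensitivity(lambda p: p**2, 3.0, relative_perturbation=0.01)
        assert s == pytest.approx(2.0, rel=1e-3)

    def test_step_halving_agreement(self):
        f = lambda p: p**1.5 + 0.1 * p
        s1 = local_sensitivity(f, 2.0, 0.1)
        s2 = local_sensitivity(f, 2.0, 0.05)
        assert s1 == pytest.approx(s2, rel=0.10)

    def test_zero_parameter_rejected(self):
        with pytest.raises(ValueError):
            local_sensitivity(lambda p: p, 0.0)
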