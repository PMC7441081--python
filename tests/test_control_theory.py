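"""Closed-form expected effects and controller-share mixture bounds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from twinstest.control_theory import (
    MixtureInterval,
    TheoryParams,
    controller_share_bound,
    controller_share_probability,
    expected_extra_births,
    expected_extra_survivors,
    last_birth_fraction,
)
from twinstest.synthetic_cohort import PRESETS

# printed expected twin effects per study sample: (births under complete
# control; survivors under no control; survivors under complete control)
SAMPLE_EXPECTATIONS = {
    "france_pre1789": (0.73, 0.24, 0.04),
    "france_post1789": (0.87, 0.12, 0.03),
    "england_campop": (0.75, 0.22, 0.05),
    "england_pre1880": (0.43, 0.45, 0.08),
    "england_1900_1949": (0.60, 0.52, 0.15),
    "quebec": (0.61, 0.33, 0.05),
}


class TestExpectedEffects:
    def test_england_prose_case(self):
        params = TheoryParams(theta_s=0.65, theta_t=0.55, phi=0.17)
        assert expected_extra_births(params, "full_control") == pytest.approx(0.43, abs=0.005)
        assert expected_extra_births(params, "no_control") == 1.0

    @pytest.mark.parametrize("name", sorted(SAMPLE_EXPECTATIONS))
    def test_sample_expectations_from_survival_rates(self, name):
        p = PRESETS[name]
        params = TheoryParams(theta_s=p["theta_s"], theta_t=p["theta_t"], mean_births=p["mean_births"])
        b_fc, s_nc, s_fc = SAMPLE_EXPECTATIONS[name]
        # inputs are printed at 2 d.p., so agreement is to +-0.01 (with a hair
        # of slack against float representation at the tolerance boundary)
        assert expected_extra_births(params, "full_control") == pytest.approx(b_fc, abs=0.0101)
        assert expected_extra_survivors(params, "no_control") == pytest.approx(s_nc, abs=0.0101)
        assert expected_extra_survivors(params, "full_control") == pytest.approx(s_fc, abs=0.0101)

    def test_equal_survival_collapses_to_phi(self):
        params = TheoryParams(theta_s=0.7, theta_t=0.7, phi=0.21)
        assert expected_extra_births(params, "full_control") == pytest.approx(0.21)
        assert expected_extra_survivors(params, "no_control") == pytest.approx(0.7)

    def test_survivors_can_be_negative(self):
        params = TheoryParams(theta_s=0.8, theta_t=0.3, phi=0.2)
        assert expected_extra_survivors(params, "no_control") < 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        theta_s=st.floats(0.05, 1.0),
        ratio=st.floats(0.5, 1.0),
        phi=st.floats(0.01, 1.0),
    )
    def test_full_control_births_below_one_when_twins_survive_half(self, theta_s, ratio, phi):
        """Fewer than one extra birth is needed whenever theta_t >= theta_s/2."""
        params = TheoryParams(theta_s=theta_s, theta_t=ratio * theta_s, phi=phi)
        assert expected_extra_births(params, "full_control") <= 1.0 + 1e-12

    def test_continuity_at_phi_one(self):
        params = TheoryParams(theta_s=0.8, theta_t=0.4, phi=1.0 - 1e-9)
        assert expected_extra_births(params, "full_control") == pytest.approx(1.0, abs=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            TheoryParams(theta_s=1.2, theta_t=0.5, phi=0.2)
        with pytest.raises(ValueError):
            TheoryParams(theta_s=0.7, theta_t=0.5)
        with pytest.raises(ValueError):
            expected_extra_births(TheoryParams(theta_s=0.0, theta_t=0.0, phi=0.2), "full_control")
        with pytest.raises(ValueError):
            expected_extra_births(TheoryParams(theta_s=0.7, theta_t=0.5, phi=0.2), "some_control")


class TestLastBirthFraction:
    def test_values(self):
        assert last_birth_fraction(5.9) == pytest.approx(0.17, abs=0.005)
        assert last_birth_fraction(1.0) == 1.0
        assert last_birth_fraction(4.66) == pytest.approx(0.2146, abs=5e-4)

    def test_below_one_rejected(self):
        with pytest.raises(ValueError):
            last_birth_fraction(0.9)

    def test_params_derive_phi_from_mean_births(self):
        params = TheoryParams(theta_s=0.7, theta_t=0.5, mean_births=5.0)
        assert params.phi == pytest.approx(0.2)


def mc_upper_bound(alpha_hat, se, alpha_nc, alpha_c, confidence, n_draws=200_000, seed=0):
    """Test inversion by simulation: the largest mixture share whose sampling
    distribution keeps the observed estimate below its upper confidence
    quantile."""
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal(n_draws)
    grid = np.linspace(0.0, 1.0, 401)
    accepted = []
    for p in grid:
        alpha_p = (1 - p) * alpha_nc + p * alpha_c
        crit = np.quantile(alpha_p + se * draws, confidence)
        if alpha_hat <= crit:
            accepted.append(p)
    return max(accepted) if accepted else 0.0


class TestControllerShareBound:
    def test_pure_natural_fertility(self):
        iv = controller_share_bound(1.0, 1e-12, 1.0, 0.61)
        assert iv.lower == 0.0
        assert iv.upper == pytest.approx(0.0, abs=1e-6)

    def test_pure_control_point(self):
        iv = controller_share_bound(0.61, 1e-12, 1.0, 0.61, side="two_sided")
        assert iv.upper == pytest.approx(1.0, abs=1e-6)
        assert iv.lower == pytest.approx(1.0, abs=1e-6)

    def test_matches_monte_carlo_test_inversion(self):
        iv = controller_share_bound(1.03, 0.05, 1.0, 0.61, confidence=0.95)
        mc = mc_upper_bound(1.03, 0.05, 1.0, 0.61, 0.95)
        assert iv.upper == pytest.approx(mc, abs=0.02)
        assert iv.upper < 0.2  # an estimate above alpha_nc rules out many controllers

    def test_monotone_in_alpha_hat(self):
        uppers = [
            controller_share_bound(a, 0.05, 1.0, 0.61).upper for a in np.linspace(0.5, 1.2, 30)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(uppers, uppers[1:]))

    def test_two_sided_contains_point(self):
        iv = controller_share_bound(0.8, 0.05, 1.0, 0.61, side="two_sided")
        point = (1.0 - 0.8) / (1.0 - 0.61)
        assert iv.lower <= point <= iv.upper

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            controller_share_bound(0.9, 0.05, 0.8, 0.8)
        with pytest.raises(ValueError):
            controller_share_bound(0.9, 0.0, 1.0, 0.61)
        with pytest.raises(ValueError):
            MixtureInterval(lower=0.5, upper=0.2, confidence=0.95, side="two_sided")


class TestControllerShareProbability:
    def test_threshold_one_is_certain(self):
        assert controller_share_probability(0.9, 0.05, 1.0, 0.61, 1.0) == 1.0

    def test_midpoint_symmetry(self):
        mid = (1.0 + 0.61) / 2
        assert controller_share_probability(mid, 0.05, 1.0, 0.61, 0.5) == pytest.approx(0.5)

    def test_threshold_zero_is_normal_tail_mass(self):
        p = controller_share_probability(1.03, 0.05, 1.0, 0.61, 0.0)
        assert p == pytest.approx(1.0 - stats.norm.cdf((1.0 - 1.03) / 0.05))

    def test_matches_monte_carlo_mixture_draws(self):
        """P(share <= t) under the normal model for the estimate."""
        rng = np.random.default_rng(1)
        alpha_hat, se, nc, c = 0.9, 0.06, 1.0, 0.61
        draws = rng.normal(alpha_hat, se, 400_000)
        shares = (nc - draws) / (nc - c)
        for t in (0.2, 0.4, 0.6):
            mc = (shares <= t).mean()
            assert controller_share_probability(alpha_hat, se, nc, c, t) == pytest.approx(mc, abs=0.005)

    def test_monotone_in_threshold(self):
        vals = [controller_share_probability(0.9, 0.05, 1.0, 0.61, t) for t in np.linspace(0, 1, 21)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
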