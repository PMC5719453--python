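"""Unit and property tests for the model's rates, fitness and gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coevodyn import (
    AdaptationParams,
    GaussianTradeOff,
    ModelParams,
    attack_rate,
    conversion_tradeoff,
    fitness_gradients,
    predator_fitness,
    prey_fitness,
    prey_growth_tradeoff,
    system_derivatives,
)

P = ModelParams()  # standard speed-analysis values
A = AdaptationParams()

traits = st.floats(0.01, 5.0)
biomass = st.floats(0.0, 3.0)


class TestAttackRate:
    @pytest.mark.parametrize("uv", [0.0, 0.3, 1.7])
    def test_equal_traits_give_half_maximum(self, uv):
        assert attack_rate(uv, uv, P) == pytest.approx(0.5)

    def test_strong_defense_suppresses_attack(self):
        # u=1, v=0, theta=10: logistic tail 1/(1+e^10)
        assert attack_rate(1.0, 0.0, P) == pytest.approx(
            1.0 / (1.0 + np.exp(10.0)), rel=1e-12
        )

    def test_overwhelming_offense_saturates_at_maximum(self):
        assert attack_rate(0.0, 10.0, P) == pytest.approx(P.a0, abs=1e-40)

    def test_extreme_trait_gap_is_finite_not_nan(self):
        # exponent clamping: the rate saturates toward 0, never NaN/overflow
        a = attack_rate(1e6, 0.0, P)
        assert np.isfinite(a) and 0.0 <= a < 1e-300
        assert attack_rate(0.0, 1e6, P) == pytest.approx(P.a0)

    @given(u=traits, v=traits)
    @settings(max_examples=50, deadline=None)
    def test_logistic_symmetry(self, u, v):
        # swapping defense and offense mirrors the rate around a0/2
        assert attack_rate(u, v, P) + attack_rate(v, u, P) == pytest.approx(P.a0)

    @given(u=traits, v=traits, du=st.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_each_trait(self, u, v, du):
        # weakly monotone everywhere (the logistic saturates in double
        # precision for large trait gaps), strictly so away from saturation
        assert attack_rate(u + du, v, P) <= attack_rate(u, v, P)
        assert attack_rate(u, v + du, P) >= attack_rate(u, v, P)
        if abs(P.theta * (u - v)) < 30 and abs(P.theta * (u + du - v)) < 30:
            assert attack_rate(u + du, v, P) < attack_rate(u, v, P)


class TestTradeOffs:
    def test_growth_maximal_at_zero_defense(self):
        assert prey_growth_tradeoff(0.0, P) == pytest.approx(P.r0)

    def test_growth_cost_of_defense(self):
        p = ModelParams(cx=3.0)
        assert prey_growth_tradeoff(0.5, p) == pytest.approx(np.exp(-0.75), rel=1e-12)

    def test_conversion_cost_of_offense(self):
        p = ModelParams(cy=2.0)
        assert conversion_tradeoff(0.0, p) == pytest.approx(p.g0)
        assert conversion_tradeoff(1.0, p) == pytest.approx(np.exp(-2.0), rel=1e-12)

    @pytest.mark.parametrize("z", [0.0, 0.5, 3.0])
    def test_zero_cost_means_no_tradeoff(self, z):
        p = ModelParams(cx=0.0, cy=0.0)
        assert prey_growth_tradeoff(z, p) == pytest.approx(p.r0)
        assert conversion_tradeoff(z, p) == pytest.approx(p.g0)

    def test_pluggable_tradeoff_hook_is_used(self):
        # a linear trade-off in place of the default Gaussian one
        class Linear:
            def value(self, z):
                return 1.0 - 0.1 * z

            def derivative(self, z):
                return -0.1

        p = ModelParams(growth_tradeoff=Linear())
        assert prey_growth_tradeoff(2.0, p) == pytest.approx(0.8)


class TestFitness:
    def test_prey_at_carrying_capacity_without_predator(self):
        assert prey_fitness(P.K, 0.0, 0.2, 0.2, P) == pytest.approx(0.0)

    def test_rare_prey_grows_at_intrinsic_rate(self):
        assert prey_fitness(0.0, 0.0, 0.4, 0.1, P) == pytest.approx(
            prey_growth_tradeoff(0.4, P)
        )

    def test_prey_fitness_term_by_term(self):
        x, y, u, v = 0.5, 0.3, 0.2, 0.2
        a = P.a0 / (1.0 + np.exp(P.theta * (u - v)))
        expected = P.r0 * np.exp(-P.cx * u**2) * (1 - x / P.K) - a * y / (
            1 + a * P.h * x
        )
        assert prey_fitness(x, y, u, v, P) == pytest.approx(expected, rel=1e-12)

    def test_starving_predator_declines_at_mortality_rate(self):
        assert predator_fitness(0.0, 1.0, 0.3, 0.3, P) == pytest.approx(-P.d)

    def test_predator_breaks_even_at_critical_prey_density(self):
        # u = v = 0 gives a = a0/2; the Holling-II subsistence density
        p = ModelParams(h=1.0, g0=1.0, d=0.1, a0=1.0)
        a = 0.5
        x_star = p.d / (a * (p.g0 - p.d * p.h))
        assert x_star == pytest.approx(0.1 / 0.45)
        assert predator_fitness(x_star, 0.7, 0.0, 0.0, p) == pytest.approx(0.0, abs=1e-14)

    @given(y1=biomass, y2=biomass)
    @settings(max_examples=25, deadline=None)
    def test_predator_fitness_independent_of_own_biomass(self, y1, y2):
        assert predator_fitness(0.4, y1, 0.2, 0.3, P) == predator_fitness(
            0.4, y2, 0.2, 0.3, P
        )


def _central_diff(f, z, dz=1e-6):
    return (f(z + dz) - f(z - dz)) / (2.0 * dz)


class TestFitnessGradients:
    def test_no_predator_defense_is_pure_cost(self):
        grad_u, _ = fitness_gradients(0.5, 0.0, 0.3, 0.2, P)
        assert grad_u < 0

    def test_zero_defense_with_predator_gradient_is_positive(self):
        # r'(0) = 0, so only the predation-release term remains
        grad_u, _ = fitness_gradients(0.5, 0.5, 0.0, 0.2, P)
        assert grad_u > 0

    @given(
        x=st.floats(0.01, 3.0),
        y=st.floats(0.01, 3.0),
        u=traits,
        v=traits,
    )
    @settings(max_examples=100, deadline=None)
    def test_gradients_match_finite_differences(self, x, y, u, v):
        grad_u, grad_v = fitness_gradients(x, y, u, v, P)
        fd_u = _central_diff(lambda z: prey_fitness(x, y, z, v, P), u)
        fd_v = _central_diff(lambda z: predator_fitness(x, y, u, z, P), v)
        assert grad_u == pytest.approx(fd_u, rel=1e-6, abs=1e-9)
        assert grad_v == pytest.approx(fd_v, rel=1e-6, abs=1e-9)


class TestSystemDerivatives:
    def test_no_genetic_variance_freezes_traits(self):
        a = AdaptationParams(Gx=0.0, Gy=0.0)
        _, _, du, dv = system_derivatives(0.5, 0.3, 0.4, 0.6, P, a)
        assert du == 0.0 and dv == 0.0

    def test_boundary_stalls_evolution_at_tiny_traits(self):
        _, _, du_small, _ = system_derivatives(0.5, 0.5, 1e-8, 0.2, P, A)
        assert abs(du_small) < 1e-12  # exp(-eps/u) crushes the gradient

    def test_extinction_is_absorbing_for_biomass(self):
        dx, dy, _, _ = system_derivatives(0.0, 0.0, 0.2, 0.2, P, A)
        assert dx == 0.0 and dy == 0.0

    def test_negative_trait_rejected(self):
        with pytest.raises(ValueError):
            system_derivatives(0.5, 0.3, -0.1, 0.2, P, A)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs", [{"r0": 0.0}, {"K": -1.0}, {"cx": -0.5}, {"h": -0.1}]
    )
    def test_invalid_model_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_invalid_adaptation_params_rejected(self):
        with pytest.raises(ValueError):
            AdaptationParams(Gx=-1.0)
        with pytest.raises(ValueError):
            AdaptationParams(eps=0.0)

    def test_default_tradeoffs_follow_cost_parameters(self):
        p = ModelParams(r0=2.0, cx=4.0)
        assert p.growth_tradeoff == GaussianTradeOff(2.0, 4.0)
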