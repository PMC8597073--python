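"""Closed-form thresholds and the three-way decision rule."""

import math

import numpy as np
import pytest

from fontan_listing import (
    DecisionLabel,
    ModelParams,
    compute_thresholds,
    decide,
    sample_valid_params,
    validate_params,
)
from fontan_listing.thresholds import Thresholds, beta1, beta2, k_high, k_low, p_high, p_low, psi

# frozen high-precision values for the worked example, computed independently
# (quadratic formula / direct arithmetic at mu=2, theta=0.8, r=0.1,
#  delta=0.5, lt=10, lnt=2)
BETA1 = 0.1849632372816139
BETA2 = 0.15238095238095238
PSI = 10.225551440775796
P_HIGH = 0.016965027351712982
P_LOW = 0.5618279569892474
K_HIGH = 2.9283035409749534
K_LOW = 0.1793154889249028


class TestParamValidation:
    def test_example_params_valid(self):
        p = validate_params(2, 0.8, 0.1, 0.5, 10, 2)
        assert p.cost == pytest.approx(1.5)

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(delta=2.5), "delta must be < LNT"),
            (dict(theta=0.5), "theta"),
            (dict(theta=1.2), "theta"),
            (dict(mu=0.0), "mu"),
            (dict(r=-0.1), "r"),
            (dict(lnt=11.0), "LNT must be < LT"),
            (dict(delta=math.nan), "finite"),
        ],
    )
    def test_invalid_params_rejected(self, kwargs, match):
        base = dict(mu=2.0, theta=0.8, r=0.1, delta=0.5, lt=10.0, lnt=2.0)
        base.update(kwargs)
        with pytest.raises(ValueError, match=match):
            ModelParams(**base)


class TestClosedForms:
    def test_beta1_value_and_defining_equation(self, example_params):
        b1 = beta1(example_params)
        assert b1 == pytest.approx(BETA1, abs=1e-12)
        assert b1 * b1 - 1.05 * b1 + 0.16 == pytest.approx(0.0, abs=1e-12)
        assert 0 < b1 < example_params.theta

    def test_beta1_vanishes_with_signal_noise(self):
        # theta(1-theta) -> 0 drives the smaller root to 0
        p = ModelParams(mu=2, theta=0.999999, r=0.1, delta=0.5, lt=10, lnt=2)
        assert beta1(p) < 1e-5

    def test_beta2_value_and_large_discount_limit(self, example_params):
        assert beta2(example_params) == pytest.approx(BETA2, abs=1e-12)
        p = ModelParams(mu=2, theta=0.8, r=1e6, delta=0.5, lt=10, lnt=2)
        assert beta2(p) < 1e-5

    def test_beta2_below_both_signal_weights(self, random_param_sets):
        rng = np.random.default_rng(7)
        for _ in range(80):
            p = sample_valid_params(rng)
            assert beta2(p) < min(p.theta, 1 - p.theta)
        for p in random_param_sets:
            assert beta2(p) < min(p.theta, 1 - p.theta)

    def test_psi_value_and_nonnegativity(self, example_params, random_param_sets):
        assert psi(example_params) == pytest.approx(PSI, abs=1e-9)
        rng = np.random.default_rng(11)
        for _ in range(80):
            assert psi(sample_valid_params(rng)) >= 0
        for p in random_param_sets:
            assert psi(p) >= 0

    def test_psi_limit_near_symmetric_quality(self):
        # numerator and denominator coincide as theta -> 1/2
        p = ModelParams(mu=2, theta=0.5 + 1e-9, r=0.1, delta=0.5, lt=10, lnt=2)
        assert psi(p) == pytest.approx(1.0, rel=1e-5)

    def test_p_high_value(self, example_params):
        assert p_high(example_params) == pytest.approx(P_HIGH, abs=1e-12)

    def test_p_high_decreasing_in_waiting_time(self):
        vals = []
        for d in np.linspace(0.1, 1.9, 19):
            vals.append(p_high(ModelParams(mu=2, theta=0.8, r=0.1, delta=d, lt=10, lnt=2)))
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_p_low_value_and_validity_sweep(self, example_params):
        assert p_low(example_params) == pytest.approx(P_LOW, abs=1e-12)
        rng = np.random.default_rng(13)
        for _ in range(100):
            p = sample_valid_params(rng)  # sampler enforces lt >= 5*lnt
            assert 0 < p_low(p) <= 1

    def test_p_low_rejection_outside_unit_interval(self):
        # long no-transplant life expectancy sends the boundary belief negative
        p = ModelParams(mu=2, theta=0.8, r=0.1, delta=0.5, lt=10, lnt=6)
        with pytest.raises(ValueError, match="not well-defined"):
            p_low(p)

    def test_k_high_and_k_low_values(self, example_params):
        assert k_high(example_params) == pytest.approx(K_HIGH, abs=1e-9)
        assert k_low(example_params) == pytest.approx(K_LOW, abs=1e-9)
        assert round(k_high(example_params), 2) == 2.93
        assert round(k_low(example_params), 2) == 0.18


class TestDecision:
    def test_example_window(self, example_thresholds):
        th = example_thresholds
        assert (th.k_high_floor, th.k_high_ceil) == (2, 3)
        assert (th.k_low_floor, th.k_low_ceil) == (0, 1)
        assert th.window == (1, 2)

    @pytest.mark.parametrize(
        "k, label",
        [
            (2, DecisionLabel.LIST),
            (1, DecisionLabel.LIST),
            (3, DecisionLabel.TOO_WELL),
            (10, DecisionLabel.TOO_WELL),
            (0, DecisionLabel.TOO_UNWELL),
            (-4, DecisionLabel.TOO_UNWELL),
        ],
    )
    def test_three_regions(self, example_thresholds, k, label):
        assert decide(k, example_thresholds).value is label

    def test_regions_partition_integers(self, example_thresholds, random_param_sets):
        for th in [example_thresholds] + [compute_thresholds(p) for p in random_param_sets]:
            labels = [decide(k, th).value for k in range(-10, 30)]
            # each count gets exactly one label and the regions are contiguous
            order = [DecisionLabel.TOO_UNWELL, DecisionLabel.LIST, DecisionLabel.TOO_WELL]
            idx = [order.index(l) for l in labels]
            assert all(a <= b for a, b in zip(idx, idx[1:]))
            assert idx[0] == 0 and idx[-1] == 2

    def test_integer_threshold_tie_breaks(self, example_params):
        # exact-integer thresholds: k = k_high stays listed, k = k_low is unwell
        th = Thresholds(
            params=example_params, beta1=BETA1, beta2=BETA2, psi=PSI,
            p_high=P_HIGH, p_low=P_LOW, k_high=3.0, k_low=1.0,
        )
        assert decide(3, th).value is DecisionLabel.LIST
        assert decide(4, th).value is DecisionLabel.TOO_WELL
        assert decide(1, th).value is DecisionLabel.TOO_UNWELL
        assert decide(2, th).value is DecisionLabel.LIST

    def test_inverted_window_rejected(self, example_params):
        with pytest.raises(ValueError, match="no listing window"):
            Thresholds(
                params=example_params, beta1=BETA1, beta2=BETA2, psi=PSI,
                p_high=P_HIGH, p_low=P_LOW, k_high=0.5, k_low=1.5,
            )

    def test_non_integer_count_rejected(self, example_thresholds):
        with pytest.raises(ValueError):
            decide(1.5, example_thresholds)


class TestMonotonicity:
    """Directions of the listing threshold around the worked example."""

    def test_k_high_increasing_in_delta(self):
        ks = [
            k_high(ModelParams(mu=2, theta=0.8, r=0.1, delta=d, lt=10, lnt=2))
            for d in np.linspace(0.1, 1.9, 19)
        ]
        assert all(a < b for a, b in zip(ks, ks[1:]))

    def test_k_high_decreasing_in_lnt(self):
        ks = [
            k_high(ModelParams(mu=2, theta=0.8, r=0.1, delta=0.5, lt=10, lnt=v))
            for v in np.linspace(1.0, 6.0, 21)
        ]
        assert all(a > b for a, b in zip(ks, ks[1:]))

    def test_k_high_increasing_in_mu(self):
        ks = [
            k_high(ModelParams(mu=m, theta=0.8, r=0.1, delta=0.5, lt=10, lnt=2))
            for m in np.linspace(0.5, 6.0, 23)
        ]
        assert all(a < b for a, b in zip(ks, ks[1:]))

    def test_k_low_floor_invariant_to_delta_and_mu(self):
        floors_d = {
            math.floor(k_low(ModelParams(mu=2, theta=0.8, r=0.1, delta=d, lt=10, lnt=2)))
            for d in np.linspace(0.1, 1.9, 19)
        }
        floors_m = {
            math.floor(k_low(ModelParams(mu=m, theta=0.8, r=0.1, delta=0.5, lt=10, lnt=2)))
            for m in np.linspace(0.5, 6.0, 23)
        }
        assert floors_d == {0} and floors_m == {0}
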