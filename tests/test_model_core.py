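"""Closed-form theory: gradient bias, entropy bookkeeping, flux law, regimes."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from demonpump import (
    DomainError,
    PumpParameters,
    classify_regime,
    delta_S,
    epsilon,
    eta_factor,
    net_efflux,
    outgoing_excess,
    phi_analytic,
    second_law_lhs,
    shannon_entropy,
)
from conftest import draw_random_params

# frozen high-precision evaluations at the worked point k=1, C_h=2, C_l=1
EPS_REF = math.tanh(0.25)            # 0.24491866240370913
ETA_REF = 0.5880358236295022         # 1 - exp(-(1 - tanh(1/4) tanh(1/2)))
PHI_REF = 0.22200743813035057        # (1 - eps)/2 * eta


def params(delta=0.5, k_h=1.0, k_l=1.0, C_h=2.0, C_l=1.0):
    return PumpParameters(delta=delta, k_h=k_h, k_l=k_l, C_h=C_h, C_l=C_l)


class TestParameterValidation:
    def test_derived_proportions(self):
        p = params(delta=0.5)
        assert p.p_t + p.p_d == 1.0
        assert p.p_t - p.p_d == pytest.approx(0.5, abs=1e-15)

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(delta=1.5), "delta"),
            (dict(k_h=0.0), "k_h"),
            (dict(k_l=-1.0), "k_l"),
            (dict(C_h=0.0), "C_h"),
            (dict(C_l=-0.1), "C_l"),
            (dict(C_h=1.0, C_l=2.0), "C_l"),
        ],
    )
    def test_invalid_parameters_name_the_field(self, kwargs, field):
        with pytest.raises(DomainError, match=field):
            params(**kwargs)


class TestEpsilon:
    @pytest.mark.parametrize(
        "C_h, C_l, expected",
        [
            (1.0, 1.0, 0.0),                # no gradient
            (2.0, 0.0, 1.0),                # empty inner reservoir (limit)
            (2.0, 1.0, math.tanh(0.25)),    # worked point
        ],
    )
    def test_values(self, C_h, C_l, expected):
        assert epsilon(params(C_h=C_h, C_l=C_l)) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_concentrations(self):
        ch_grid = np.linspace(1.1, 8.0, 40)
        vals = [epsilon(params(C_h=c)) for c in ch_grid]
        assert np.all(np.diff(vals) > 0)
        cl_grid = np.linspace(0.1, 1.9, 40)
        vals = [epsilon(params(C_l=c)) for c in cl_grid]
        assert np.all(np.diff(vals) < 0)

    def test_bounded_on_random_draws(self, rng):
        for p in draw_random_params(rng, 500):
            e = epsilon(p)
            assert 0.0 <= e <= 1.0
            if p.C_l > 0 and p.C_h > p.C_l:
                assert 0.0 < e


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "excess, expected",
        [
            (1.0, 0.0),
            (-1.0, 0.0),
            (0.0, math.log(2)),
            (0.5, -0.75 * math.log(0.75) - 0.25 * math.log(0.25)),  # 0.56233...
        ],
    )
    def test_values_nat(self, excess, expected):
        assert shannon_entropy(excess) == pytest.approx(expected, abs=1e-12)

    def test_bit_units(self):
        assert shannon_entropy(0.0, base="bit") == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            shannon_entropy(1.0001)

    @given(st.floats(min_value=-1.0, max_value=1.0))
    def test_symmetric_and_below_log2(self, x):
        s = shannon_entropy(x)
        assert s == shannon_entropy(-x)
        assert 0.0 <= s <= math.log(2) + 1e-15

    def test_strictly_concave(self):
        grid = np.linspace(-0.99, 0.99, 67)
        s = np.array([shannon_entropy(x) for x in grid])
        # midpoint value exceeds chord for every adjacent triple
        assert np.all(s[1:-1] > (s[:-2] + s[2:]) / 2)


class TestEtaAndPhi:
    def test_eta_worked_point(self):
        assert eta_factor(params()) == pytest.approx(ETA_REF, abs=1e-12)

    def test_eta_saturating_limit(self):
        p = params(k_h=1e9, k_l=1e9, C_h=2.0, C_l=1.0)
        assert eta_factor(p) == pytest.approx(1 - math.exp(-1), abs=1e-8)

    def test_eta_positive_and_bounded(self, rng):
        for p in draw_random_params(rng, 500):
            eta = eta_factor(p)
            assert 0.0 <= eta <= 1 - math.exp(-1) + 1e-15
            # strictly positive wherever the true value is representable
            # (it underflows double precision once min(a, b) > ~370)
            if min(1 / (2 * p.k_h * p.C_h), 1 / (2 * p.k_l * p.C_l)) < 350:
                assert eta > 0.0

    def test_phi_worked_point(self):
        assert phi_analytic(params(delta=1.0)) == pytest.approx(PHI_REF, abs=1e-12)

    def test_phi_zero_at_stall(self):
        p = params(delta=EPS_REF)
        assert phi_analytic(p) == pytest.approx(0.0, abs=1e-15)

    def test_phi_negative_under_adp_excess(self):
        assert phi_analytic(params(delta=-0.5)) < 0

    def test_phi_linear_in_delta_with_slope_eta_half(self):
        slope = eta_factor(params())
        deltas = np.linspace(-1, 1, 9)
        phis = np.array([phi_analytic(params(delta=d)) for d in deltas])
        expected = (deltas - EPS_REF) / 2 * slope
        np.testing.assert_allclose(phis, expected, atol=1e-14)

    def test_sign_matches_delta_minus_epsilon(self, rng):
        for p in draw_random_params(rng, 1000):
            gap = p.delta - epsilon(p)
            if abs(gap) > 1e-9 and eta_factor(p) > 0.0:
                assert phi_analytic(p) * gap > 0

    def test_net_efflux_equals_phi(self):
        p = params(delta=0.8)
        assert net_efflux(p) == phi_analytic(p)


class TestOutgoingStream:
    def test_identity_when_stalled(self):
        p = params(delta=EPS_REF)
        assert outgoing_excess(p) == pytest.approx(EPS_REF, abs=1e-12)

    def test_worked_point(self):
        assert outgoing_excess(params(delta=1.0)) == pytest.approx(
            1 - 2 * PHI_REF, abs=1e-12
        )

    def test_remains_a_valid_excess(self, rng):
        for p in draw_random_params(rng, 1000):
            assert abs(outgoing_excess(p)) <= 1.0

    def test_delta_S_zero_at_stall(self):
        assert delta_S(params(delta=EPS_REF)) == pytest.approx(0.0, abs=1e-12)

    def test_delta_S_positive_in_pump_regime(self):
        # whenever 0 <= eps < delta the outgoing excess lands in (eps, delta)
        # so entropy rises: transport paid for by information writing
        for delta in [0.5, 0.8, 1.0]:
            p = params(delta=delta)
            assert net_efflux(p) > 0
            assert delta_S(p) > 0

    def test_delta_S_negative_when_erasing_from_balanced_stream(self):
        assert delta_S(params(delta=0.0)) < 0


class TestSecondLaw:
    def test_zero_at_stall(self):
        assert second_law_lhs(params(delta=EPS_REF)) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_on_random_grid(self, rng):
        vals = [second_law_lhs(p) for p in draw_random_params(rng, 10_000)]
        assert min(vals) >= -1e-12

    def test_multiplier_is_twice_artanh_epsilon(self, rng):
        # guard away the saturated tail where artanh amplifies rounding
        for p in draw_random_params(rng, 200):
            e = epsilon(p)
            if e < 0.999:
                mult = (p.C_h - p.C_l) / (p.k_h * p.k_l * p.C_h * p.C_l)
                assert mult == pytest.approx(2 * math.atanh(e), rel=1e-9)

    def test_requires_positive_inner_concentration(self):
        with pytest.raises(DomainError, match="C_l"):
            second_law_lhs(params(C_l=0.0))


class TestRegimeClassification:
    @pytest.mark.parametrize(
        "delta, label",
        [(0.9, "pump"), (0.0, "eraser"), (EPS_REF, "stalled")],
    )
    def test_labels(self, delta, label):
        r = classify_regime(params(delta=delta))
        assert r.label == label

    def test_signs_are_consistent(self, rng):
        for p in draw_random_params(rng, 300):
            if eta_factor(p) == 0.0:
                continue  # flux underflows double precision; sign undefined
            r = classify_regime(p)
            if r.label == "pump":
                assert r.q_sign == 1 and net_efflux(p) > 0
            elif r.label == "eraser":
                assert r.q_sign == -1 and net_efflux(p) < 0
            else:
                assert abs(net_efflux(p)) <= 1e-9
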