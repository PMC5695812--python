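"""Mechanism math: kobs hyperbola, residual activity, assay signal model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covkit.kinetics import (
    AssayMix,
    InactivationObservation,
    InactivationParams,
    NonLinearCurveWarning,
    ProgressCurve,
    ScavengerSpec,
    kobs,
    percent_inhibition,
    rate_from_curve,
    residual_fraction,
    simulate_progress_curve,
)

LEAD = InactivationParams(K_I=40.0, k_inact=0.5)


class TestKobs:
    @pytest.mark.parametrize(
        "I,expected", [(0.0, 0.0), (40.0, 0.25), (1e9, pytest.approx(0.5, rel=1e-6))]
    )
    def test_hyperbola_identities(self, I, expected):
        assert kobs(LEAD, I) == expected

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            kobs(LEAD, -1.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(1.0, 500.0),
        st.floats(0.01, 5.0),
        st.floats(0.0, 1000.0),
        st.floats(0.0, 1000.0),
    )
    def test_monotone_concave_bounded(self, K_I, k_inact, a, b):
        p = InactivationParams(K_I, k_inact)
        lo, hi = sorted((a, b))
        assert kobs(p, lo) <= kobs(p, hi) <= k_inact
        mid = (lo + hi) / 2
        assert kobs(p, mid) >= (kobs(p, lo) + kobs(p, hi)) / 2 - 1e-12  # concavity
        assert kobs(p, K_I) == pytest.approx(k_inact / 2, rel=1e-12)


class TestResidualFraction:
    def test_zero_time(self):
        assert residual_fraction(LEAD, 100.0, 0.0) == 1.0

    def test_closed_form_at_half_saturation(self):
        assert residual_fraction(LEAD, 40.0, 5.0) == pytest.approx(math.exp(-1.25), rel=1e-12)

    def test_inert_scavenger_equals_closed_form(self):
        inert = ScavengerSpec(concentration=1.0, k2=0.0)
        for I, t in [(10, 1), (40, 5), (90, 30)]:
            assert residual_fraction(LEAD, I, t, inert) == pytest.approx(
                residual_fraction(LEAD, I, t), rel=1e-8
            )

    def test_quadrature_matches_analytic_decaying_inhibitor(self):
        # independent oracle: with I(s) = I e^{-ks} the exposure integral has
        # the closed form (1/k) ln((K_I + I)/(K_I + I e^{-kt}))
        sc = ScavengerSpec(concentration=1.0, k2=1000.0)  # k = 1 /min
        k = sc.pseudo_first_order_rate
        for I, t in [(10.0, 2.0), (40.0, 5.0), (90.0, 30.0)]:
            closed = math.exp(
                -LEAD.k_inact / k * math.log((LEAD.K_I + I) / (LEAD.K_I + I * math.exp(-k * t)))
            )
            assert residual_fraction(LEAD, I, t, sc) == pytest.approx(closed, rel=1e-7)

    def test_scavenger_long_time_floor(self):
        # total exposure is finite when the inhibitor decays, so residual
        # activity plateaus at exp(-k_inact/k * ln(1 + I/K_I)) > 0
        sc = ScavengerSpec(concentration=1.0, k2=2000.0)
        k = sc.pseudo_first_order_rate
        I = 40.0
        floor = math.exp(-LEAD.k_inact / k * math.log(1 + I / LEAD.K_I))
        assert residual_fraction(LEAD, I, 1e4, sc) == pytest.approx(floor, rel=1e-6)
        assert residual_fraction(LEAD, I, 1e4, sc) > 0

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(0.0, 200.0), st.floats(0.0, 60.0), st.floats(0.0, 60.0))
    def test_monotone_in_time(self, I, t1, t2):
        lo, hi = sorted((t1, t2))
        assert residual_fraction(LEAD, I, hi) <= residual_fraction(LEAD, I, lo) + 1e-12


class TestProgressCurve:
    def test_blank_well_is_flat(self):
        curve = simulate_progress_curve(AssayMix(), 0.0, 0.05, 5.0, 11)
        assert len(set(curve.A340)) == 1

    def test_slope_proportional_to_activity(self):
        mix = AssayMix()
        r1 = rate_from_curve(simulate_progress_curve(mix, 0.1, 0.05, 5.0, 11))
        r2 = rate_from_curve(simulate_progress_curve(mix, 0.2, 0.05, 5.0, 11))
        assert r2 == pytest.approx(2 * r1, rel=1e-9)
        assert r1 < 0

    def test_nadph_limited_plateau(self):
        # disulfide substrate in excess of NADPH: the trace bottoms out after
        # consuming all 0.2 mM NADPH, a drop of epsilon * l * 2e-4 AU
        mix = AssayMix(nadph_mM=0.2, cyssg_mM=0.4)
        with pytest.warns(NonLinearCurveWarning):
            curve = simulate_progress_curve(mix, 50.0, 0.05, 60.0, 61)
        drop = curve.A340[0] - curve.A340[-1]
        assert drop == pytest.approx(mix.epsilon340 * mix.path_cm * 0.2e-3, rel=1e-9)
        assert curve.A340[-1] == curve.A340[-2]  # flat after depletion

    def test_nadph_conservation(self):
        import warnings as _warnings

        mix = AssayMix()
        volume_l = 0.05e-3
        for activity in (0.05, 0.2, 5.0, 500.0):
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", NonLinearCurveWarning)
                curve = simulate_progress_curve(mix, activity, 0.05, 20.0, 6)
            consumed = (curve.A340[0] - min(curve.A340)) / (mix.epsilon340 * mix.path_cm) * volume_l
            assert consumed <= mix.nadph_mM * 1e-3 * volume_l + 1e-18
            assert consumed <= mix.cyssg_mM * 1e-3 * volume_l + 1e-18

    def test_early_depletion_warns(self):
        with pytest.warns(NonLinearCurveWarning):
            simulate_progress_curve(AssayMix(), 1e4, 0.05, 20.0, 6)

    def test_never_negative(self):
        curve = simulate_progress_curve(AssayMix(blank_rate=0.5), 0.0, 0.05, 10.0, 21)
        assert min(curve.A340) >= 0.0

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            ProgressCurve((0.0, 1.0), (1.0,))
        with pytest.raises(ValueError):
            ProgressCurve((1.0, 2.0), (1.0, 0.9))
        with pytest.raises(ValueError):
            ProgressCurve((0.0, 0.0), (1.0, 0.9))


class TestRateAndInhibition:
    def test_ols_on_exact_line(self):
        times = tuple(np.linspace(0, 5, 11))
        curve = ProgressCurve(times, tuple(1.0 - 0.01 * t for t in times))
        assert rate_from_curve(curve) == pytest.approx(-0.01, abs=1e-12)

    def test_constant_curve_zero_slope(self):
        curve = ProgressCurve((0.0, 1.0, 2.0), (0.5, 0.5, 0.5))
        assert rate_from_curve(curve) == pytest.approx(0.0, abs=1e-12)

    def test_two_point_curve_is_secant(self):
        curve = ProgressCurve((0.0, 4.0), (1.0, 0.8))
        assert rate_from_curve(curve) == pytest.approx(-0.05)

    def test_window_too_small(self):
        curve = ProgressCurve((0.0, 1.0, 2.0), (1.0, 0.9, 0.8))
        with pytest.raises(ValueError):
            rate_from_curve(curve, window=(0.0, 0.5))

    @pytest.mark.parametrize(
        "treated,expected", [(-0.01, 0.0), (0.0, 100.0), (-0.005, 50.0)]
    )
    def test_percent_inhibition(self, treated, expected):
        assert percent_inhibition(treated, -0.01, 0.0) == pytest.approx(expected)

    def test_collapsed_window_rejected(self):
        with pytest.raises(ValueError):
            percent_inhibition(-0.005, -0.01, -0.01)


class TestDomainValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"K_I": 0.0, "k_inact": 0.5},
            {"K_I": -1.0, "k_inact": 0.5},
            {"K_I": 40.0, "k_inact": -0.1},
            {"K_I": math.inf, "k_inact": 0.5},
        ],
    )
    def test_bad_params(self, kwargs):
        with pytest.raises(ValueError):
            InactivationParams(**kwargs)

    def test_bad_observation(self):
        with pytest.raises(ValueError):
            InactivationObservation(I=10, E0=0.0, Et=1.0, t=5.0)
        with pytest.raises(ValueError):
            InactivationObservation(I=10, E0=4.0, Et=1.0, t=0.0)
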