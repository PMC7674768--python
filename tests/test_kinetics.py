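"""Planar quantification, isotope conversion, washout fitting, residence times."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actichain import (
    AC225_HALF_LIFE_H,
    LU177_HALF_LIFE_H,
    FitError,
    PlanarCounts,
    TimeActivityCurve,
    TimeActivityModel,
    apply_physical_decay,
    conjugate_view_fraction,
    convert_isotope,
    decay_correct,
    fit_exponential,
    tew_scatter_correct,
)

LN2 = math.log(2.0)


def make_tac(times, values, organ="parotid", half_life=math.inf):
    return TimeActivityCurve(organ, tuple(times), tuple(values), physical_half_life_h=half_life)


class TestPlanarQuantification:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((1000, 0, 0, 41.6, 17.5, 23.8), 1000.0),       # no scatter
            ((1000, 100, 100, 40, 20, 20), 800.0),          # hand-evaluated trapezoid
            ((100, 1000, 1000, 40, 20, 20), 0.0),           # clamped at zero
        ],
    )
    def test_tew_formula(self, args, expected):
        assert tew_scatter_correct(*args) == pytest.approx(expected)

    def test_tew_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            tew_scatter_correct(-1, 0, 0, 40, 20, 20)

    @pytest.mark.parametrize(
        "organ, ref, expected",
        [
            (PlanarCounts(400, 100), PlanarCounts(10000, 10000), 0.02),
            (PlanarCounts(123, 456), PlanarCounts(123, 456), 1.0),
            (PlanarCounts(0, 500), PlanarCounts(100, 100), 0.0),
        ],
    )
    def test_conjugate_view_geometric_mean(self, organ, ref, expected):
        assert conjugate_view_fraction(organ, ref) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            conjugate_view_fraction(PlanarCounts(10, 10), PlanarCounts(0, 100))


class TestDecayCorrection:
    def test_one_half_life_doubles_value(self):
        tac = make_tac([100.0], [0.5], half_life=100.0)
        assert decay_correct(tac).values[0] == pytest.approx(1.0)

    def test_round_trip_is_identity(self):
        t = [0.75, 20.0, 42.0, 120.0]
        v = [0.04, 0.02, 0.015, 0.005]
        tac = make_tac(t, v, half_life=LU177_HALF_LIFE_H)
        back = apply_physical_decay(decay_correct(tac), LU177_HALF_LIFE_H)
        assert np.allclose(back.v, v, rtol=1e-12)

    def test_lu_to_ac_conversion_closed_form(self):
        # per-point factor exp(ln2·t·(1/T_Lu − 1/T_Ac)), checked at 120 h
        tac = make_tac([120.0], [0.01], half_life=LU177_HALF_LIFE_H)
        converted = convert_isotope(tac, AC225_HALF_LIFE_H)
        factor = math.exp(LN2 * 120.0 * (1 / LU177_HALF_LIFE_H - 1 / AC225_HALF_LIFE_H))
        assert converted.values[0] == pytest.approx(0.01 * factor, rel=1e-12)
        assert converted.physical_half_life_h == AC225_HALF_LIFE_H

    def test_decay_correct_marks_curve_biological(self):
        tac = make_tac([1.0], [0.5], half_life=100.0)
        assert math.isinf(decay_correct(tac).physical_half_life_h)


class TestValidation:
    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            make_tac([1.0, 1.0], [0.1, 0.1])

    def test_values_nonnegative(self):
        with pytest.raises(ValueError):
            make_tac([1.0, 2.0], [0.1, -0.1])


class TestExponentialFit:
    def test_noiseless_mono_recovery(self):
        t = np.array([1.0, 20.0, 40.0, 120.0])
        fit = fit_exponential(make_tac(t, 0.05 * np.exp(-0.0272 * t)))
        assert fit.amplitudes[0] == pytest.approx(0.05, rel=1e-6)
        assert fit.rates[0] == pytest.approx(0.0272, rel=1e-6)
        # parotid-like washout: effective half-life of the cohort median
        assert fit.effective_half_life_h == pytest.approx(25.5, abs=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_exponential(make_tac([1.0], [0.1]))
        with pytest.raises(FitError):
            fit_exponential(make_tac([1.0, 2.0, 3.0], [0.3, 0.2, 0.1]), model="bi")

    def test_constant_curve_hits_rate_floor(self):
        # degenerate washout: the rate is driven to its lower bound
        t = [1.0, 20.0, 40.0, 120.0]
        fit = fit_exponential(make_tac(t, [0.05] * 4))
        assert fit.rates[0] == pytest.approx(1e-6, rel=1.0)

    def test_bi_slow_phase_rule(self):
        t = np.linspace(0.5, 120, 8)
        v = 0.02 * np.exp(-0.02 * t) + 0.03 * np.exp(-0.5 * t)
        fit = fit_exponential(make_tac(t, v), model="bi")
        assert fit.model == "bi"
        assert fit.rates[0] < fit.rates[1]
        assert fit.slow_rate == pytest.approx(0.02, rel=1e-4)
        assert fit.effective_half_life_h == pytest.approx(LN2 / 0.02, rel=1e-4)

    def test_bi_recovery_under_noise(self, rng):
        """Median recovered slow rate within 15% of truth at 5% noise."""
        A1, l1, A2, l2 = 0.02, 0.015, 0.03, 0.3
        errs = []
        for _ in range(200):
            t = np.sort(
                np.concatenate(
                    [rng.uniform(0.5, 1, 1), rng.uniform(16, 24, 1),
                     rng.uniform(36, 48, 1), rng.uniform(118, 122, 1),
                     rng.uniform(2, 10, 2)]
                )
            )
            clean = A1 * np.exp(-l1 * t) + A2 * np.exp(-l2 * t)
            noisy = clean * rng.lognormal(0, 0.05, t.size)
            fit = fit_exponential(make_tac(t, noisy), model="bi")
            errs.append(fit.slow_rate / l1 - 1.0)
        assert abs(np.median(errs)) < 0.15

    def test_summary_mentions_key_quantities(self):
        t = np.array([1.0, 20.0, 40.0, 120.0])
        s = fit_exponential(make_tac(t, 0.05 * np.exp(-0.0272 * t))).summary()
        assert "effective half-life" in s and "residence time" in s


class TestResidenceTime:
    @pytest.mark.parametrize(
        "amps, rates, expected",
        [
            ((0.05,), (0.0272,), 0.05 / 0.0272),       # A/λ = 1.8382 h
            ((0.03, 0.02), (0.3, 0.02), 0.1 + 1.0),    # additive across terms
        ],
    )
    def test_analytic_integral(self, amps, rates, expected):
        from actichain.kinetics import ExponentialFitResults

        order = sorted(range(len(rates)), key=lambda i: rates[i])  # slow phase first
        fit = ExponentialFitResults(
            model="bi" if len(amps) == 2 else "mono",
            amplitudes=tuple(amps[i] for i in order),
            rates=tuple(rates[i] for i in order),
            rss=0.0,
            nobs=4,
        )
        assert fit.residence_time_h == pytest.approx(expected, rel=1e-12)

    def test_quadrature_oracle(self):
        """Trapezoid to 10·T_eff plus analytic tail agrees within 0.5%."""
        A, lam = 0.04, 0.03
        t = np.linspace(0, 10 * LN2 / lam, 20001)
        numeric = np.trapezoid(A * np.exp(-lam * t), t) + A * np.exp(-lam * t[-1]) / lam
        fit = fit_exponential(make_tac([1, 20, 40, 120], A * np.exp(-lam * np.array([1, 20, 40, 120]))))
        assert fit.residence_time_h == pytest.approx(numeric, rel=0.005)

    @settings(derandomize=True, max_examples=50)
    @given(
        A=st.floats(1e-4, 0.5), lam_bio=st.floats(1e-3, 1.0), scale=st.floats(0.1, 10.0)
    )
    def test_linearity_in_amplitude_and_isotope_conversion(self, A, lam_bio, scale):
        """τ is linear in amplitude, and folding in the Ac-225 physical decay
        multiplies the pure biological integral by λ_bio/(λ_bio+λ_phys)."""
        lam_ac = LN2 / AC225_HALF_LIFE_H
        tau_bio = A / lam_bio
        tau_ac = A / (lam_bio + lam_ac)
        assert (scale * A) / lam_bio == pytest.approx(scale * tau_bio, rel=1e-12)
        assert tau_ac == pytest.approx(tau_bio * lam_bio / (lam_bio + lam_ac), rel=1e-12)
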