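"""Chromatographic descriptor calculations against closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from protacprofiler.chromatography import (
    ChromatographicSystem,
    IonizationClass,
    RetentionMeasurement,
    brlogd,
    capacity_factor,
    chamelogk,
    classify_chameleon,
    clogkw_iam,
    compute_descriptors,
    delta_logkw_iam,
    etr,
    fit_retention_line,
    ionization_class,
    logkw_iam_extrapolate,
)
from protacprofiler.errors import (
    InsufficientDataError,
    InvalidDeadTimeError,
    InvalidDenominatorError,
    NonRetainedSoluteError,
)

finite = st.floats(-10, 10, allow_nan=False)


class TestCapacityFactor:
    @pytest.mark.parametrize(
        "t_r,t_0,expected",
        [(2.0, 1.0, 0.0), (11.0, 1.0, 1.0), (1.5, 1.0, math.log10(0.5))],
    )
    def test_examples(self, t_r, t_0, expected):
        assert capacity_factor(t_r, t_0) == pytest.approx(expected, abs=1e-12)

    def test_non_retained_solute_rejected(self):
        with pytest.raises(NonRetainedSoluteError):
            capacity_factor(0.9, 1.0)
        with pytest.raises(NonRetainedSoluteError):
            capacity_factor(1.0, 1.0)

    def test_invalid_dead_time_rejected(self):
        with pytest.raises(InvalidDeadTimeError):
            capacity_factor(2.0, 0.0)

    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    def test_strictly_increasing_in_retention_time(self, k1, k2):
        t_0 = 1.3
        if math.isclose(k1, k2):
            return
        lo, hi = sorted([k1, k2])
        assert capacity_factor(t_0 * (1 + lo), t_0) < capacity_factor(
            t_0 * (1 + hi), t_0
        )

    def test_measurement_invariants(self):
        with pytest.raises(NonRetainedSoluteError):
            RetentionMeasurement("X", ChromatographicSystem.RP18, 60, 7, 0.8, 1.0)


class TestCalibrationLines:
    def test_brlogd_intercept_and_root(self):
        assert brlogd(0.0) == pytest.approx(2.79, abs=1e-12)
        assert brlogd(-2.79 / 3.31) == pytest.approx(0.0, abs=1e-12)
        assert brlogd(1.0) == pytest.approx(6.10, abs=1e-9)

    def test_clogkw_iam_intercept_and_root(self):
        assert clogkw_iam(0.0) == pytest.approx(-1.03, abs=1e-12)
        assert clogkw_iam(1.03 / 0.92) == pytest.approx(0.0, abs=1e-12)
        assert clogkw_iam(2.0) == pytest.approx(0.81, abs=1e-9)

    @given(finite, finite, st.floats(0, 1))
    def test_affine_consistency(self, x, y, alpha):
        mix = alpha * x + (1 - alpha) * y
        for f in (brlogd, clogkw_iam):
            assert f(mix) == pytest.approx(
                alpha * f(x) + (1 - alpha) * f(y), abs=1e-8
            )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            brlogd(float("nan"))


class TestDeltaLogkwIam:
    @given(finite, finite)
    def test_self_consistency(self, b, d):
        delta, _ = delta_logkw_iam(clogkw_iam(b) + d, b)
        assert delta == pytest.approx(d, abs=1e-9)

    def test_examples_and_flag(self):
        delta, flagged = delta_logkw_iam(2.0, 2.0)
        assert delta == pytest.approx(1.19, abs=1e-9)
        assert not flagged
        delta, flagged = delta_logkw_iam(2.4, 0.0)
        assert delta == pytest.approx(3.43, abs=1e-9)
        assert flagged


class TestRetentionLine:
    def test_exact_collinear(self):
        line = fit_retention_line([(50, -0.5), (60, -1.0), (70, -1.5)])
        assert line.slope == pytest.approx(-0.05, abs=1e-12)
        assert line.intercept == pytest.approx(2.0, abs=1e-10)
        assert line.r2 == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(-3, 3), st.floats(-0.1, 0.1))
    def test_recovers_any_planted_line(self, a, b):
        line = fit_retention_line([(f, a + b * f) for f in (50, 60, 70)])
        assert line.slope == pytest.approx(b, abs=1e-7)
        assert line.intercept == pytest.approx(a, abs=1e-6)

    def test_matches_closed_form_ols_on_noisy_data(self, rng):
        x = np.array([50.0, 60.0, 70.0])
        y = 2.0 - 0.05 * x + rng.normal(0, 0.01, size=3)
        line = fit_retention_line(list(zip(x, y)))
        # normal-equation oracle
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert line.intercept == pytest.approx(beta[0], abs=1e-10)
        assert line.slope == pytest.approx(beta[1], abs=1e-12)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_retention_line([(50, 1.0)])
        with pytest.raises(InsufficientDataError):
            fit_retention_line([(50, 1.0), (50, 1.2)])


class TestLogkwIamExtrapolation:
    def test_exact_line_intercept(self):
        assert logkw_iam_extrapolate(
            [(10, 2.9), (30, 2.7), (50, 2.5)]
        ) == pytest.approx(3.0, abs=1e-10)

    def test_single_point_rejected(self):
        with pytest.raises(InsufficientDataError):
            logkw_iam_extrapolate([(30, 2.7)])

    def test_noisy_recovery_within_ols_error(self, rng):
        x = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        est = [
            logkw_iam_extrapolate(
                list(zip(x, 2.5 - 0.02 * x + rng.normal(0, 0.02, 5)))
            )
            for _ in range(200)
        ]
        assert np.mean(est) == pytest.approx(2.5, abs=0.06)

    def test_extrapolation_target_is_configurable(self):
        pts = [(10, 2.9), (30, 2.7), (50, 2.5)]
        assert logkw_iam_extrapolate(pts, at_fraction=100.0) == pytest.approx(
            2.5 - 0.5, abs=1e-10
        )


class TestChamelogk:
    def test_zero_when_measured_equals_extrapolation(self):
        pts = {50: -0.5, 60: -1.0, 70: -1.5}
        value, strong = chamelogk(pts, -3.0)
        assert value == pytest.approx(0.0, abs=1e-10)
        assert not strong

    @given(st.floats(-2, 4), st.floats(-0.08, -0.02), st.floats(-1, 2))
    def test_planted_offset_recovered(self, a, b, offset):
        pts = {f: a + b * f for f in (50, 60, 70)}
        value, _ = chamelogk(pts, a + 100 * b + offset)
        assert value == pytest.approx(offset, abs=1e-7)

    def test_strong_chameleon_threshold(self):
        pts = {50: 0.0, 60: -0.5, 70: -1.0}
        value, strong = chamelogk(pts, -2.5 + 0.65)
        assert value == pytest.approx(0.65, abs=1e-10)
        assert strong
        assert classify_chameleon(0.65)
        assert not classify_chameleon(0.6)

    @given(st.floats(-2, 2))
    def test_invariant_to_constant_shift(self, c):
        pts = {50: -0.5, 60: -1.0, 70: -1.5}
        v0, _ = chamelogk(pts, -2.2)
        v1, _ = chamelogk({k: v + c for k, v in pts.items()}, -2.2 + c)
        assert v1 == pytest.approx(v0, abs=1e-8)

    def test_extra_composition_warns_and_is_ignored(self):
        pts = {50: -0.5, 60: -1.0, 70: -1.5, 80: -3.0}
        with pytest.warns(UserWarning):
            value, _ = chamelogk(pts, -2.2)
        assert value == pytest.approx(0.8, abs=1e-10)

    def test_missing_observation_rejected(self):
        with pytest.raises(InsufficientDataError):
            chamelogk({50: -0.5, 60: -1.0}, -2.2)


class TestEtr:
    @given(st.floats(1, 500))
    def test_identity_ratio(self, x):
        assert etr(x, x) == pytest.approx(1.0)

    def test_example(self):
        assert etr(140, 200) == pytest.approx(0.7)

    def test_zero_tpsa_rejected(self):
        with pytest.raises(InvalidDenominatorError):
            etr(120, 0)


class TestIonizationClass:
    @pytest.mark.parametrize(
        "profile,expected",
        [
            ({2: 1.0, 7: 1.0, 12: 1.0}, IonizationClass.NEUTRAL),
            # a base still partially ionized at pH 7: retention recovers
            # only at high pH
            ({2: 0.1, 7: 0.4, 12: 1.0}, IonizationClass.BASE_IONIZED),
            ({2: 1.0, 7: 0.4, 12: 0.1}, IonizationClass.ACID_IONIZED),
            # dominantly neutral at pH 7 wins even with basic-side depression
            ({2: 0.2, 7: 1.0, 12: 1.0}, IonizationClass.NEUTRAL),
            ({2: 1.0, 7: 0.9, 12: 0.2}, IonizationClass.NEUTRAL),
            ({2: 1.0, 7: 0.5, 12: 0.2}, IonizationClass.ACID_IONIZED),
            # NEUTRAL takes priority whenever pH-7 retention sits at the
            # profile maximum, even with both extremes depressed
            ({2: 0.3, 7: 1.0, 12: 0.3}, IonizationClass.NEUTRAL),
        ],
    )
    def test_rule_evaluation(self, profile, expected):
        assert ionization_class(profile) is expected

    def test_missing_ph_gives_undetermined_with_warning(self):
        with pytest.warns(UserWarning):
            assert (
                ionization_class({2: 1.0, 7: 1.0}) is IonizationClass.UNDETERMINED
            )


class TestComputeDescriptors:
    def test_full_suite_from_measurements(self):
        t0 = 1.0
        mk = lambda sys, frac, ph, logk: RetentionMeasurement(
            "CPD", sys, frac, ph, t0 * (1 + 10**logk), t0
        )
        a, b = 2.0, -0.05
        ms = [
            mk(ChromatographicSystem.RP18, 60.0, 7.0, 0.5),
            mk(ChromatographicSystem.PLRP_S, 80.0, 7.0, 0.8),
            mk(ChromatographicSystem.PLRP_S, 80.0, 2.0, 0.8),
            mk(ChromatographicSystem.PLRP_S, 80.0, 12.0, 0.8),
            *[
                mk(ChromatographicSystem.PLRP_S, f, 7.0, a + b * f)
                for f in (50.0, 60.0, 70.0)
            ],
            mk(ChromatographicSystem.PLRP_S, 100.0, 7.0, a + 100 * b + 0.9),
            *[
                mk(ChromatographicSystem.IAM, f, 7.0, 2.5 - 0.03 * f)
                for f in (10.0, 30.0, 50.0)
            ],
        ]
        (rec,) = compute_descriptors(ms, {"CPD": {"epsa": 140.0, "tpsa": 200.0}})
        assert rec.logk60_rp18 == pytest.approx(0.5, abs=1e-9)
        assert rec.brlogd == pytest.approx(3.31 * 0.5 + 2.79, abs=1e-9)
        assert rec.chamelogk == pytest.approx(0.9, abs=1e-8)
        assert "strong_chameleon" in rec.flags
        assert rec.ionization_class is IonizationClass.NEUTRAL
        assert rec.logkw_iam == pytest.approx(2.5, abs=1e-8)
        assert rec.delta_logkw_iam == pytest.approx(
            2.5 - (0.92 * rec.brlogd - 1.03), abs=1e-8
        )
        assert rec.etr == pytest.approx(0.7)

    def test_missing_inputs_stay_missing(self):
        ms = [
            RetentionMeasurement(
                "X", ChromatographicSystem.RP18, 60.0, 7.0, 4.0, 1.0
            )
        ]
        (rec,) = compute_descriptors(ms)
        assert rec.brlogd is not None
        assert rec.chamelogk is None
        assert rec.etr is None
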