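"""Kinetic-parameter extraction: smoothing, onset detection, the 17 features."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pupilperim as pp
from pupilperim.features import (
    PARAMETER_NAMES,
    ExtractionSettings,
    UnusableTraceError,
    smooth_and_differentiate,
)
from pupilperim.synth import velocity_peak_time

from conftest import random_shape


def _trace_from_array(d, fs=30.0, condition=pp.Condition.dim_blue):
    d = np.asarray(d, dtype=float)
    return pp.PupilTrace(
        subject_id="S0", eye=pp.Eye.right, condition=condition,
        target_index=1, times=np.arange(len(d)) / fs, diameters=d,
    )


class TestSmoothing:
    def test_constant_trace_has_zero_derivatives(self):
        kin = smooth_and_differentiate(_trace_from_array(np.full(120, 6.0)))
        assert np.allclose(kin.velocity, 0.0, atol=1e-10)
        assert np.allclose(kin.acceleration, 0.0, atol=1e-8)

    def test_linear_ramp_has_constant_velocity_equal_to_slope(self):
        t = np.arange(120) / 30.0
        kin = smooth_and_differentiate(_trace_from_array(6.0 - 0.25 * t))
        assert np.allclose(kin.velocity, -0.25, atol=1e-9)
        assert np.allclose(kin.acceleration, 0.0, atol=1e-7)

    def test_velocity_extremum_matches_analytic_optimum(self, default_shape, dim_blue_spec):
        tr = pp.simulate_trace(default_shape, dim_blue_spec, 30.0, 0)
        kin = smooth_and_differentiate(tr)
        t_star = kin.times[np.argmin(kin.velocity)]
        assert t_star == pytest.approx(velocity_peak_time(default_shape), abs=1 / 30.0)

    def test_missing_samples_interpolated_and_flagged(self, default_shape, dim_blue_spec):
        tr = pp.simulate_trace(default_shape, dim_blue_spec, 30.0, 0)
        tr.diameters[40:44] = np.nan
        kin = smooth_and_differentiate(tr)
        assert kin.missing.sum() == 4
        assert np.isfinite(kin.diameter).all()

    def test_mostly_missing_trace_rejected(self):
        d = np.full(120, 6.0)
        d[: 70] = np.nan
        with pytest.raises(UnusableTraceError):
            smooth_and_differentiate(_trace_from_array(d))

    def test_bad_settings_rejected(self):
        with pytest.raises(ValueError):
            ExtractionSettings(smooth_window=6)
        with pytest.raises(ValueError):
            ExtractionSettings(smooth_window=3, poly_order=2)


class TestOnsetDetection:
    def test_noise_free_latency_recovered_within_one_sample(self, dim_blue_spec):
        sh = pp.PLRShapeParams(6.0, 0.478, 0.9, 0.9, 1.5, 0.0)
        fx = pp.extract_parameters(pp.simulate_trace(sh, dim_blue_spec, 30.0, 0))
        assert fx.PRL == pytest.approx(0.478, abs=1 / 30.0)

    def test_flat_trace_yields_undefined(self):
        fx = pp.extract_parameters(_trace_from_array(np.full(120, 6.0)))
        assert all(math.isnan(v) for v in fx.to_dict().values())

    def test_translation_equivariance(self, dim_blue_spec):
        base = pp.PLRShapeParams(6.0, 0.45, 0.9, 0.9, 1.5, 0.0)
        shifted = pp.PLRShapeParams(6.0, 0.48, 0.9, 0.9, 1.5, 0.0)
        f0 = pp.extract_parameters(pp.simulate_trace(base, dim_blue_spec, 30.0, 0))
        f1 = pp.extract_parameters(pp.simulate_trace(shifted, dim_blue_spec, 30.0, 0))
        assert f1.PRL - f0.PRL == pytest.approx(0.03, abs=1 / 30.0)

    def test_noise_robustness_median_error_under_two_samples(self, dim_blue_spec):
        sh = pp.PLRShapeParams(6.0, 0.478, 0.9, 0.9, 1.5, noise_sd_mm=0.02)
        errs = []
        for seed in range(200):
            fx = pp.extract_parameters(pp.simulate_trace(sh, dim_blue_spec, 30.0, seed))
            if not math.isnan(fx.PRL):
                errs.append(abs(fx.PRL - 0.478))
        assert len(errs) >= 190
        assert np.median(errs) < 2 / 30.0


class TestParameterSet:
    def test_seventeen_named_parameters(self, default_shape, dim_blue_spec):
        fx = pp.extract_parameters(pp.simulate_trace(default_shape, dim_blue_spec, 30.0, 0))
        d = fx.to_dict()
        assert len(d) == 17
        assert tuple(d) == PARAMETER_NAMES

    def test_amplitude_and_percent_contraction(self, default_shape, dim_blue_spec):
        fx = pp.extract_parameters(pp.simulate_trace(default_shape, dim_blue_spec, 30.0, 0))
        assert fx.AC == pytest.approx(0.9, abs=1e-3)
        assert fx.PPC == pytest.approx(15.0, abs=0.1)
        assert fx.LMP == pytest.approx(0.478 + 0.9, abs=1 / 30.0)

    def test_full_recovery_gives_prp_100(self, dim_blue_spec):
        sh = pp.PLRShapeParams(6.0, 0.3, 0.9, 0.7, 0.15, 0.0)  # fast redilation
        fx = pp.extract_parameters(pp.simulate_trace(sh, dim_blue_spec, 30.0, 0))
        assert fx.PRP == pytest.approx(100.0, abs=0.5)

    def test_unusable_trace_gives_all_missing(self, dim_blue_spec):
        tr = pp.simulate_trace(pp.PLRShapeParams(6, 0.4, 0.9, 0.9, 1.5), dim_blue_spec, 30.0, 0)
        tr.diameters[:] = np.nan
        fx = pp.extract_parameters(tr)
        assert all(math.isnan(v) for v in fx.to_dict().values())

    def test_thirty_four_parameters_per_dim_pair(self):
        # one dim-red and one dim-blue response per target -> 34 values
        sh = pp.PLRShapeParams(6.0, 0.45, 0.9, 0.9, 1.5, 0.0)
        traces = [
            pp.simulate_trace(sh, pp.STIMULI[c], 30.0, 0, target_index=5)
            for c in (pp.Condition.dim_red, pp.Condition.dim_blue)
        ]
        df = pp.extract_features(traces)
        values = df[list(PARAMETER_NAMES)].to_numpy().ravel()
        assert values.size == 34
        assert np.isfinite(values).all()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_contraction_latency_ordering_invariant(self, seed):
        """PRL <= LMCV <= LMP and PRL <= LMCA <= LMCD <= LMP on model traces."""
        rng = np.random.default_rng(seed)
        sh = random_shape(rng, noise_sd=rng.uniform(0, 0.02))
        tr = pp.simulate_trace(sh, pp.STIMULI[pp.Condition.dim_blue], 30.0, rng)
        fx = pp.extract_parameters(tr)
        tol = 1e-9
        if not any(math.isnan(v) for v in (fx.PRL, fx.LMCV, fx.LMP)):
            assert fx.PRL <= fx.LMCV + tol <= fx.LMP + 2 * tol
        if not any(math.isnan(v) for v in (fx.PRL, fx.LMCA, fx.LMCD, fx.LMP)):
            assert fx.PRL <= fx.LMCA + tol
            assert fx.LMCA <= fx.LMCD + tol <= fx.LMP + 2 * tol

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_percentages_clipped_and_magnitudes_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        sh = random_shape(rng, noise_sd=rng.uniform(0, 0.03))
        fx = pp.extract_parameters(
            pp.simulate_trace(sh, pp.STIMULI[pp.Condition.dim_blue], 30.0, rng))
        for name in ("PPC", "PRP"):
            v = getattr(fx, name)
            assert math.isnan(v) or 0 <= v <= 100
        for name in ("AC", "MCV", "MCA", "MCD", "MRV", "MRA", "MRD"):
            v = getattr(fx, name)
            assert math.isnan(v) or v >= 0
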