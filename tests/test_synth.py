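"""Synthetic-cohort generator: waveform model, cohort structure, missingness."""

import math

import numpy as np
import pytest

import pupilperim as pp
from pupilperim.synth import contraction_kernel, noise_free_diameter, velocity_peak_time

from conftest import random_shape


class TestWaveform:
    def test_zero_amplitude_gives_constant_trace(self, dim_blue_spec):
        shape = pp.PLRShapeParams(6.0, 0.4, 0.0, 0.9, 1.5, 0.0)
        tr = pp.simulate_trace(shape, dim_blue_spec, 30.0, 0)
        assert np.allclose(tr.diameters, 6.0)
        assert len(tr.times) == 120
        assert np.allclose(np.diff(tr.times), 1 / 30.0)

    def test_trough_depth_and_location_closed_form(self, default_shape, dim_blue_spec):
        # dense evaluation: minimum D_b - A at exactly t = L + t_p
        t = np.linspace(0, 4, 40001)
        d = noise_free_diameter(t, default_shape, dim_blue_spec)
        i = d.argmin()
        assert d[i] == pytest.approx(6.0 - 0.9, abs=1e-6)
        assert t[i] == pytest.approx(0.478 + 0.9, abs=2e-4)
        # percent contraction 15% >= the 10% the stimuli are chosen to evoke
        assert 100 * (6.0 - d[i]) / 6.0 == pytest.approx(15.0, abs=0.01)

    def test_kernel_peak_is_unity_at_tp(self):
        assert contraction_kernel(0.9, 0.9, 1.5) == pytest.approx(1.0)
        assert contraction_kernel(-0.1, 0.9, 1.5) == 0.0

    def test_max_contraction_velocity_time_analytic(self, default_shape, dim_blue_spec):
        # root of the analytic second derivative: L + t_p (1 - sqrt(2)/2)
        t = np.linspace(0, 4, 40001)
        d = noise_free_diameter(t, default_shape, dim_blue_spec)
        v = np.gradient(d, t)
        t_star = t[v.argmin()]
        expected = velocity_peak_time(default_shape)
        assert expected == pytest.approx(0.478 + 0.9 * (1 - math.sqrt(2) / 2), abs=1e-12)
        assert t_star == pytest.approx(expected, abs=1e-3)

    def test_bright_condition_adds_sustained_component(self):
        shape = pp.PLRShapeParams(6.0, 0.4, 0.9, 0.9, 1.5, 0.0,
                                  sustained_amplitude_mm=0.4, sustained_tau_s=2.0)
        spec = pp.STIMULI[pp.Condition.bright_blue]
        t = np.linspace(0, 16, 1601)
        d = noise_free_diameter(t, shape, spec)
        # near stimulus offset the transient has decayed but the sustained
        # component keeps the pupil constricted below baseline
        assert d[t == 8.0][0] < 6.0 - 0.25
        assert len(pp.simulate_trace(shape, spec, 30.0, 0).times) == 480

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            pp.PLRShapeParams(6.0, 0.4, 6.5, 0.9, 1.5)
        with pytest.raises(ValueError):
            pp.PLRShapeParams(6.0, -0.1, 0.9, 0.9, 1.5)
        with pytest.raises(ValueError):
            pp.PLRShapeParams(6.0, 0.4, 0.9, 0.9, 1.5, noise_sd_mm=-1)

    def test_trace_determinism(self, dim_blue_spec):
        sh = pp.PLRShapeParams(6.0, 0.4, 0.9, 0.9, 1.5, 0.02)
        a = pp.simulate_trace(sh, dim_blue_spec, 30.0, 123)
        b = pp.simulate_trace(sh, dim_blue_spec, 30.0, 123)
        assert np.array_equal(a.diameters, b.diameters)


class TestCohort:
    def test_group_sizes_match_design(self):
        cfg = pp.CohortConfig(conditions=(pp.Condition.dim_blue,),
                              eyes=(pp.Eye.right,), seed=0,
                              missingness_rate=0.0, blink_rate=0.0)
        cohort = pp.simulate_cohort(cfg)
        counts = cohort.subjects["group"].value_counts()
        assert counts["FHpos"] == 125 and counts["FHneg"] == 61
        assert len(cohort.traces) == 186 * 54

    def test_cohort_determinism(self):
        cfg = pp.CohortConfig(n_subjects=12, n_fh_pos=8, seed=5,
                              conditions=(pp.Condition.dim_blue,),
                              eyes=(pp.Eye.right,))
        a, b = pp.simulate_cohort(cfg), pp.simulate_cohort(cfg)
        assert a.subjects.equals(b.subjects)
        for ta, tb in zip(a.traces, b.traces):
            assert np.array_equal(ta.diameters, tb.diameters, equal_nan=True)
        assert a.missing_mask == b.missing_mask

    def test_effect_latency_truth_recovers_configured_mean(self):
        cfg = pp.CohortConfig(conditions=(pp.Condition.dim_blue,),
                              eyes=(pp.Eye.right,), seed=3,
                              missingness_rate=0.0, blink_rate=0.0)
        cohort = pp.simulate_cohort(cfg)
        pos_ids = set(cohort.subjects.query("group == 'FHpos'")["subject_id"])
        lats = [tr.truth.latency_s for tr in cohort.traces
                if tr.subject_id in pos_ids and tr.target_index in cfg.effect_targets]
        n = len(lats)
        sd = math.sqrt(cfg.between_subject_sd**2 + cfg.target_jitter_sd**2)
        assert np.mean(lats) == pytest.approx(cfg.latency_fh_pos,
                                              abs=3 * sd / math.sqrt(n))

    def test_null_config_removes_group_effect(self):
        cfg = pp.null_config(n_subjects=10, n_fh_pos=5)
        assert cfg.latency_fh_pos == cfg.latency_fh_neg == cfg.latency_other

    def test_ages_truncated_and_group_specific(self):
        cfg = pp.CohortConfig(conditions=(pp.Condition.dim_blue,),
                              eyes=(pp.Eye.right,), seed=1,
                              missingness_rate=0.0, blink_rate=0.0)
        subjects = pp.simulate_cohort(cfg).subjects
        assert subjects["age_years"].between(44, 71).all()
        assert subjects.query("group == 'FHpos'")["age_years"].mean() == pytest.approx(
            59.93, abs=3 * 6.69 / math.sqrt(125))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pp.CohortConfig(n_subjects=10, n_fh_pos=10)


class TestMissingness:
    def test_zero_rate_leaves_everything_observed(self):
        cfg = pp.CohortConfig(n_subjects=10, n_fh_pos=6, missingness_rate=0.0,
                              blink_rate=0.0, conditions=(pp.Condition.dim_blue,),
                              eyes=(pp.Eye.right,), seed=2)
        cohort = pp.simulate_cohort(cfg)
        assert cohort.n_masked == 0
        assert all(np.isfinite(tr.diameters).all() for tr in cohort.traces)

    def test_rate_recovered_within_binomial_error(self):
        cfg = pp.CohortConfig(missingness_rate=0.0076, blink_rate=0.0,
                              conditions=(pp.Condition.dim_red, pp.Condition.dim_blue),
                              eyes=(pp.Eye.right, pp.Eye.left), seed=7)
        cohort = pp.simulate_cohort(cfg)
        n = len(cohort.traces)
        frac = cohort.n_masked / n
        se = math.sqrt(0.0076 * (1 - 0.0076) / n)
        assert frac == pytest.approx(0.0076, abs=3 * se)
        # masked traces are entirely NaN
        key = cohort.missing_mask[0]
        tr = next(t for t in cohort.traces
                  if (t.subject_id, t.eye.value, t.condition.value, t.target_index) == key)
        assert np.isnan(tr.diameters).all()

    def test_invalid_rate_rejected(self):
        cohort = pp.Cohort(traces=[], subjects=None)
        with pytest.raises(ValueError):
            pp.inject_missingness(cohort, 1.5)


def test_blink_retest_rule_keeps_first_window_clean():
    # blinks must never land inside the protected first 2.5 s; retests counted
    cfg = pp.CohortConfig(n_subjects=10, n_fh_pos=6, blink_rate=1.0,
                          missingness_rate=0.0, conditions=(pp.Condition.dim_blue,),
                          eyes=(pp.Eye.right,), seed=9)
    cohort = pp.simulate_cohort(cfg)
    for tr in cohort.traces:
        gap = np.flatnonzero(np.isnan(tr.diameters))
        assert len(gap) > 0
        assert tr.times[gap[0]] >= 2.5
    assert cohort.n_retests > 0


def test_noise_free_extraction_recovers_truth(dim_blue_spec):
    # generator/extractor consistency on random noise-free draws
    rng = np.random.default_rng(11)
    for _ in range(20):
        sh = random_shape(rng)
        fx = pp.extract_parameters(pp.simulate_trace(sh, dim_blue_spec, 30.0, 1))
        assert fx.PRL == pytest.approx(sh.latency_s, abs=1 / 30.0)
        assert fx.AC == pytest.approx(sh.amplitude_mm, abs=1e-3)
        assert fx.LMP == pytest.approx(sh.latency_s + sh.time_to_peak_s, abs=1 / 30.0)
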