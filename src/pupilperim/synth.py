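"""Synthetic chromatic-pupilloperimetry cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: per-subject, per-target transient pupil light reflex (PLR) traces
with a case/control difference in contraction latency concentrated at a
small set of visual-field targets, plus measurement noise, occasional
blinks and a low rate of whole-response missingness.

Waveform model
--------------
The noise-free pupil diameter is

    D(t) = D_b - A * k(t - L) - sustained(t)

with a gamma-shaped contraction kernel

    k(u) = (u / t_p)^2 * exp(2 * (1 - u / t_p)) * exp(-max(0, u - t_p) / tau_r)

for u >= 0 and k = 0 otherwise.  The kernel rises smoothly from zero
(zero initial velocity), peaks at exactly 1 when u = t_p, and then decays
with redilation time constant ``tau_r``; the multiplicative redilation
factor equals 1 at the peak, so the waveform is continuous there.  The
pre-peak branch has closed-form velocity and acceleration extrema; in
particular maximal contraction velocity occurs at u = t_p * (1 - sqrt(2)/2),
which downstream extraction tests use as an analytic oracle.

Bright (melanopsin-probing) conditions add a slow sustained component
A_s * (1 - exp(-(t - L) / tau_s)) while the stimulus is on, decaying with
time constant 2 * tau_s after light offset.

Default cohort composition follows the study design this pipeline targets:
125 subjects with a parental family history of Alzheimer's disease (FH+)
and 61 without (FH-), ages ~N(59.9, 6.7) / N(59.1, 5.6) truncated to
44-71 years, and a shorter FH+ contraction latency (0.450 s vs 0.477 s)
injected at the two peripheral temporal-field targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .protocol import (
    BRIGHT_CONDITIONS,
    STIMULI,
    TEMPORAL_PERIPHERY_TARGETS,
    Condition,
    Eye,
    StimulusSpec,
    VisualFieldGrid,
)

__all__ = [
    "PLRShapeParams",
    "PupilTrace",
    "CohortConfig",
    "Cohort",
    "simulate_trace",
    "simulate_cohort",
    "inject_missingness",
    "contraction_kernel",
    "velocity_peak_time",
]


@dataclass(frozen=True)
class PLRShapeParams:
    """Ground-truth waveform parameters for one pupil response.

    Attributes
    ----------
    baseline_mm:
        Pre-stimulus pupil diameter D_b (mm); must be positive.
    latency_s:
        Contraction latency L from stimulus onset (s).
    amplitude_mm:
        Transient contraction amplitude A (mm); 0 <= A < D_b.
    time_to_peak_s:
        Time from contraction onset to maximal contraction t_p (s).
    redilation_tau_s:
        Redilation time constant tau_r (s).
    noise_sd_mm:
        Per-sample Gaussian measurement noise SD sigma (mm).
    sustained_amplitude_mm:
        Sustained (melanopsin-like) amplitude A_s (mm); used only for
        bright conditions.
    sustained_tau_s:
        Sustained component time constant tau_s (s).
    """

    baseline_mm: float
    latency_s: float
    amplitude_mm: float
    time_to_peak_s: float
    redilation_tau_s: float
    noise_sd_mm: float = 0.0
    sustained_amplitude_mm: float = 0.0
    sustained_tau_s: float = 2.0

    def __post_init__(self) -> None:
        if not self.baseline_mm > 0:
            raise ValueError("baseline diameter must be positive")
        if not 0 <= self.amplitude_mm < self.baseline_mm:
            raise ValueError("contraction amplitude must satisfy 0 <= A < D_b")
        if self.latency_s < 0:
            raise ValueError("latency must be non-negative")
        if not self.time_to_peak_s > 0:
            raise ValueError("time to peak must be positive")
        if not self.redilation_tau_s > 0:
            raise ValueError("redilation tau must be positive")
        if self.noise_sd_mm < 0:
            raise ValueError("noise SD must be non-negative")
        if self.sustained_amplitude_mm < 0:
            raise ValueError("sustained amplitude must be non-negative")
        if self.amplitude_mm + self.sustained_amplitude_mm >= self.baseline_mm:
            raise ValueError("total contraction must stay below baseline diameter")
        if not self.sustained_tau_s > 0:
            raise ValueError("sustained tau must be positive")


@dataclass
class PupilTrace:
    """One sampled pupil-diameter time series for (subject, eye, condition, target).

    ``times`` is a uniform grid starting at the stimulus onset (t = 0);
    ``diameters`` may contain NaN for missing samples.  ``truth`` carries the
    generating parameters when the trace is synthetic.
    """

    subject_id: str
    eye: Eye
    condition: Condition
    target_index: int
    times: np.ndarray
    diameters: np.ndarray
    stimulus_onset: float = 0.0
    truth: PLRShapeParams | None = None

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])


def contraction_kernel(
    u: np.ndarray | float, time_to_peak: float, redilation_tau: float
) -> np.ndarray:
    """Evaluate the unit-peak contraction kernel k(u) (see module docstring)."""
    u = np.asarray(u, dtype=float)
    v = np.clip(u, 0.0, None) / time_to_peak
    shape = v**2 * np.exp(2.0 * (1.0 - v))
    decay = np.exp(-np.clip(u - time_to_peak, 0.0, None) / redilation_tau)
    return np.where(u > 0, shape * decay, 0.0)


def velocity_peak_time(shape: PLRShapeParams) -> float:
    """Analytic time of maximal contraction velocity, L + t_p * (1 - sqrt(2)/2)."""
    return shape.latency_s + shape.time_to_peak_s * (1.0 - math.sqrt(2.0) / 2.0)


def _sustained(
    t: np.ndarray, shape: PLRShapeParams, stim_duration: float
) -> np.ndarray:
    if shape.sustained_amplitude_mm == 0:
        return np.zeros_like(t)
    u = t - shape.latency_s
    rise = shape.sustained_amplitude_mm * (1.0 - np.exp(-np.clip(u, 0.0, None) / shape.sustained_tau_s))
    rise = np.where(u > 0, rise, 0.0)
    off = stim_duration
    at_off = shape.sustained_amplitude_mm * (
        1.0 - math.exp(-max(off - shape.latency_s, 0.0) / shape.sustained_tau_s)
    )
    post = at_off * np.exp(-(t - off) / (2.0 * shape.sustained_tau_s))
    return np.where(t <= off, rise, post)


def noise_free_diameter(
    t: np.ndarray, shape: PLRShapeParams, spec: StimulusSpec
) -> np.ndarray:
    """Closed-form noise-free diameter D(t) in mm."""
    t = np.asarray(t, dtype=float)
    d = shape.baseline_mm - shape.amplitude_mm * contraction_kernel(
        t - shape.latency_s, shape.time_to_peak_s, shape.redilation_tau_s
    )
    if spec.condition in BRIGHT_CONDITIONS:
        d = d - _sustained(t, shape, spec.stim_duration_s)
    return d


def simulate_trace(
    shape: PLRShapeParams,
    spec: StimulusSpec,
    sampling_rate: float = 30.0,
    seed: int | np.random.Generator | None = None,
    *,
    subject_id: str = "S000",
    eye: Eye | str = Eye.right,
    target_index: int = 1,
) -> PupilTrace:
    """Simulate one pupil trace on a uniform grid from stimulus onset.

    Gaussian noise of SD ``shape.noise_sd_mm`` is added per sample.  The
    generating parameters are stored in ``truth``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(spec.record_duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate
    d = noise_free_diameter(t, shape, spec)
    if shape.noise_sd_mm > 0:
        d = d + rng.normal(0.0, shape.noise_sd_mm, size=n)
    return PupilTrace(
        subject_id=subject_id,
        eye=Eye(eye),
        condition=spec.condition,
        target_index=target_index,
        times=t,
        diameters=d,
        truth=shape,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level simulation settings.

    Defaults reproduce the study design the pipeline targets: 186 subjects
    (125 FH+, 61 FH-), group contraction latencies 0.450 s (FH+) vs 0.477 s
    (FH-) injected at the two peripheral temporal-field targets of each eye,
    0.76% whole-response missingness, 30 Hz sampling.
    """

    n_subjects: int = 186
    n_fh_pos: int = 125
    effect_targets: tuple[int, ...] = TEMPORAL_PERIPHERY_TARGETS
    latency_fh_pos: float = 0.450
    latency_fh_neg: float = 0.477
    latency_other: float = 0.460
    between_subject_sd: float = 0.012
    target_jitter_sd: float = 0.005
    missingness_rate: float = 0.0076
    blink_rate: float = 0.02
    noise_sd_mm: float = 0.015
    sampling_rate: float = 30.0
    conditions: tuple[Condition, ...] = (
        Condition.dim_red,
        Condition.dim_blue,
        Condition.bright_red,
        Condition.bright_blue,
    )
    eyes: tuple[Eye, ...] = (Eye.right, Eye.left)
    seed: int = 0

    # Group-specific age models (mean, SD), truncated to 44-71 years.
    age_fh_pos: tuple[float, float] = (59.93, 6.69)
    age_fh_neg: tuple[float, float] = (59.08, 5.56)
    female_frac_fh_pos: float = 0.60
    female_frac_fh_neg: float = 0.74

    def __post_init__(self) -> None:
        if self.n_fh_pos > self.n_subjects:
            raise ValueError("n_fh_pos cannot exceed n_subjects")
        if self.n_fh_pos < 1 or self.n_subjects - self.n_fh_pos < 1:
            raise ValueError("both FH+ and FH- groups must be non-empty")
        if not 0 <= self.missingness_rate < 1:
            raise ValueError("missingness rate must lie in [0, 1)")
        if any(not 1 <= t <= 54 for t in self.effect_targets):
            raise ValueError("effect targets must be 24-2 indices in 1..54")


@dataclass
class Cohort:
    """A simulated cohort: traces, subject table, and missingness mask.

    ``subjects`` columns: subject_id, group (FHpos/FHneg), age_years, sex.
    ``missing_mask`` lists the (subject_id, eye, condition, target_index)
    responses that were blanked by :func:`inject_missingness`.
    """

    traces: list[PupilTrace]
    subjects: pd.DataFrame
    missing_mask: list[tuple[str, str, str, int]] = field(default_factory=list)
    n_retests: int = 0

    @property
    def n_masked(self) -> int:
        return len(self.missing_mask)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _apply_blink(
    trace: PupilTrace, rng: np.random.Generator, gap_s: float = 0.15
) -> int:
    """Insert one blink gap, retesting (redrawing) if it falls in the first 2.5 s.

    Mirrors the acquisition rule that a target at which the subject blinked
    during the first 2.5 s after light onset is automatically retested.
    Returns the number of retests performed.
    """
    n = len(trace.times)
    fs = trace.sampling_rate
    gap = max(1, int(round(gap_s * fs)))
    retests = 0
    while True:
        start = rng.uniform(0.0, trace.times[-1])
        if start >= 2.5:
            break
        retests += 1  # blink inside the protected window: retest the target
    i0 = int(start * fs)
    trace.diameters[i0 : min(i0 + gap, n)] = np.nan
    return retests


def simulate_cohort(
    config: CohortConfig,
    grid: VisualFieldGrid | None = None,
    specs: Iterable[StimulusSpec] | None = None,
) -> Cohort:
    """Simulate a full cohort of pupil traces with known ground truth.

    Latency structure: each subject draws one effect-target latency from the
    group-specific distribution N(latency_group, between_subject_sd), shared
    across the configured ``effect_targets`` of both eyes, and one background
    latency from N(latency_other, between_subject_sd) shared across all other
    targets; every individual response adds independent N(0, target_jitter_sd)
    jitter.  Pupil size, contraction amplitude (drawn to give 12-18% pupil
    contraction), time-to-peak and redilation tau vary between subjects.

    Deterministic for a fixed config (``config.seed``).
    """
    rng = np.random.default_rng(config.seed)
    if specs is None:
        specs = [STIMULI[c] for c in config.conditions]
    specs = list(specs)

    n_pos = config.n_fh_pos
    n_neg = config.n_subjects - n_pos
    groups = ["FHpos"] * n_pos + ["FHneg"] * n_neg
    ages = np.concatenate(
        [
            _truncated_normal(rng, *config.age_fh_pos, 44.0, 71.0, n_pos),
            _truncated_normal(rng, *config.age_fh_neg, 44.0, 71.0, n_neg),
        ]
    )
    female = np.concatenate(
        [
            rng.random(n_pos) < config.female_frac_fh_pos,
            rng.random(n_neg) < config.female_frac_fh_neg,
        ]
    )
    ids = [f"S{i:03d}" for i in range(config.n_subjects)]
    subjects = pd.DataFrame(
        {
            "subject_id": ids,
            "group": groups,
            "age_years": np.round(ages, 1),
            "sex": np.where(female, "F", "M"),
        }
    )

    effect = set(config.effect_targets)
    traces: list[PupilTrace] = []
    n_retests = 0
    for sid, group in zip(ids, groups):
        lat_group = config.latency_fh_pos if group == "FHpos" else config.latency_fh_neg
        lat_effect = rng.normal(lat_group, config.between_subject_sd)
        lat_base = rng.normal(config.latency_other, config.between_subject_sd)
        d_b = rng.normal(6.0, 0.5)
        d_b = float(np.clip(d_b, 4.5, 8.0))
        ppc = float(np.clip(rng.normal(0.15, 0.03), 0.08, 0.25))
        t_p = float(np.clip(rng.normal(0.90, 0.08), 0.6, 1.2))
        tau_r = float(np.clip(rng.normal(1.5, 0.25), 0.8, 2.5))
        a_sus = float(np.clip(rng.normal(0.05, 0.015), 0.0, 0.12)) * d_b

        for eye in config.eyes:
            for spec in specs:
                bright = spec.condition in BRIGHT_CONDITIONS
                for target in range(1, spec.n_targets + 1):
                    if not bright and target in effect:
                        lat = lat_effect
                    else:
                        lat = lat_base
                    lat = max(0.15, lat + rng.normal(0.0, config.target_jitter_sd))
                    shape = PLRShapeParams(
                        baseline_mm=d_b,
                        latency_s=lat,
                        amplitude_mm=ppc * d_b,
                        time_to_peak_s=t_p,
                        redilation_tau_s=tau_r,
                        noise_sd_mm=config.noise_sd_mm,
                        sustained_amplitude_mm=a_sus if bright else 0.0,
                    )
                    trace = simulate_trace(
                        shape,
                        spec,
                        sampling_rate=config.sampling_rate,
                        seed=rng,
                        subject_id=sid,
                        eye=eye,
                        target_index=target,
                    )
                    if config.blink_rate > 0 and rng.random() < config.blink_rate:
                        n_retests += _apply_blink(trace, rng)
                    traces.append(trace)

    cohort = Cohort(traces=traces, subjects=subjects, n_retests=n_retests)
    if config.missingness_rate > 0:
        inject_missingness(cohort, config.missingness_rate, seed=rng)
    return cohort


def inject_missingness(
    cohort: Cohort,
    rate: float,
    seed: int | np.random.Generator | None = None,
) -> Cohort:
    """Blank whole (subject, eye, condition, target) responses at random.

    Each response is marked missing independently with probability ``rate``,
    emulating feature-level missingness: a blanked response yields a missing
    cell in every per-parameter feature table downstream.  The blanked keys
    are appended to ``cohort.missing_mask``.  Modifies the cohort in place
    and returns it.
    """
    if not 0 <= rate < 1:
        raise ValueError("missingness rate must lie in [0, 1)")
    if rate == 0:
        return cohort
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.random(len(cohort.traces))
    for trace, u in zip(cohort.traces, draws):
        if u < rate:
            trace.diameters[:] = np.nan
            cohort.missing_mask.append(
                (trace.subject_id, trace.eye.value, trace.condition.value, trace.target_index)
            )
    return cohort


def null_config(**overrides) -> CohortConfig:
    """A no-effect configuration: both groups share the background latency."""
    base = CohortConfig(**overrides)
    return replace(
        base, latency_fh_pos=base.latency_other, latency_fh_neg=base.latency_other
    )
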