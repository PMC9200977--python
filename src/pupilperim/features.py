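"""Extraction of the 17 pupil-light-reflex kinetic parameters from one trace.

The parameter set covers both the contraction and the redilation arm of the
transient PLR (Table abbreviations in parentheses):

==========  ===========================================================
AC          contraction amplitude, baseline minus trough diameter (mm)
PPC         percentage of pupil contraction, 100 * AC / baseline (%)
PRL         pupil response latency: stimulus onset to contraction onset (s)
LMP         latency of maximal pupil contraction (trough time) (s)
MCV / LMCV  maximal contraction velocity (mm/s) and its latency (s)
MCA / LMCA  maximal contraction acceleration (mm/s^2) and latency (s)
MCD / LMCD  maximal contraction deceleration (mm/s^2) and latency (s)
MRV / LMRV  maximal redilation velocity (mm/s) and latency (s)
MRA / LMRA  maximal redilation acceleration (mm/s^2) and latency (s)
MRD / LMRD  maximal redilation deceleration (mm/s^2) and latency (s)
PRP         percent pupil recovery at the end of the recording (%)
==========  ===========================================================

All latencies are measured from stimulus onset.  Velocity and acceleration
come from a Savitzky-Golay local-polynomial fit of the diameter trace, so
they are analytic derivatives of the local fit rather than raw finite
differences.  Any parameter may be undefined (NaN) — e.g. when no
contraction is detected — and undefined values propagate downstream as
missing feature cells.

Operational definitions that the source protocol leaves open (baseline
window, onset criterion, recovery definition) are centralised in
:class:`ExtractionSettings` so alternative readings can be swapped without
touching callers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_coeffs, savgol_filter

from .protocol import STIMULI
from .synth import PupilTrace

__all__ = [
    "PARAMETER_NAMES",
    "ExtractionSettings",
    "KinematicSeries",
    "PLRFeatureSet",
    "UnusableTraceError",
    "smooth_and_differentiate",
    "detect_contraction_onset",
    "extract_parameters",
    "extract_features",
]

PARAMETER_NAMES: tuple[str, ...] = (
    "AC", "PPC", "PRL", "LMP",
    "MCV", "LMCV", "MCA", "LMCA", "MCD", "LMCD",
    "MRV", "LMRV", "MRA", "LMRA", "MRD", "LMRD",
    "PRP",
)


class UnusableTraceError(ValueError):
    """Raised when a trace has too many missing samples to analyse."""


@dataclass(frozen=True)
class ExtractionSettings:
    """Tunable extraction settings with the package defaults.

    smooth_window / poly_order:
        Savitzky-Golay window (samples, odd) and polynomial order.
    onset_threshold_frac:
        Contraction onset is located by walking back from the maximal
        contraction velocity to where speed falls below this fraction of
        MCV, then extrapolating the local velocity segment to zero.
    baseline_samples:
        Number of initial smoothed samples averaged for the baseline
        diameter (traces start at stimulus onset, before any response).
    noise_floor_mult:
        MCV must exceed this multiple of the robust pre-response velocity
        SD for a contraction to count as detected.
    contraction_extra_s:
        The contraction search window runs from onset to stimulus offset
        plus this margin.
    max_missing_frac:
        Traces with more than this fraction of missing samples are
        rejected as unusable.
    end_samples:
        Number of final smoothed samples averaged for the end-of-recording
        diameter used by PRP.
    """

    smooth_window: int = 7
    poly_order: int = 2
    onset_threshold_frac: float = 0.1
    baseline_samples: int = 2
    noise_floor_mult: float = 3.0
    contraction_extra_s: float = 1.0
    max_missing_frac: float = 0.5
    end_samples: int = 2

    def __post_init__(self) -> None:
        if self.smooth_window % 2 == 0 or self.smooth_window < self.poly_order + 2:
            raise ValueError("window must be odd and >= poly_order + 2")
        if not 0 < self.onset_threshold_frac < 1:
            raise ValueError("onset threshold fraction must lie in (0, 1)")


@dataclass
class KinematicSeries:
    """Smoothed diameter with analytic first and second derivatives.

    ``raw`` is the unsmoothed diameter after interpolation of missing
    samples; the onset detector fits its change-point on it because
    smoothing smears the contraction onset across the filter window.
    """

    times: np.ndarray
    diameter: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray
    missing: np.ndarray  # boolean mask of samples that were interpolated
    raw: np.ndarray | None = None


@dataclass(frozen=True)
class PLRFeatureSet:
    """The 17 named kinetic parameters of one trace; NaN marks undefined."""

    AC: float = math.nan
    PPC: float = math.nan
    PRL: float = math.nan
    LMP: float = math.nan
    MCV: float = math.nan
    LMCV: float = math.nan
    MCA: float = math.nan
    LMCA: float = math.nan
    MCD: float = math.nan
    LMCD: float = math.nan
    MRV: float = math.nan
    LMRV: float = math.nan
    MRA: float = math.nan
    LMRA: float = math.nan
    MRD: float = math.nan
    LMRD: float = math.nan
    PRP: float = math.nan

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAMETER_NAMES])


def smooth_and_differentiate(
    trace: PupilTrace, settings: ExtractionSettings | None = None
) -> KinematicSeries:
    """Savitzky-Golay smoothing and analytic differentiation of a trace.

    Missing samples are linearly interpolated before smoothing and
    re-flagged in the returned ``missing`` mask.  Traces with more than
    ``max_missing_frac`` missing samples raise :class:`UnusableTraceError`.
    """
    settings = settings or ExtractionSettings()
    d = np.asarray(trace.diameters, dtype=float)
    t = np.asarray(trace.times, dtype=float)
    if len(t) < settings.smooth_window:
        raise UnusableTraceError("trace shorter than the smoothing window")
    dt = float(t[1] - t[0])
    if not np.allclose(np.diff(t), dt, rtol=0, atol=1e-9):
        raise UnusableTraceError("time grid is not uniform")
    missing = ~np.isfinite(d)
    if missing.mean() > settings.max_missing_frac:
        raise UnusableTraceError(
            f"{missing.mean():.0%} of samples missing exceeds the usability limit"
        )
    if missing.any():
        valid = ~missing
        d = d.copy()
        d[missing] = np.interp(t[missing], t[valid], d[valid])
    w, p = settings.smooth_window, settings.poly_order
    smooth = savgol_filter(d, w, p)
    vel = savgol_filter(d, w, p, deriv=1, delta=dt)
    acc = savgol_filter(d, w, p, deriv=2, delta=dt)
    return KinematicSeries(times=t, diameter=smooth, velocity=vel,
                           acceleration=acc, missing=missing, raw=d)


from functools import lru_cache


@lru_cache(maxsize=32)
def _deriv_kernel_norm(window: int, order: int, dt: float) -> float:
    return float(np.linalg.norm(savgol_coeffs(window, order, deriv=1, delta=dt)))


def velocity_noise_sd(kin: KinematicSeries, settings: ExtractionSettings) -> float:
    """Robust estimate of the noise SD of the velocity series.

    The diameter noise SD is estimated from the median absolute first
    difference of the raw trace (differencing suppresses the slowly
    varying physiological signal) and propagated through the norm of the
    Savitzky-Golay derivative kernel.
    """
    d = kin.raw if kin.raw is not None else kin.diameter
    dt = float(kin.times[1] - kin.times[0])
    diffs = np.abs(np.diff(d))
    sigma_d = float(np.median(diffs)) / (0.6745 * math.sqrt(2.0))
    return sigma_d * _deriv_kernel_norm(settings.smooth_window,
                                        settings.poly_order, round(dt, 9))


def _robust_sd(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def _changepoint_refine(
    t: np.ndarray,
    d: np.ndarray,
    start: int,
    t_lo: float,
    t_hi: float,
    window_end: float,
    beta: float = 0.0,
    n_refine: int = 24,
) -> float:
    """Least-squares change-point: flat baseline, then a rising decline.

    For each candidate onset L the model is d = b for t <= L and
    d = b - c * (t - L)^2 * exp(-beta * (t - L)) afterwards, with b and
    c >= 0 fit by least squares over the fixed window
    [t[start], window_end] shared by all candidates.  With beta = 0 this
    is the generic quadratic leading-order onset; a positive beta matches
    a gamma-shaped contraction whose peak occurs 2/beta after the onset.
    A coarse sample-aligned pass is refined on a fine grid around the
    best candidate.  Returns the L with minimal residual sum of squares.
    """
    dt = float(t[1] - t[0])
    sel = slice(start, int(np.searchsorted(t, window_end, "right")))
    ts, ds = t[sel], d[sel]
    if len(ts) < 4:
        return float(t_hi)
    n_s = len(ts)
    sd_ = ds.sum()

    def sse(L: np.ndarray) -> np.ndarray:
        u = np.clip(ts[None, :] - L[:, None], 0.0, None)
        q = u * u
        if beta:
            q = q * np.exp(-beta * u)
        # per-candidate normal equations for [b, -c] against columns [1, q]
        sq = q.sum(axis=1)
        sqq = (q * q).sum(axis=1)
        sdq = q @ ds
        det = n_s * sqq - sq * sq
        safe = det > 0
        det = np.where(safe, det, 1.0)
        b = np.where(safe, (sqq * sd_ - sq * sdq) / det, sd_ / n_s)
        c = np.where(safe, -(n_s * sdq - sq * sd_) / det, 0.0)
        c = np.clip(c, 0.0, None)
        resid = ds[None, :] - (b[:, None] - c[:, None] * q)
        return (resid * resid).sum(axis=1)

    coarse = t[(t >= t_lo) & (t <= t_hi)]
    if len(coarse) == 0:
        coarse = np.array([t_lo])
    best = float(coarse[int(np.argmin(sse(coarse)))])
    fine = best + (np.arange(n_refine + 1) / n_refine - 0.5) * 2.0 * dt
    fine = fine[(fine >= t_lo) & (fine <= t_hi)]
    if len(fine):
        best = float(fine[int(np.argmin(sse(fine)))])
    return best


def detect_contraction_onset(
    kin: KinematicSeries,
    stimulus_onset: float = 0.0,
    threshold_frac: float = 0.1,
    noise_floor_mult: float = 3.0,
    window_end: float | None = None,
    noise_sd: float | None = None,
) -> float:
    """Pupil response latency (PRL); NaN when no contraction is detected.

    Three stages.  First the contraction is located on the smoothed
    velocity: the maximal contraction speed (MCV) inside the search window
    is found, and the detector walks back from it to the first sample at
    which the speed falls below ``threshold_frac * MCV``, which brackets
    the onset from below; the half-maximum speed crossing bounds it from
    above (speed is zero at the onset).  Second, the onset is localised by
    a change-point least-squares fit of a flat baseline followed by a
    quadratic decline on the raw diameter trace.  Third, the fit is
    repeated with the gamma-form decline c*u^2*exp(-beta*u), with beta
    set from the provisional onset-to-trough interval, which removes the
    curvature bias of the pure quadratic over longer fit windows.  The
    bracket-then-refine split makes the detector robust to noise
    excursions before the true onset, while fitting the change-point on
    the raw trace avoids the early bias that smoothing imposes on any
    velocity zero-crossing at video sampling rates.

    Returns NaN when MCV does not exceed ``noise_floor_mult`` times the
    robust SD of the early (pre-response) velocity, i.e. no contraction.
    """
    t, vel = kin.times, kin.velocity
    dt = float(t[1] - t[0])
    start = int(np.searchsorted(t, stimulus_onset))
    end = len(t) if window_end is None else int(np.searchsorted(t, window_end, "right"))
    if end - start < 3:
        return math.nan
    speed = -vel[start:end]
    imax = int(np.argmax(speed)) + start
    mcv = -vel[imax]
    if noise_sd is None:
        n_pre = max(8, int(round(0.25 / dt)))
        noise_sd = _robust_sd(vel[start : start + n_pre])
    if mcv <= max(noise_floor_mult * noise_sd, 1e-9):
        return math.nan
    # Bracket: the onset lies between the last sub-threshold sample before
    # the speed maximum and the half-maximum speed crossing (speed is zero
    # at the onset, so it must precede the half-max crossing).
    thr = -threshold_frac * mcv
    k = imax
    while k > start and vel[k] < thr:
        k -= 1
    k_half = imax
    while k_half > start and vel[k_half] < -0.5 * mcv:
        k_half -= 1
    d = kin.raw if kin.raw is not None else kin.diameter
    t_hi = float(t[min(k_half + 1, imax)])
    t_lo = max(float(t[start]), float(t[k]) - 0.25)
    i_trough = int(np.argmin(kin.diameter[start:end])) + start
    t_trough = float(t[i_trough])
    onset = _changepoint_refine(
        t, d, start, t_lo, t_hi, window_end=min(t_hi + 0.15, t_trough)
    )
    time_to_peak = t_trough - onset
    if time_to_peak > 2 * dt:
        onset = _changepoint_refine(
            t, d, start, t_lo, t_hi,
            window_end=t_trough, beta=2.0 / time_to_peak,
        )
    return float(np.clip(onset, stimulus_onset, t[imax]))


def _refine_trough(
    t: np.ndarray, d: np.ndarray, i0: int, lo: int, hi: int
) -> tuple[float, float]:
    """Sub-sample trough location and depth around grid minimum ``i0``.

    The model trough is a corner (zero pre-side slope, finite redilation
    slope), so the refinement intersects a cubic fitted to the samples
    before the minimum with a quadratic fitted after it, on the raw
    series; the corner is the intersection nearest the grid minimum.  A
    second pass reassigns the minimum sample to the correct side of the
    corner.  Falls back to the grid value near window boundaries or when
    no plausible intersection exists.
    """
    t0 = float(t[i0])
    dt = float(t[1] - t[0])

    def fit(pre: np.ndarray, post: np.ndarray) -> tuple[float, float] | None:
        qp = np.polyfit(t[pre] - t0, d[pre], 3)
        pq = np.polyfit(t[post] - t0, d[post], 2)
        roots = np.roots(np.polysub(qp, pq))
        roots = [r.real for r in roots
                 if abs(r.imag) < 1e-9 and abs(r.real) <= 1.5 * dt]
        if not roots:
            return None
        x = min(roots, key=abs)
        return x, float(min(np.polyval(qp, x), np.polyval(pq, x)))

    pre = np.arange(max(lo, i0 - 6), i0)
    post = np.arange(i0 + 1, min(hi, i0 + 6))
    if len(pre) < 5 or len(post) < 4:
        return t0, float(d[i0])
    first = fit(pre, post)
    if first is None:
        return t0, float(d[i0])
    x, depth = first
    # reassign the minimum sample to the side of the corner it lies on
    second = fit(np.append(pre[1:], i0), post) if x > 0 else fit(pre, np.append(i0, post[:-1]))
    if second is not None:
        x, depth = second
    return t0 + float(x), depth


def _segment_extreme(
    x: np.ndarray, t: np.ndarray, i0: int, i1: int, sign: float
) -> tuple[float, float]:
    """Max of sign*x on the inclusive index range [i0, i1] with its time."""
    if i1 < i0:
        return math.nan, math.nan
    seg = sign * x[i0 : i1 + 1]
    j = int(np.argmax(seg))
    return float(seg[j]), float(t[i0 + j])


def extract_parameters(
    trace: PupilTrace, settings: ExtractionSettings | None = None
) -> PLRFeatureSet:
    """Compute the 17 kinetic parameters of one pupil trace.

    Returns an all-NaN feature set for unusable traces (too many missing
    samples) and NaN for any individual parameter that is undefined (e.g.
    no detectable contraction, or no redilation samples).
    """
    settings = settings or ExtractionSettings()
    try:
        kin = smooth_and_differentiate(trace, settings)
    except UnusableTraceError:
        return PLRFeatureSet()

    t = kin.times
    d = kin.diameter
    onset = trace.stimulus_onset
    spec = STIMULI[trace.condition]
    win_end = onset + spec.stim_duration_s + settings.contraction_extra_s

    prl = detect_contraction_onset(
        kin,
        stimulus_onset=onset,
        threshold_frac=settings.onset_threshold_frac,
        noise_floor_mult=settings.noise_floor_mult,
        window_end=win_end,
        noise_sd=velocity_noise_sd(kin, settings),
    )
    if math.isnan(prl):
        return PLRFeatureSet()

    start = int(np.searchsorted(t, onset))
    baseline = float(np.mean(d[start : start + settings.baseline_samples]))

    # Trough: minimal smoothed diameter in the contraction window after
    # onset, refined to sub-sample resolution (the model trough is a corner
    # between the contraction and redilation arms, which the sample grid
    # and the smoother both miss slightly).
    end = int(np.searchsorted(t, win_end, "right"))
    i_trough = int(np.argmin(d[start:end])) + start
    raw = kin.raw if kin.raw is not None else d
    t_trough, trough = _refine_trough(t, raw, i_trough, start, len(t))
    lmp = float(t_trough - onset)
    ac = baseline - trough
    if ac <= 0:
        return PLRFeatureSet()
    ppc = float(np.clip(100.0 * ac / baseline, 0.0, 100.0))

    # Contraction arm: speed/acceleration extrema between onset and trough.
    # Latencies are clamped to LMP: the refined trough time may fall a
    # fraction of a sample before the grid sample holding the extremum.
    i_prl = max(start, int(math.ceil((prl - t[0]) / (t[1] - t[0]))))
    mcv, t_mcv = _segment_extreme(kin.velocity, t, i_prl, i_trough, -1.0)
    lmcv = min(t_mcv - onset, lmp)
    i_mcv = int(round((t_mcv - t[0]) / (t[1] - t[0])))
    mca, t_mca = _segment_extreme(kin.acceleration, t, i_prl, i_mcv, -1.0)
    mcd, t_mcd = _segment_extreme(kin.acceleration, t, i_mcv, i_trough, +1.0)
    lmca = min(t_mca - onset, lmcv)
    lmcd = min(t_mcd - onset, lmp)

    # Redilation arm: from the trough to the end of the recording.
    if i_trough + 2 < len(t):
        mrv, t_mrv = _segment_extreme(kin.velocity, t, i_trough + 1, len(t) - 1, +1.0)
        i_mrv = int(round((t_mrv - t[0]) / (t[1] - t[0])))
        mra, t_mra = _segment_extreme(kin.acceleration, t, i_trough + 1, i_mrv, +1.0)
        mrd, t_mrd = _segment_extreme(kin.acceleration, t, i_mrv, len(t) - 1, -1.0)
        lmrv, lmra, lmrd = t_mrv - onset, t_mra - onset, t_mrd - onset
    else:
        mrv = mra = mrd = lmrv = lmra = lmrd = math.nan

    d_end = float(np.mean(d[-settings.end_samples :]))
    prp = float(np.clip(100.0 * (d_end - trough) / ac, 0.0, 100.0))

    return PLRFeatureSet(
        AC=ac, PPC=ppc, PRL=prl - onset, LMP=lmp,
        MCV=mcv, LMCV=lmcv, MCA=mca, LMCA=lmca,
        MCD=mcd, LMCD=lmcd,
        MRV=mrv, LMRV=lmrv, MRA=mra, LMRA=lmra, MRD=mrd, LMRD=lmrd,
        PRP=prp,
    )


def extract_features(
    traces, settings: ExtractionSettings | None = None
) -> pd.DataFrame:
    """Extract parameters for a collection of traces into a long DataFrame.

    One row per (subject_id, eye, condition, target_index) with 17 named
    parameter columns; undefined parameters are NaN.
    """
    settings = settings or ExtractionSettings()
    rows = []
    for trace in traces:
        fs = extract_parameters(trace, settings)
        row = {
            "subject_id": trace.subject_id,
            "eye": trace.eye.value,
            "condition": trace.condition.value,
            "target_index": trace.target_index,
        }
        row.update(fs.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
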