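"""Skin-conductance-response (SCR) detection and characterization.

An SCR is a transient conductance rise: after a stimulus there is a
latency of typically 1–5 s, then the signal climbs from an onset trough
to a peak (rise time, seconds), and relaxes back more slowly (recovery
time, measured to the 50 % point of the amplitude below the peak; when
the recording ends first, the recovery time is censored and only a
lower bound is known).  Peak amplitude is the conductance at the peak
minus the conductance at the onset.

Detection is two-stage:

1. *Candidate scan* — local maxima of a lightly smoothed copy of the
   signal whose prominence exceeds the onset amplitude criterion, each
   paired with its preceding local minimum (the excursion base).
2. *Refinement* — by default each candidate is refined by fitting a
   canonical SCR template (constant local baseline, linear rise,
   exponential recovery) with bounded least squares, which localizes
   onset and peak to well under one 2-s sample even when the per-sample
   noise is comparable to the criterion.  Onset and peak times are then
   snapped to sample times.  ``refine="samples"`` keeps the classical
   trough/peak sample values instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks, peak_prominences

from .device_model import ConductanceTrace
from .preprocess import PhasicTrace

__all__ = ["DetectionConfig", "SCREvent", "detect_events", "characterize", "peak_width"]


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable knobs of the SCR detector.

    ``onset_amplitude_criterion`` is the minimum excursion (µS) above
    the preceding local minimum for a rise to count as an SCR onset;
    the conventional values are 0.05 (default) and 0.01.  Events whose
    refined amplitude falls below ``min_peak_prominence`` (defaults to
    the onset criterion) are discarded.  ``er_latency_window`` is the
    stimulus-to-onset latency range of event-related SCRs.
    """

    onset_amplitude_criterion: float = 0.05
    er_latency_window: Tuple[float, float] = (1.0, 5.0)
    min_peak_prominence: Optional[float] = None
    smooth_samples: int = 5
    refine: str = "template"  # or "samples"
    use_phasic: bool = False
    late_latency_class: str = "NS_SCR"

    def __post_init__(self) -> None:
        if not self.onset_amplitude_criterion > 0:
            raise ValueError("onset_amplitude_criterion must be > 0")
        lo, hi = self.er_latency_window
        if not (lo >= 0 and lo < hi):
            raise ValueError("er_latency_window must satisfy 0 <= lo < hi")
        if self.refine not in ("template", "samples"):
            raise ValueError("refine must be 'template' or 'samples'")

    @property
    def prominence(self) -> float:
        return (
            self.onset_amplitude_criterion
            if self.min_peak_prominence is None
            else self.min_peak_prominence
        )


@dataclass
class SCREvent:
    """One detected skin-conductance response."""

    onset_time: float
    onset_value: float
    peak_time: float
    peak_value: float
    amplitude: float
    rise_time: float
    recovery_time: Optional[float]
    recovery_censored: bool
    recovery_lower_bound: Optional[float] = None
    latency: Optional[float] = None
    latency_class: str = "unknown"
    onset_index: int = -1
    peak_index: int = -1


def _smooth(y: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return y.copy()
    pad = n // 2
    k = np.ones(n) / n
    return np.convolve(np.pad(y, pad, mode="edge"), k, mode="valid")


def _template(tt: np.ndarray, t_on: float, rise: float, amp: float, tau: float, base: float) -> np.ndarray:
    """Canonical SCR: flat baseline, linear rise, exponential recovery
    with half-life ``tau`` (the 50 % level is crossed ``tau`` s after the
    peak)."""
    v = np.full(tt.shape, base)
    pk = t_on + rise
    up = (tt >= t_on) & (tt < pk)
    v[up] = base + amp * (tt[up] - t_on) / rise
    dn = tt >= pk
    v[dn] = base + amp * np.exp2(-(tt[dn] - pk) / tau)
    return v


def _candidate_peaks(ys: np.ndarray, excursion: float) -> List[Tuple[int, int, int]]:
    """Local maxima whose *rising* excursion above the preceding local
    minimum reaches ``excursion``.

    The preceding minimum is searched back to the nearest earlier sample
    higher than the peak (or the trace start) — the left base in the
    prominence sense.  A one-sided criterion is deliberate: an SCR whose
    slow recovery is cut off by the end of the recording has little
    height on its right side but a full-sized rise.  Plateau peaks use
    the first plateau sample.  Candidates sharing a left base collapse
    to the highest peak.  Returns ``(peak, left_base, right_base)``
    index triples.
    """
    peaks, props = find_peaks(ys, plateau_size=(1, None))
    if peaks.size == 0:
        return []
    peaks = props["left_edges"]  # plateau tie-break: first sample
    _, left_bases, right_bases = peak_prominences(ys, peaks)
    out: dict = {}
    for p, lb, rb in zip(peaks, left_bases, right_bases):
        if ys[p] - ys[lb] < excursion:
            continue
        if lb in out and ys[out[lb][0]] >= ys[p]:
            continue
        out[lb] = (int(p), int(lb), int(rb))
    return sorted(out.values())


def _nearest_index(t: np.ndarray, x: float) -> int:
    return int(np.argmin(np.abs(t - x)))


def _half_recovery(
    t: np.ndarray,
    y: np.ndarray,
    peak_index: int,
    peak_time: float,
    level: float,
    recovery_start_time: Optional[float] = None,
) -> Tuple[Optional[float], bool, Optional[float]]:
    """First crossing of ``level`` after the peak, linearly interpolated.

    Returns ``(recovery_time, censored, lower_bound)``.  When the trace
    ends before the crossing, the recovery is censored with lower bound
    ``t_end − peak_time`` (or ``t_end − recovery_start_time`` when the
    recovery phase is stated to begin later, e.g. after a plateau).
    """
    start = peak_index + 1
    if recovery_start_time is not None:
        start = max(start, int(np.searchsorted(t, recovery_start_time, side="left")))
    for j in range(start, t.size):
        if not np.isfinite(y[j]):
            continue
        if y[j] <= level:
            jprev = j - 1
            while jprev > peak_index and not np.isfinite(y[jprev]):
                jprev -= 1
            if jprev >= peak_index and np.isfinite(y[jprev]) and y[jprev] > level:
                frac = (y[jprev] - level) / (y[jprev] - y[j])
                t_cross = t[jprev] + frac * (t[j] - t[jprev])
            else:
                t_cross = t[j]
            return float(t_cross - peak_time), False, None
    ref = peak_time if recovery_start_time is None else recovery_start_time
    return None, True, float(t[-1] - ref)


def _classify_latency(
    onset_time: float, stimulus_time: Optional[float], cfg: DetectionConfig
) -> Tuple[Optional[float], str]:
    if stimulus_time is None:
        return None, "unknown"
    latency = onset_time - stimulus_time
    lo, hi = cfg.er_latency_window
    if lo <= latency <= hi:
        return latency, "ER_SCR"
    if latency < lo:
        return latency, "NS_SCR"
    return latency, cfg.late_latency_class


def characterize(
    trace: ConductanceTrace,
    onset_index: int,
    peak_index: int,
    stimulus_time: Optional[float] = None,
    recovery_start_time: Optional[float] = None,
    cfg: DetectionConfig = DetectionConfig(),
) -> SCREvent:
    """Characterize an SCR from explicit onset and peak sample indices.

    Amplitude is the peak sample value minus the onset sample value;
    rise time the corresponding time difference.  Recovery is the time
    from the peak to the 50 %-of-amplitude crossing (interpolated
    between samples), censored with a lower bound when the recording
    ends first.  ``recovery_start_time`` lets the caller place the start
    of the recovery phase after a plateau, which only affects the
    censored lower bound.
    """
    t, y = trace.times, trace.conductance
    n = t.size
    if not (0 <= onset_index < peak_index < n):
        raise IndexError("require 0 <= onset_index < peak_index < len(trace)")
    onset_value, peak_value = float(y[onset_index]), float(y[peak_index])
    amplitude = peak_value - onset_value
    if amplitude <= 0:
        raise ValueError(
            f"peak value {peak_value} not above onset value {onset_value}: not an SCR"
        )
    level = peak_value - amplitude / 2.0
    rec, censored, lower = _half_recovery(
        t, y, peak_index, float(t[peak_index]), level, recovery_start_time
    )
    latency, lat_class = _classify_latency(float(t[onset_index]), stimulus_time, cfg)
    return SCREvent(
        onset_time=float(t[onset_index]),
        onset_value=onset_value,
        peak_time=float(t[peak_index]),
        peak_value=peak_value,
        amplitude=amplitude,
        rise_time=float(t[peak_index] - t[onset_index]),
        recovery_time=rec,
        recovery_censored=censored,
        recovery_lower_bound=lower,
        latency=latency,
        latency_class=lat_class,
        onset_index=onset_index,
        peak_index=peak_index,
    )


def _refine_template(
    t: np.ndarray,
    y: np.ndarray,
    left_base: int,
    peak0: int,
    right_base: int,
    base_level: float,
    amp0: float,
) -> Optional[Tuple[float, float, float, float]]:
    """Bounded least-squares fit of the SCR template around a candidate.

    Returns ``(t_onset, t_peak, amplitude, base)`` or None when the fit
    is not applicable."""
    w0, w1 = max(left_base - 3, 0), min(right_base + 2, t.size)
    tw, yw = t[w0:w1], y[w0:w1]
    ok = np.isfinite(yw)
    if ok.sum() < 6:
        return None
    tw, yw = tw[ok], yw[ok]
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    x0 = np.array([t[left_base], max(t[peak0] - t[left_base], dt), amp0, 10.0, base_level])
    lb = np.array([t[w0], dt / 2.0, 0.0, 1.0, base_level - 1.0])
    ub = np.array(
        [t[peak0], max(t[peak0] - t[w0] + dt, dt), 3.0 * amp0 + 0.5, 200.0, base_level + 1.0]
    )
    x0 = np.clip(x0, lb, ub)
    try:
        res = least_squares(
            lambda x: _template(tw, *x) - yw, x0, bounds=(lb, ub), method="trf"
        )
    except Exception:
        return None
    t_on, rise, amp, _tau, base = res.x
    return float(t_on), float(t_on + rise), float(amp), float(base)


def detect_events(
    trace: ConductanceTrace,
    phasic: Optional[PhasicTrace] = None,
    cfg: DetectionConfig = DetectionConfig(),
    stimulus_time: Optional[float] = None,
) -> List[SCREvent]:
    """Detect SCRs: onsets, peaks and their characteristics.

    An excursion qualifies when it rises at least the onset amplitude
    criterion above its preceding local minimum; the onset is the start
    of the excursion (the trough) and the peak the subsequent local
    maximum.  Events are returned in onset order.  With a
    ``stimulus_time``, each event is tagged ER-SCR when its latency
    falls inside the 1–5 s window, NS-SCR otherwise.
    """
    t = np.asarray(trace.times, dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("trace timestamps must be strictly increasing")
    if cfg.use_phasic:
        if phasic is None:
            raise ValueError("use_phasic requires a phasic trace")
        y = np.asarray(phasic.phasic, dtype=float)
    else:
        y = np.asarray(trace.conductance, dtype=float)
    if t.size < 3:
        return []
    finite = np.isfinite(y)
    if not finite.any():
        return []
    if not finite.all():
        y = y.copy()
        y[~finite] = np.interp(t[~finite], t[finite], y[finite])

    ys = _smooth(y, cfg.smooth_samples)
    candidates = _candidate_peaks(ys, cfg.prominence)
    events: List[SCREvent] = []
    used_peaks: set = set()
    for p, b, rb in candidates:
        lo, hi = max(p - 2, 0), min(p + 3, y.size)
        pi0 = lo + int(np.argmax(y[lo:hi]))
        blo, bhi = max(b - 3, 0), min(b + 3, y.size)
        base_level = float(np.median(y[blo:bhi]))
        amp0 = float(y[pi0]) - base_level
        if amp0 <= 0:
            continue

        oi = pi = None
        onset_value = peak_value = None
        if cfg.refine == "template":
            fit = _refine_template(t, y, b, pi0, rb, base_level, amp0)
            if fit is not None:
                t_on, t_pk, amp_fit, base_fit = fit
                oi = _nearest_index(t, t_on)
                pi = _nearest_index(t, t_pk)
                if pi <= oi:
                    pi = min(oi + 1, y.size - 1)
                if pi <= oi:
                    continue
                onset_value = base_fit
                peak_value = base_fit + amp_fit
        if oi is None:
            # classical route: trough and peak sample values
            lo2, hi2 = max(b - 1, 0), min(b + 2, y.size)
            oi = lo2 + int(np.argmin(y[lo2:hi2]))
            pi = pi0
            if oi >= pi:
                continue
            onset_value = float(y[oi])
            peak_value = float(y[pi])

        amplitude = peak_value - onset_value
        if amplitude < cfg.onset_amplitude_criterion or amplitude < cfg.prominence:
            continue
        if pi in used_peaks:
            continue
        used_peaks.add(pi)

        level = peak_value - amplitude / 2.0
        rec, censored, lower = _half_recovery(t, y, pi, float(t[pi]), level)
        latency, lat_class = _classify_latency(float(t[oi]), stimulus_time, cfg)
        events.append(
            SCREvent(
                onset_time=float(t[oi]),
                onset_value=float(onset_value),
                peak_time=float(t[pi]),
                peak_value=float(peak_value),
                amplitude=float(amplitude),
                rise_time=float(t[pi] - t[oi]),
                recovery_time=rec,
                recovery_censored=censored,
                recovery_lower_bound=lower,
                latency=latency,
                latency_class=lat_class,
                onset_index=int(oi),
                peak_index=int(pi),
            )
        )
    events.sort(key=lambda e: e.onset_time)
    return events


def peak_width(trace: ConductanceTrace, event: SCREvent) -> float:
    """Full width at half amplitude of an SCR, in seconds.

    Duration for which the conductance stays at or above
    ``onset_value + amplitude/2`` in the contiguous region around the
    peak, with the two crossings linearly interpolated; truncated at
    the trace boundaries when the signal never drops below the level.
    """
    t, y = trace.times, trace.conductance
    level = event.onset_value + event.amplitude / 2.0
    pi = event.peak_index if event.peak_index >= 0 else _nearest_index(t, event.peak_time)

    t_left = t[0]
    for i in range(pi - 1, -1, -1):
        if np.isfinite(y[i]) and y[i] < level:
            frac = (level - y[i]) / (y[i + 1] - y[i])
            t_left = t[i] + frac * (t[i + 1] - t[i])
            break
    t_right = t[-1]
    for j in range(pi + 1, t.size):
        if np.isfinite(y[j]) and y[j] < level:
            frac = (y[j - 1] - level) / (y[j - 1] - y[j])
            t_right = t[j - 1] + frac * (t[j] - t[j - 1])
            break
    return float(t_right - t_left)
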