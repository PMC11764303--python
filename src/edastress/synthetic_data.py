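"""Synthetic GSR cohorts with ground truth.

The generator emulates short field recordings (1–2 min, one sample
every 2 s): a tonic baseline in the physiological 1–20 µS band, zero
or more SCR bumps (latency 1–5 s after a stimulus, amplitude 0.2–3 µS,
seconds-scale linear rise, slower exponential recovery) and additive
Gaussian sensor noise well below the 0.05 µS onset criterion.  Invalid
recordings are flat lines — either below the 1 µS band (open-air
reading, 0.93 µS) or inside it (constant 1.99 µS) — mimicking poor
electrode contact.  Every trace carries its generating label and the
injected events, so detection and categorization can be scored against
ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .device_model import ConductanceTrace, DeviceParams, RawTrace

__all__ = [
    "SCRShape",
    "CohortSpec",
    "SimulatedTrace",
    "simulate_trace",
    "simulate_cohort",
    "conductance_to_au",
]

MAX_PHYSIO_US = 20.0


@dataclass(frozen=True)
class SCRShape:
    """Parameters of one injected SCR bump.

    The default morphology is a linear rise to ``amplitude`` over
    ``rise_time`` followed by an exponential decay whose half-life is
    ``recovery_half_time`` — so the 50 % recovery level is crossed
    exactly ``recovery_half_time`` seconds after the peak, making the
    detector's recovery estimate analytically checkable.  The
    ``triangular`` variant descends linearly, reaching baseline at
    ``2 × recovery_half_time`` after the peak.
    """

    stimulus_time: float
    latency: float = 3.0
    amplitude: float = 1.0
    rise_time: float = 20.0
    recovery_half_time: float = 30.0
    shape: str = "linear_rise_exp_decay"

    def __post_init__(self) -> None:
        if min(self.latency, self.amplitude, self.rise_time, self.recovery_half_time) <= 0:
            raise ValueError("latency, amplitude, rise_time, recovery_half_time must be > 0")
        if self.shape not in ("linear_rise_exp_decay", "triangular"):
            raise ValueError(f"unknown shape {self.shape!r}")

    @property
    def onset_time(self) -> float:
        return self.stimulus_time + self.latency

    @property
    def peak_time(self) -> float:
        return self.onset_time + self.rise_time

    @classmethod
    def draw(cls, rng: np.random.Generator, stimulus_time: float) -> "SCRShape":
        """Draw one bump from the default physiological distributions:
        latency U[1,5] s, amplitude U[0.2,3] µS, rise U[5,35] s,
        recovery half-time U[1.2,3]×rise (recovery slower than rise)."""
        rise = rng.uniform(5.0, 35.0)
        return cls(
            stimulus_time=stimulus_time,
            latency=rng.uniform(1.0, 5.0),
            amplitude=rng.uniform(0.2, 3.0),
            rise_time=rise,
            recovery_half_time=rng.uniform(1.2, 3.0) * rise,
        )

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Bump value (µS above baseline) at each time point."""
        v = np.zeros(t.shape)
        on, pk = self.onset_time, self.peak_time
        up = (t >= on) & (t < pk)
        v[up] = self.amplitude * (t[up] - on) / self.rise_time
        dn = t >= pk
        if self.shape == "linear_rise_exp_decay":
            v[dn] = self.amplitude * np.exp2(-(t[dn] - pk) / self.recovery_half_time)
        else:
            fall = 2.0 * self.recovery_half_time
            v[dn] = self.amplitude * np.clip(1.0 - (t[dn] - pk) / fall, 0.0, None)
        return v


@dataclass(frozen=True)
class CohortSpec:
    """Composition and acquisition parameters of a simulated cohort."""

    n_stressed: int = 36
    n_calm: int = 12
    n_invalid: int = 3
    tonic_range: Tuple[float, float] = (2.0, 8.0)
    noise_sd: float = 0.02
    duration: float = 120.0
    sample_interval: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_stressed, self.n_calm, self.n_invalid) < 0:
            raise ValueError("cohort counts must be >= 0")
        if self.duration < 10 * self.sample_interval:
            raise ValueError("duration must be at least 10 sample intervals")

    @property
    def n_total(self) -> int:
        return self.n_stressed + self.n_calm + self.n_invalid


@dataclass
class SimulatedTrace:
    """A generated trace with its ground-truth label and injected events."""

    trace: ConductanceTrace
    label: str  # stressed | calm | invalid
    shapes: List[SCRShape] = field(default_factory=list)
    clipped: bool = False


def _check_spacing(shapes: Sequence[SCRShape]) -> None:
    for a, b in zip(shapes, shapes[1:]):
        min_gap = a.rise_time + 2.0 * a.recovery_half_time
        if b.onset_time - a.onset_time < min_gap:
            raise ValueError(
                "SCR shapes overlap: consecutive onsets must be at least "
                f"rise_time + 2×recovery_half_time = {min_gap:.1f} s apart"
            )


def simulate_trace(
    shapes: Sequence[SCRShape],
    tonic_baseline: float = 4.0,
    noise_sd: float = 0.02,
    duration: float = 120.0,
    sample_interval: float = 2.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedTrace:
    """Tonic baseline + sum of SCR bumps + Gaussian noise, sampled on a
    regular grid.  Conductance exceeding the 20 µS physiological
    ceiling is clipped with a warning and the trace flagged."""
    shapes = sorted(shapes, key=lambda s: s.onset_time)
    _check_spacing(shapes)
    if rng is None:
        rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, sample_interval)
    y = np.full(t.shape, float(tonic_baseline))
    for s in shapes:
        y = y + s.evaluate(t)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, t.shape)
    clipped = bool(np.any(y > MAX_PHYSIO_US))
    if clipped:
        warnings.warn(
            "simulated conductance exceeds 20 µS; clipping to the physiological ceiling",
            stacklevel=2,
        )
        y = np.minimum(y, MAX_PHYSIO_US)
    trace = ConductanceTrace(t, y, source="synthetic")
    label = "stressed" if shapes else "calm"
    return SimulatedTrace(trace, label, list(shapes), clipped)


def conductance_to_au(
    trace: ConductanceTrace, device: DeviceParams = DeviceParams()
) -> RawTrace:
    """Inverse of the circuit conversion: conductance → ADC readings.

    ``X = 1/Y``, ``Vx = V·X/(R+X)`` (voltage divider), then ``Vx/λ``
    rounded to the nearest integer code and clamped to the ADC range.
    """
    y = np.asarray(trace.conductance, dtype=float)
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("conductance must be finite and > 0 for ADC synthesis")
    x_kohm = 1000.0 / y
    vx = device.supply_voltage * x_kohm / (device.series_resistance + x_kohm)
    au = np.rint(vx / device.conversion_factor).astype(int)
    au = np.clip(au, 0, device.adc_levels - 1)
    return RawTrace(trace.times.copy(), au, device=device)


def _stressed_shapes(rng: np.random.Generator, spec: CohortSpec) -> List[SCRShape]:
    """One or occasionally two non-overlapping bumps that fit the recording."""
    first_stim = rng.uniform(5.0, 50.0)
    first = SCRShape.draw(rng, first_stim)
    # keep the peak comfortably inside the recording
    while first.peak_time > spec.duration - 20.0:
        first_stim = rng.uniform(5.0, 30.0)
        first = SCRShape.draw(rng, first_stim)
    shapes = [first]
    if rng.random() < 0.3:
        gap = first.rise_time + 2.0 * first.recovery_half_time
        second_on = first.onset_time + gap + rng.uniform(2.0, 10.0)
        second = SCRShape.draw(rng, second_on)  # stimulus at the gap end
        if second.peak_time <= spec.duration - 10.0:
            shapes.append(second)
    return shapes


def simulate_cohort(spec: CohortSpec) -> List[SimulatedTrace]:
    """Generate a labeled cohort: stressed traces carry ≥1 SCR bump,
    calm traces are noisy baselines, invalid traces alternate between
    an open-air flat line (0.93 µS) and an in-band flat line (1.99 µS).

    Deterministic for a fixed ``spec.seed``; per-trace seeds are spawned
    from it so the cohort is reproducible trace by trace.
    """
    if spec.n_total < 1:
        raise ValueError("cohort must contain at least one trace")
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_total)
    out: List[SimulatedTrace] = []
    i = 0
    for _ in range(spec.n_stressed):
        rng = np.random.default_rng(children[i]); i += 1
        tonic = rng.uniform(*spec.tonic_range)
        shapes = _stressed_shapes(rng, spec)
        sim = simulate_trace(
            shapes, tonic, spec.noise_sd, spec.duration, spec.sample_interval, rng=rng
        )
        out.append(sim)
    for _ in range(spec.n_calm):
        rng = np.random.default_rng(children[i]); i += 1
        tonic = rng.uniform(*spec.tonic_range)
        sim = simulate_trace(
            [], tonic, spec.noise_sd, spec.duration, spec.sample_interval, rng=rng
        )
        out.append(sim)
    for k in range(spec.n_invalid):
        rng = np.random.default_rng(children[i]); i += 1
        level = 0.93 if k % 2 == 0 else 1.99  # open-air vs in-band flat line
        t = np.arange(0.0, spec.duration, spec.sample_interval)
        trace = ConductanceTrace(t, np.full(t.shape, level), source="synthetic")
        out.append(SimulatedTrace(trace, "invalid", []))
    return out
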