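"""Equivalent-circuit model of the GSR sensor front end.

The sensor is a simple voltage divider: a fixed series resistance ``R``
(500 kΩ by default) in series with the unknown skin resistance ``X``,
driven by the supply voltage ``V`` (5 V).  The microcontroller's ADC
digitizes the voltage drop ``Vx`` across the skin in "Arduino Units"
(AU), one unit being ``V / 1024`` volts.  From ``Vx`` the circuit gives

    I = (V - Vx) / R        (sensor current)
    X = Vx / I              (skin resistance)
    Y = 1 / X               (skin conductance)

Units are fixed throughout: ``Vx`` in volts, ``I`` in microamperes,
``X`` in kiloohms and ``Y`` in microsiemens.  Note that conductance is
strictly *decreasing* in the ADC reading: a sweatier (more conductive)
hand drops less voltage across itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "DeviceParams",
    "RawTrace",
    "ConductanceTrace",
    "au_to_volts",
    "sensor_current",
    "subject_conductance",
    "convert_trace",
]


@dataclass(frozen=True)
class DeviceParams:
    """Electrical parameters of the acquisition front end.

    Attributes
    ----------
    supply_voltage : float
        Supply voltage ``V`` in volts (default 5.0).
    adc_levels : int
        Number of ADC quantization levels (default 1024 for a 10-bit ADC).
    series_resistance : float
        Fixed divider resistance ``R`` in kiloohms (default 500).
    """

    supply_voltage: float = 5.0
    adc_levels: int = 1024
    series_resistance: float = 500.0

    def __post_init__(self) -> None:
        if not self.supply_voltage > 0:
            raise ValueError("supply_voltage must be > 0")
        if self.adc_levels < 2:
            raise ValueError("adc_levels must be >= 2")
        if not self.series_resistance > 0:
            raise ValueError("series_resistance must be > 0 (kΩ)")

    @property
    def conversion_factor(self) -> float:
        """Volts per ADC unit, λ = supply_voltage / adc_levels."""
        return self.supply_voltage / self.adc_levels


def _check_times(times: np.ndarray) -> None:
    if times.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")


@dataclass
class RawTrace:
    """Timestamped raw ADC readings plus the device that produced them."""

    times: np.ndarray
    values: np.ndarray
    device: DeviceParams = field(default_factory=DeviceParams)
    sample_interval: float = 2.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values)
        _check_times(self.times)
        if self.values.shape != self.times.shape:
            raise ValueError("times and values must have the same length")
        if self.values.size:
            bad = (self.values < 0) | (self.values > self.device.adc_levels - 1)
            if np.any(bad):
                idx = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"ADC value out of range [0, {self.device.adc_levels - 1}] "
                    f"at sample {idx}: {self.values[idx]}"
                )

    def __len__(self) -> int:
        return self.times.size


@dataclass
class ConductanceTrace:
    """Timestamped skin-conductance samples in µS.

    Samples that could not be computed (degenerate circuit states) are
    stored as NaN rather than dropped, so indices line up with the raw
    recording.
    """

    times: np.ndarray
    conductance: np.ndarray
    source: Literal["converted", "native", "synthetic"] = "native"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conductance = np.asarray(self.conductance, dtype=float)
        _check_times(self.times)
        if self.conductance.shape != self.times.shape:
            raise ValueError("times and conductance must have the same length")

    def __len__(self) -> int:
        return self.times.size

    @property
    def flagged(self) -> np.ndarray:
        """Boolean mask of samples flagged during conversion (non-finite)."""
        return ~np.isfinite(self.conductance)


def au_to_volts(au, device: DeviceParams = DeviceParams()):
    """Convert ADC readings to volts: ``Vx = au × λ``.

    Accepts scalars or arrays; raises a range error naming the first
    offending sample if a reading falls outside ``[0, adc_levels - 1]``.
    """
    arr = np.asarray(au, dtype=float)
    bad = (arr < 0) | (arr > device.adc_levels - 1)
    if np.any(bad):
        idx = int(np.flatnonzero(np.atleast_1d(bad))[0])
        val = np.atleast_1d(arr)[idx]
        raise ValueError(
            f"ADC reading {val} at sample {idx} outside "
            f"[0, {device.adc_levels - 1}]"
        )
    out = arr * device.conversion_factor
    return float(out) if np.isscalar(au) else out


def sensor_current(vx, device: DeviceParams = DeviceParams()):
    """Current through the divider in µA: ``I = (V − Vx) / R``.

    ``Vx ≥ V`` is impossible in this topology (it would imply zero or
    negative current) and raises.
    """
    arr = np.asarray(vx, dtype=float)
    if np.any(arr >= device.supply_voltage):
        raise ValueError(
            "vx >= supply voltage: degenerate circuit (current would be <= 0)"
        )
    if np.any(arr < 0):
        raise ValueError("vx must be >= 0")
    # V / kΩ = mA; scale to µA
    out = (device.supply_voltage - arr) / device.series_resistance * 1000.0
    return float(out) if np.isscalar(vx) else out


def subject_conductance(vx, device: DeviceParams = DeviceParams()):
    """Skin conductance in µS from the measured voltage drop.

    ``X = Vx / I`` (kΩ), ``Y = 1 / X`` (µS).  ``vx == 0`` implies zero
    skin resistance and unbounded conductance — an electrode artifact —
    and raises.
    """
    arr = np.asarray(vx, dtype=float)
    if np.any(arr == 0):
        raise ValueError(
            "vx == 0: zero subject resistance, conductance undefined (artifact)"
        )
    current = sensor_current(vx, device)  # µA
    x_kohm = arr / np.asarray(current) * 1000.0  # V/µA = MΩ → kΩ
    y_us = 1000.0 / x_kohm  # 1/kΩ = mS → µS
    return float(y_us) if np.isscalar(vx) else y_us


def convert_trace(raw: RawTrace) -> ConductanceTrace:
    """Convert a raw ADC trace to conductance, sample by sample.

    Length and timestamps are preserved.  Samples whose conversion is
    degenerate (``au == 0``, i.e. ``Vx == 0``) become NaN and are
    reported via :attr:`ConductanceTrace.flagged` instead of aborting
    the recording.
    """
    if len(raw) == 0:
        return ConductanceTrace(raw.times, np.empty(0), source="converted")
    vx = au_to_volts(raw.values, raw.device)
    y = np.full(vx.shape, np.nan)
    ok = (vx > 0) & (vx < raw.device.supply_voltage)
    if np.any(ok):
        y[ok] = subject_conductance(vx[ok], raw.device)
    return ConductanceTrace(raw.times.copy(), y, source="converted")
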