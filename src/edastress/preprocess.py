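"""Validity screening and phasic/tonic separation.

Human skin conductance lies between 1 and 20 µS; samples outside that
band indicate poor electrode contact (open air reads below 1 µS).  The
phasic component is obtained by subtracting a local baseline — the mean
(or median) of all samples within ±4 s of each sample — leaving only
the fast, event-driven fluctuations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .device_model import ConductanceTrace

__all__ = [
    "ValidityConfig",
    "ValidityResult",
    "PhasicTrace",
    "validity_flags",
    "local_baseline",
    "phasic_component",
    "normalize_01",
]


@dataclass(frozen=True)
class ValidityConfig:
    """Physiological validity band and trace-level rejection threshold."""

    min_valid: float = 1.0  # µS
    max_valid: float = 20.0  # µS
    invalid_fraction_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.min_valid < self.max_valid:
            raise ValueError("require 0 < min_valid < max_valid")


@dataclass
class ValidityResult:
    sample_valid: np.ndarray
    invalid_fraction: float
    trace_invalid: bool


@dataclass
class PhasicTrace:
    """Phasic component plus the baseline that was subtracted.

    ``phasic + baseline`` reconstructs the input exactly at every sample.
    """

    times: np.ndarray
    phasic: np.ndarray
    baseline: np.ndarray
    half_window: float = 4.0


def validity_flags(trace: ConductanceTrace, cfg: ValidityConfig = ValidityConfig()) -> ValidityResult:
    """Flag each sample against the 1–20 µS band; reject the trace when
    more than ``invalid_fraction_threshold`` of samples fall outside."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    y = trace.conductance
    valid = np.isfinite(y) & (y >= cfg.min_valid) & (y <= cfg.max_valid)
    frac = 1.0 - valid.mean()
    return ValidityResult(valid, float(frac), bool(frac > cfg.invalid_fraction_threshold))


def local_baseline(
    trace: ConductanceTrace, half_window: float = 4.0, method: str = "mean"
) -> np.ndarray:
    """Windowed local average of the trace.

    For each sample, the mean (or median) of every sample whose
    timestamp lies within ``±half_window`` seconds of it, the window
    truncated at the trace boundaries (closed interval — samples at
    exactly ``±half_window`` are included).  Non-finite samples are
    excluded from the average; a sample with no finite neighbours gets
    a NaN baseline.
    """
    if half_window <= 0:
        raise ValueError("half_window must be > 0")
    if len(trace) == 0:
        raise ValueError("trace must contain at least one sample")
    t, y = trace.times, trace.conductance
    lo = np.searchsorted(t, t - half_window, side="left")
    hi = np.searchsorted(t, t + half_window, side="right")
    if method == "mean":
        finite = np.isfinite(y)
        cs = np.concatenate([[0.0], np.cumsum(np.where(finite, y, 0.0))])
        cn = np.concatenate([[0], np.cumsum(finite)])
        n = cn[hi] - cn[lo]
        with np.errstate(invalid="ignore"):
            out = np.where(n > 0, (cs[hi] - cs[lo]) / np.maximum(n, 1), np.nan)
        return out
    if method == "median":
        out = np.empty_like(y)
        for i in range(y.size):
            w = y[lo[i] : hi[i]]
            w = w[np.isfinite(w)]
            out[i] = np.median(w) if w.size else np.nan
        return out
    raise ValueError(f"unknown baseline method {method!r} (use 'mean' or 'median')")


def phasic_component(
    trace: ConductanceTrace, half_window: float = 4.0, method: str = "mean"
) -> PhasicTrace:
    """Subtract the local baseline, leaving the phasic signal.

    The returned pair satisfies ``phasic + baseline == raw`` bit for bit
    at every finite sample: the baseline is re-centered onto the sample
    (a ≤1-ulp adjustment of the windowed average) and any residual
    rounding defect is folded into whichever component has the finer
    floating-point resolution.
    """
    y = trace.conductance
    baseline = y - (phasic := y - local_baseline(trace, half_window, method))
    for _ in range(2):
        defect = (phasic + baseline) - y
        bad = np.isfinite(defect) & (defect != 0)
        if not bad.any():
            break
        into_phasic = bad & (np.abs(phasic) <= np.abs(baseline))
        phasic = np.where(into_phasic, phasic - defect, phasic)
        baseline = np.where(bad & ~into_phasic, baseline - defect, baseline)
    return PhasicTrace(trace.times.copy(), phasic, baseline, half_window)


def normalize_01(values) -> np.ndarray:
    """Affine rescale to [0, 1]; a constant series maps to all zeros
    (the degenerate 0/0 case is declared, not an error)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot normalize an empty series")
    vmin, vmax = np.nanmin(v), np.nanmax(v)
    if vmax == vmin:
        return np.zeros_like(v)
    return (v - vmin) / (vmax - vmin)
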