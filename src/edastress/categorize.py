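"""Rule-based three-way trace categorization and cohort summaries.

Each recording is assigned exactly one of three labels:

* ``invalid`` — the validity screen rejected the trace (too many
  samples outside the 1–20 µS band or non-finite), or the trace is a
  flat line (near-zero variance, a sensor-contact fault: a constant
  reading can sit inside the physiological band and still be air
  conductivity).
* ``stressed`` — at least one detected SCR shows the canonical
  onset→peak→recovery pattern (pattern check) with an amplitude that
  clearly separates the peak phase from the latency phase (magnitude
  check).
* ``not_stressed`` — a valid trace with no qualifying peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import List, Sequence

import numpy as np

from .device_model import ConductanceTrace
from .preprocess import ValidityResult
from .scr_events import SCREvent

__all__ = [
    "CategorizeConfig",
    "TraceCategory",
    "CohortSummary",
    "categorize_trace",
    "summarize_cohort",
    "pct_half_up",
]

LABELS = ("stressed", "not_stressed", "invalid")


@dataclass(frozen=True)
class CategorizeConfig:
    """Thresholds of the rule-based classifier.

    ``magnitude_margin`` (µS) operationalizes the "magnitude
    comparison": the peak phase must exceed the latency phase by at
    least this amplitude.  ``flat_std_floor`` (µS) is the sample
    standard deviation below which a trace counts as a flat line.
    """

    magnitude_margin: float = 0.1
    flat_std_floor: float = 0.005
    onset_amplitude_criterion: float = 0.05


@dataclass
class TraceCategory:
    label: str
    n_events: int
    pattern_ok: bool
    magnitude_ok: bool
    evidence: str


@dataclass
class CohortSummary:
    n_total: int
    n_stressed: int
    n_not_stressed: int
    n_invalid: int
    pct_stressed: int
    pct_not_stressed: int
    pct_invalid: int


def pct_half_up(count: int, total: int) -> int:
    """Integer percentage with half-up rounding (23.53 → 24, 5.88 → 6)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(
        (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
    )


def categorize_trace(
    trace: ConductanceTrace,
    events: Sequence[SCREvent],
    validity: ValidityResult,
    cfg: CategorizeConfig = CategorizeConfig(),
) -> TraceCategory:
    """Apply the invalid → stressed → not-stressed decision cascade."""
    y = trace.conductance[np.isfinite(trace.conductance)]
    flat = y.size < 2 or float(np.std(y, ddof=1)) < cfg.flat_std_floor
    if validity.trace_invalid or flat:
        reason = (
            f"{validity.invalid_fraction:.0%} of samples outside the valid band"
            if validity.trace_invalid
            else "flat line (near-zero variance), sensor-contact fault"
        )
        return TraceCategory("invalid", len(events), False, False, reason)

    threshold = max(cfg.magnitude_margin, cfg.onset_amplitude_criterion)
    qualifying = [
        ev for ev in events if ev.rise_time > 0 and ev.amplitude >= threshold
    ]
    pattern_ok = any(ev.rise_time > 0 for ev in events)
    magnitude_ok = bool(qualifying)
    if qualifying:
        best = max(qualifying, key=lambda e: e.amplitude)
        return TraceCategory(
            "stressed",
            len(events),
            True,
            True,
            f"{len(qualifying)} qualifying SCR(s); largest amplitude "
            f"{best.amplitude:.2f} µS at t={best.peak_time:.0f} s",
        )
    return TraceCategory(
        "not_stressed",
        len(events),
        pattern_ok,
        magnitude_ok,
        "no discernible peaks above the average level; rest state",
    )


def summarize_cohort(categories: Sequence[TraceCategory]) -> CohortSummary:
    """Counts and half-up integer percentages per label.

    Percentages are rounded independently and need not sum to 100.
    """
    if not categories:
        raise ValueError("cannot summarize an empty cohort")
    n = len(categories)
    counts = {label: sum(1 for c in categories if c.label == label) for label in LABELS}
    unknown = n - sum(counts.values())
    if unknown:
        raise ValueError("categories contain unknown labels")
    return CohortSummary(
        n_total=n,
        n_stressed=counts["stressed"],
        n_not_stressed=counts["not_stressed"],
        n_invalid=counts["invalid"],
        pct_stressed=pct_half_up(counts["stressed"], n),
        pct_not_stressed=pct_half_up(counts["not_stressed"], n),
        pct_invalid=pct_half_up(counts["invalid"], n),
    )
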