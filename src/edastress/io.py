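"""CSV readers/writers for traces, events and feature tables.

Trace files have two comma-separated columns with a header naming the
unit of the value column:

* ``time_s,value_au`` — raw integer ADC readings, or
* ``time_s,value_us`` — conductance in microsiemens.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .device_model import ConductanceTrace, DeviceParams, RawTrace

AU_COLUMNS = ("time_s", "value_au")
US_COLUMNS = ("time_s", "value_us")

EVENT_COLUMNS = (
    "onset_s",
    "onset_us",
    "peak_s",
    "peak_us",
    "amplitude_us",
    "rise_s",
    "recovery_s",
    "censored",
    "latency_class",
)


def read_trace_csv(
    path, device: DeviceParams = DeviceParams()
) -> Union[RawTrace, ConductanceTrace]:
    """Read a trace CSV, dispatching on the header.

    ``value_au`` files come back as :class:`RawTrace`, ``value_us``
    files as :class:`ConductanceTrace` (source ``native``).
    """
    df = pd.read_csv(path)
    cols = tuple(df.columns[:2])
    if cols == AU_COLUMNS:
        return RawTrace(
            df["time_s"].to_numpy(float),
            df["value_au"].to_numpy(int),
            device=device,
        )
    if cols == US_COLUMNS:
        return ConductanceTrace(
            df["time_s"].to_numpy(float),
            df["value_us"].to_numpy(float),
            source="native",
        )
    raise ValueError(
        f"{path}: expected header 'time_s,value_au' or 'time_s,value_us', got {list(df.columns)}"
    )


def write_trace_csv(trace: Union[RawTrace, ConductanceTrace], path) -> None:
    path = Path(path)
    if isinstance(trace, RawTrace):
        df = pd.DataFrame({"time_s": trace.times, "value_au": trace.values.astype(int)})
    else:
        df = pd.DataFrame({"time_s": trace.times, "value_us": trace.conductance})
    df.to_csv(path, index=False)


def events_to_frame(events) -> pd.DataFrame:
    """Tabulate detected SCR events, one row per event."""
    rows = []
    for ev in events:
        rows.append(
            {
                "onset_s": ev.onset_time,
                "onset_us": ev.onset_value,
                "peak_s": ev.peak_time,
                "peak_us": ev.peak_value,
                "amplitude_us": ev.amplitude,
                "rise_s": ev.rise_time,
                "recovery_s": np.nan if ev.recovery_censored else ev.recovery_time,
                "censored": ev.recovery_censored,
                "latency_class": ev.latency_class,
            }
        )
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))


def write_events_csv(events, path) -> None:
    events_to_frame(events).to_csv(path, index=False)
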