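"""The two waveform-processing methods: start-point offset and min-max.

Both operate on one analysis waveform (a full sample+purge cycle slice).
The start-point offset method subtracts the value at the sample-injection
start tick, preserving amplitude; min-max normalization rescales the
waveform so its minimum is 0 and maximum is 1, discarding amplitude — and
with it most of the purge-humidity information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProcessedWaveform",
    "DegenerateWaveformError",
    "start_point_offset",
    "min_max_normalize",
    "process",
    "METHODS",
]

METHODS = ("start_point_offset", "min_max")


class DegenerateWaveformError(ValueError):
    """Raised when min-max normalization meets a flat waveform."""


@dataclass
class ProcessedWaveform:
    """A processed analysis waveform with its provenance.

    ``source`` is ``(measurement_id, channel, waveform_label)``; channel is
    1-based, waveform_label is one of T1–T5.
    """

    values: np.ndarray
    method: str
    source: tuple[str, int, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")


def start_point_offset(
    values: np.ndarray, source: tuple[str, int, str] | None = None
) -> ProcessedWaveform:
    """Subtract the signal value at the sample-injection start tick.

    ``output[i] = input[i] - input[0]``; the first element of the result is
    exactly zero and differences between samples are preserved.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot offset an empty waveform")
    return ProcessedWaveform(values - values[0], "start_point_offset", source)


def min_max_normalize(
    values: np.ndarray,
    source: tuple[str, int, str] | None = None,
    span_ticks: int | None = None,
    on_degenerate: str = "error",
) -> ProcessedWaveform:
    """Rescale a waveform so its minimum maps to 0 and its maximum to 1.

    The min and max are searched over the first ``span_ticks`` samples
    (default: the full cycle slice).  A flat waveform (max == min) raises
    :class:`DegenerateWaveformError` by default; with
    ``on_degenerate="zeros"`` it returns all zeros with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot normalize an empty waveform")
    span = values if span_ticks is None else values[:span_ticks]
    lo, hi = float(np.min(span)), float(np.max(span))
    if hi == lo:
        if on_degenerate == "zeros":
            warnings.warn("flat waveform: min == max, returning zeros", stacklevel=2)
            return ProcessedWaveform(np.zeros_like(values), "min_max", source)
        raise DegenerateWaveformError("flat waveform: min == max")
    return ProcessedWaveform((values - lo) / (hi - lo), "min_max", source)


def process(
    values: np.ndarray,
    method: str,
    source: tuple[str, int, str] | None = None,
    **kwargs,
) -> ProcessedWaveform:
    """Dispatch to the named processing method."""
    if method == "start_point_offset":
        return start_point_offset(values, source)
    if method == "min_max":
        return min_max_normalize(values, source, **kwargs)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
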