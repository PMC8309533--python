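"""Raw waveform records, the injection sequence, and cycle segmentation.

A measurement is stored on disk as a plain CSV (``time_s, ch1, ch2, ch3``)
with a JSON sidecar (``<stem>.meta.json``) carrying the measurement metadata.
There is no community standard for raw e-nose data; this pair of
human-inspectable text files is the package's canonical format.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np

__all__ = [
    "InjectionSequence",
    "WaveformRecord",
    "Cycle",
    "CycleSet",
    "FormatError",
    "default_sequence",
    "read_record",
    "write_record",
    "segment_cycles",
    "select_waveforms",
]

N_CHANNELS = 3

#: Sample types a record may carry.
SAMPLE_TYPES = ("breath", "reference", "room_air")

#: Experimental conditions a record may carry.
CONDITIONS = ("none", "pre_alcohol", "post_alcohol")


class FormatError(ValueError):
    """Raised when a record file or record violates the format contract."""


@dataclass(frozen=True)
class InjectionSequence:
    """Valve programming of the measurement module.

    Each block is ``(half_period_s, repetitions)``; one repetition is a
    sample-injection half-cycle followed by a purge half-cycle of equal
    length.  The default is the study protocol: 40 cycles of 5 s, 10 cycles
    of 10 s and one cycle of 30 s, sampled at 100 Hz (660 s, 66 000 ticks).
    """

    sampling_rate: float = 100.0
    blocks: tuple[tuple[float, int], ...] = ((5.0, 40), (10.0, 10), (30.0, 1))

    def __post_init__(self) -> None:
        if not np.isfinite(self.sampling_rate) or self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be a finite positive number")
        if not self.blocks:
            raise ValueError("sequence must contain at least one block")
        for half_period, reps in self.blocks:
            if half_period <= 0:
                raise ValueError("half_period must be > 0")
            if reps < 1:
                raise ValueError("repetitions must be >= 1")
            ticks = half_period * self.sampling_rate
            if abs(ticks - round(ticks)) > 1e-9:
                raise ValueError(
                    f"half_period {half_period} s is not an integer number of "
                    f"ticks at {self.sampling_rate} Hz"
                )

    @property
    def duration_s(self) -> float:
        return sum(2.0 * hp * reps for hp, reps in self.blocks)

    @property
    def n_ticks(self) -> int:
        return int(round(self.duration_s * self.sampling_rate))

    def half_cycles(self) -> list[tuple[float, str]]:
        """Flatten to an ordered list of (half_period_s, phase) entries,
        phase alternating 'sample', 'purge' within each cycle."""
        out: list[tuple[float, str]] = []
        for hp, reps in self.blocks:
            for _ in range(reps):
                out.append((hp, "sample"))
                out.append((hp, "purge"))
        return out


def default_sequence() -> InjectionSequence:
    """The study's injection sequence (40×5 s, 10×10 s, 1×30 s at 100 Hz)."""
    return InjectionSequence()


def _validate_metadata(metadata: dict) -> None:
    for key in ("rh_sample", "rh_purge"):
        if key in metadata and metadata[key] is not None:
            rh = float(metadata[key])
            if not (0.0 <= rh <= 100.0):
                raise FormatError(f"metadata field {key}={rh} outside [0, 100]")
    cond = metadata.get("condition", "none")
    if cond not in CONDITIONS:
        raise FormatError(f"metadata field condition={cond!r} not one of {CONDITIONS}")


@dataclass
class WaveformRecord:
    """One measurement: a 3-channel relative-resistance-change time series
    plus environment and subject metadata.

    ``signals`` has shape ``(3, n_ticks)`` (dimensionless ΔR/R); timestamps
    are seconds, strictly increasing and uniformly spaced.
    """

    measurement_id: str
    sample_type: str
    timestamps: np.ndarray
    signals: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.sample_type not in SAMPLE_TYPES:
            raise FormatError(
                f"sample_type={self.sample_type!r} not one of {SAMPLE_TYPES}"
            )
        if self.signals.ndim != 2 or self.signals.shape[0] != N_CHANNELS:
            raise FormatError(
                f"signals must have shape (3, n); got {self.signals.shape}"
            )
        if self.signals.shape[1] != self.timestamps.size:
            raise FormatError(
                "channel length mismatch: "
                f"{self.signals.shape[1]} samples vs {self.timestamps.size} timestamps"
            )
        if self.timestamps.size >= 2:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                raise FormatError("timestamps must be strictly increasing")
            if np.max(np.abs(dt - dt[0])) > 1e-6 * dt[0]:
                raise FormatError("timestamps are not uniformly spaced")
        _validate_metadata(self.metadata)

    @property
    def sampling_rate(self) -> float:
        if self.timestamps.size < 2:
            raise ValueError("cannot infer sampling rate from < 2 samples")
        return 1.0 / float(self.timestamps[1] - self.timestamps[0])

    @property
    def n_ticks(self) -> int:
        return int(self.timestamps.size)

    def copy(self) -> "WaveformRecord":
        return replace(
            self,
            timestamps=self.timestamps.copy(),
            signals=self.signals.copy(),
            metadata=dict(self.metadata),
        )


def write_record(record: WaveformRecord, path: str | Path) -> Path:
    """Write ``record`` to ``path`` (CSV) plus ``<stem>.meta.json``.

    Floats are printed with 17 significant digits so that a read round-trips
    bit-exactly.
    """
    path = Path(path)
    data = np.column_stack([record.timestamps, record.signals.T])
    np.savetxt(
        path,
        data,
        fmt="%.17g",
        delimiter=",",
        header="time_s,ch1,ch2,ch3",
        comments="",
    )
    meta = {
        "measurement_id": record.measurement_id,
        "sample_type": record.sample_type,
        "metadata": record.metadata,
    }
    sidecar = path.with_suffix(".meta.json")
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_record(path: str | Path) -> WaveformRecord:
    """Read a record written by :func:`write_record`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().strip()
    expected = "time_s,ch1,ch2,ch3"
    if header != expected:
        raise FormatError(f"malformed header: expected {expected!r}, got {header!r}")
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != 1 + N_CHANNELS:
        raise FormatError(f"expected 4 columns, got {data.shape[1]}")
    sidecar = path.with_suffix(".meta.json")
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    for key in ("measurement_id", "sample_type"):
        if key not in meta:
            raise FormatError(f"metadata sidecar missing field {key!r}")
    return WaveformRecord(
        measurement_id=meta["measurement_id"],
        sample_type=meta["sample_type"],
        timestamps=data[:, 0],
        signals=data[:, 1:].T,
        metadata=meta.get("metadata", {}),
    )


@dataclass(frozen=True)
class Cycle:
    """One sample/purge cycle as half-open tick intervals.

    ``[sample_start, purge_start)`` is the sample-injection half,
    ``[purge_start, end)`` the purge half.
    """

    sample_start: int
    purge_start: int
    end: int
    half_period_s: float


@dataclass
class CycleSet:
    """Segmentation of a record plus the designated analysis waveforms.

    ``analysis_indices`` point into ``cycles`` and identify T1–T5 (the last
    five cycles of the analysis half-period, 10 s by default).
    """

    cycles: list[Cycle]
    analysis_indices: list[int]
    sampling_rate: float

    @property
    def analysis_cycles(self) -> list[Cycle]:
        return [self.cycles[i] for i in self.analysis_indices]

    @property
    def waveform_labels(self) -> list[str]:
        return [f"T{k + 1}" for k in range(len(self.analysis_indices))]


def segment_cycles(
    record: WaveformRecord,
    sequence: InjectionSequence,
    analysis_half_period_s: float = 10.0,
    n_analysis: int = 5,
    strict: bool = True,
) -> CycleSet:
    """Segment a record into sample/purge cycles and mark T1–T5.

    The cycles tile the record exactly; the last ``n_analysis`` cycles with
    half-period ``analysis_half_period_s`` become the analysis waveforms.
    With ``strict=True`` fewer than ``n_analysis`` such cycles is an error;
    otherwise the available ones are used with a warning.
    """
    expected = sequence.n_ticks
    if record.n_ticks != expected:
        raise FormatError(
            f"record length mismatch: sequence requires {expected} ticks, "
            f"record has {record.n_ticks}"
        )
    rate = sequence.sampling_rate
    cycles: list[Cycle] = []
    tick = 0
    for hp, reps in sequence.blocks:
        half_ticks = int(round(hp * rate))
        for _ in range(reps):
            cycles.append(
                Cycle(
                    sample_start=tick,
                    purge_start=tick + half_ticks,
                    end=tick + 2 * half_ticks,
                    half_period_s=hp,
                )
            )
            tick += 2 * half_ticks

    candidates = [
        i for i, c in enumerate(cycles)
        if abs(c.half_period_s - analysis_half_period_s) < 1e-9
    ]
    if len(candidates) < n_analysis:
        msg = (
            f"only {len(candidates)} cycles of half-period "
            f"{analysis_half_period_s} s available; {n_analysis} required"
        )
        if strict:
            raise FormatError(msg)
        warnings.warn(msg, stacklevel=2)
        chosen = candidates
    else:
        chosen = candidates[-n_analysis:]
    return CycleSet(cycles=cycles, analysis_indices=chosen, sampling_rate=rate)


def select_waveforms(
    record: WaveformRecord, cycle_set: CycleSet
) -> dict[str, np.ndarray]:
    """Extract the analysis waveforms T1–T5 from a record.

    Returns a mapping ``label -> array of shape (3, cycle_ticks)``; each
    slice spans a full cycle (sample half followed by purge half).
    """
    if len(cycle_set.analysis_indices) < 5:
        raise FormatError(
            f"need 5 analysis cycles, have {len(cycle_set.analysis_indices)}"
        )
    out: dict[str, np.ndarray] = {}
    for label, cyc in zip(cycle_set.waveform_labels, cycle_set.analysis_cycles):
        out[label] = record.signals[:, cyc.sample_start : cyc.end]
    return out
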