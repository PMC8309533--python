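"""Synthetic MSS waveforms and whole-study fixtures.

The sensor response is modelled as a sum of first-order sorption components,
one for the humidity difference between sample and purge gas and one per
volatile compound.  Each component relaxes exponentially toward its
steady-state amplitude during sample injection (time constant ``tau_sorb``)
and decays toward zero during purging (``tau_desorb``); the total
steady-state amplitude is

    A = h * (rh_sample - rh_purge) + sum_v vocsens[v] * (conc_sample[v] - conc_purge[v])

with additive linear drift and i.i.d. Gaussian noise on top.  Compounds may
carry their own time constants, which is what leaves compound information in
a min-max-normalized waveform after the amplitude (and with it most of the
humidity signal) has been scaled away.

The parameters here are free modelling choices that reproduce the
qualitative shape and statistics of the real device's output; they are not
estimates of any physical sensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import InjectionSequence, WaveformRecord, default_sequence

__all__ = [
    "ChannelModel",
    "GasState",
    "SimStudyConfig",
    "simulate_waveform",
    "simulate_record",
    "simulate_study",
    "simulate_alcohol_experiment",
    "default_channel_models",
    "default_study_config",
    "scale_only_study_config",
    "default_breath_rh_purge",
    "default_reference_rh_purge",
]


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value}")
    return value


@dataclass(frozen=True)
class ChannelModel:
    """Response model of one sensor channel.

    Parameters
    ----------
    tau_sorb, tau_desorb
        Sorption/desorption time constants in seconds (> 0) governing the
        humidity component (and any compound without its own constant).
    h
        Humidity sensitivity, signal units per %RH (>= 0).
    vocsens
        Compound sensitivities, signal units per ppm.
    voc_tau_sorb, voc_tau_desorb
        Optional per-compound time constants; a compound not listed uses the
        channel constants.
    drift_rate
        Linear baseline drift, signal units per second.
    noise_sd
        Standard deviation of the per-tick Gaussian noise (>= 0).
    """

    name: str = "ch"
    tau_sorb: float = 1.0
    tau_desorb: float = 1.0
    h: float = 0.01
    vocsens: Mapping[str, float] = field(default_factory=dict)
    voc_tau_sorb: Mapping[str, float] = field(default_factory=dict)
    voc_tau_desorb: Mapping[str, float] = field(default_factory=dict)
    drift_rate: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for attr in ("tau_sorb", "tau_desorb"):
            v = _check_finite(attr, getattr(self, attr))
            if v <= 0:
                raise ValueError(f"{attr} must be > 0, got {v}")
        if _check_finite("h", self.h) < 0:
            raise ValueError("h must be >= 0")
        if _check_finite("noise_sd", self.noise_sd) < 0:
            raise ValueError("noise_sd must be >= 0")
        _check_finite("drift_rate", self.drift_rate)
        for m in (self.vocsens, self.voc_tau_sorb, self.voc_tau_desorb):
            for k, v in m.items():
                _check_finite(k, v)
        for m in (self.voc_tau_sorb, self.voc_tau_desorb):
            for k, v in m.items():
                if v <= 0:
                    raise ValueError(f"time constant for {k} must be > 0")


@dataclass(frozen=True)
class GasState:
    """Humidity, temperature and compound content of a gas."""

    rh: float
    temperature: float = 25.0
    voc_conc: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rh = _check_finite("rh", self.rh)
        if not (0.0 <= rh <= 100.0):
            raise ValueError(f"rh={rh} outside [0, 100]")
        _check_finite("temperature", self.temperature)
        for name, conc in self.voc_conc.items():
            if _check_finite(name, conc) < 0:
                raise ValueError(f"concentration of {name} must be >= 0")


def _components(
    channel: ChannelModel, sample: GasState, purge: GasState
) -> list[tuple[float, float, float]]:
    """(amplitude, tau_sorb, tau_desorb) per active stimulus."""
    comps = [
        (
            channel.h * (sample.rh - purge.rh),
            channel.tau_sorb,
            channel.tau_desorb,
        )
    ]
    vocs = set(sample.voc_conc) | set(purge.voc_conc)
    for v in sorted(vocs):
        sens = channel.vocsens.get(v, 0.0)
        delta = sample.voc_conc.get(v, 0.0) - purge.voc_conc.get(v, 0.0)
        if sens == 0.0 or delta == 0.0:
            continue
        comps.append(
            (
                sens * delta,
                channel.voc_tau_sorb.get(v, channel.tau_sorb),
                channel.voc_tau_desorb.get(v, channel.tau_desorb),
            )
        )
    return comps


def simulate_waveform(
    channel: ChannelModel,
    sample: GasState,
    purge: GasState,
    sequence: InjectionSequence | None = None,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Simulate one channel's response to the injection sequence.

    Returns one value per clock tick at the sequence's sampling rate.  With
    ``noise_sd = 0`` and ``drift_rate = 0`` the response during the first
    sample half-cycle is exactly ``A * (1 - exp(-t / tau_sorb))`` per
    component, measured from the half-cycle start.
    """
    if sequence is None:
        sequence = default_sequence()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rate = sequence.sampling_rate
    comps = _components(channel, sample, purge)
    n = sequence.n_ticks
    signal = np.zeros(n)

    state = [0.0] * len(comps)  # component value at the current phase start
    tick = 0
    for half_period, phase in sequence.half_cycles():
        m = int(round(half_period * rate))
        t_local = np.arange(m) / rate
        for ci, (amp, ts, td) in enumerate(comps):
            v0 = state[ci]
            if phase == "sample":
                decay = np.exp(-t_local / ts)
                signal[tick : tick + m] += amp + (v0 - amp) * decay
                state[ci] = amp + (v0 - amp) * np.exp(-half_period / ts)
            else:
                decay = np.exp(-t_local / td)
                signal[tick : tick + m] += v0 * decay
                state[ci] = v0 * np.exp(-half_period / td)
        tick += m

    if channel.drift_rate != 0.0:
        signal += channel.drift_rate * (np.arange(n) / rate)
    if channel.noise_sd > 0.0:
        signal += rng.normal(0.0, channel.noise_sd, size=n)
    return signal


def simulate_record(
    measurement_id: str,
    sample_type: str,
    channels: Sequence[ChannelModel],
    sample: GasState,
    purge: GasState,
    sequence: InjectionSequence,
    rng: np.random.Generator,
    metadata: dict | None = None,
) -> WaveformRecord:
    """Simulate all three channels of one measurement."""
    signals = np.vstack(
        [simulate_waveform(ch, sample, purge, sequence, rng) for ch in channels]
    )
    timestamps = np.arange(sequence.n_ticks) / sequence.sampling_rate
    meta = {
        "temperature_sample": sample.temperature,
        "rh_sample": sample.rh,
        "temperature_purge": purge.temperature,
        "rh_purge": purge.rh,
        "subject": "S1",
        "date": "",
        "condition": "none",
    }
    if metadata:
        meta.update(metadata)
    return WaveformRecord(
        measurement_id=measurement_id,
        sample_type=sample_type,
        timestamps=timestamps,
        signals=signals,
        metadata=meta,
    )


# --------------------------------------------------------------------------
# Study fixture
# --------------------------------------------------------------------------

def default_channel_models() -> tuple[ChannelModel, ChannelModel, ChannelModel]:
    """Three channels mimicking the study device's qualitative behaviour.

    Ch 1 and Ch 2 carry hydrophobic-like receptor parameters (strong ethanol
    sensitivity); Ch 3 is hydrophilic-like: ethanol-insensitive and with
    slower sorption kinetics.  Endogenous breath volatiles are lumped into a
    single compound ``breath_voc``.
    """
    return (
        ChannelModel(
            name="ch1",
            tau_sorb=1.2,
            tau_desorb=0.9,
            h=0.010,
            vocsens={"breath_voc": 0.08, "ethanol": 0.0008},
            voc_tau_sorb={"breath_voc": 0.35, "ethanol": 0.30},
            voc_tau_desorb={"breath_voc": 0.30, "ethanol": 0.25},
            drift_rate=2e-6,
            noise_sd=5e-4,
        ),
        ChannelModel(
            name="ch2",
            tau_sorb=1.5,
            tau_desorb=1.1,
            h=0.008,
            vocsens={"breath_voc": 0.05, "ethanol": 0.0006},
            voc_tau_sorb={"breath_voc": 0.40, "ethanol": 0.35},
            voc_tau_desorb={"breath_voc": 0.35, "ethanol": 0.30},
            drift_rate=2e-6,
            noise_sd=5e-4,
        ),
        ChannelModel(
            name="ch3",
            tau_sorb=2.5,
            tau_desorb=2.0,
            h=0.012,
            vocsens={"breath_voc": 0.03, "ethanol": 0.0},
            voc_tau_sorb={"breath_voc": 0.50},
            voc_tau_desorb={"breath_voc": 0.45},
            drift_rate=2e-6,
            noise_sd=5e-4,
        ),
    )


def _rh_comb(
    lo: float,
    n_pairs: int,
    n_singles: int,
    start_offset: float = 0.5,
    slot_step: float = 0.3,
    pair_gap: float = 0.06,
) -> list[float]:
    """Deterministic purge-RH values inside one 10-%RH bin.

    Matched pairs sit ``pair_gap`` (< 0.1 %RH) apart; distinct slots sit
    ``slot_step`` apart so nothing else falls within the matching tolerance.
    """
    vals: list[float] = []
    x = lo + start_offset
    for _ in range(n_pairs):
        vals.extend([x, x + pair_gap])
        x += slot_step
    for _ in range(n_singles):
        vals.append(x)
        x += slot_step
    return vals


def default_breath_rh_purge() -> tuple[float, ...]:
    """Fixed purge-RH values for the 83 breath measurements.

    Binned at 20/30/40/50 they give 24/25/34 members; greedy matching at
    0.1 %RH tolerance gives exactly 29 pairs (8 + 9 + 12 per bin).
    """
    vals = _rh_comb(20.0, 8, 8) + _rh_comb(30.0, 9, 7) + _rh_comb(40.0, 12, 10)
    return tuple(vals)


def default_reference_rh_purge() -> tuple[float, ...]:
    """Fixed purge-RH values for the 33 reference measurements (10/12/11 per
    bin; offset 0.17 %RH from the breath comb so no reference value falls
    within the 0.1 %RH matching tolerance of any other value)."""
    vals = (
        _rh_comb(20.0, 0, 10, start_offset=0.67)
        + _rh_comb(30.0, 0, 12, start_offset=0.67)
        + _rh_comb(40.0, 0, 11, start_offset=0.67)
    )
    return tuple(vals)


@dataclass(frozen=True)
class SimStudyConfig:
    """Full parameterization of the synthetic reproducibility study.

    The default replicates the study design: 83 breath and 33 reference
    measurements with purge-gas RH spanning 20–50 %RH in three subgroups and
    29 RH-matched breath pairs, sample gas at 70.3–75.3 %RH.
    """

    n_breath: int = 83
    n_reference: int = 33
    rh_purge_breath: tuple[float, ...] = field(default_factory=default_breath_rh_purge)
    rh_purge_reference: tuple[float, ...] = field(
        default_factory=default_reference_rh_purge
    )
    rh_sample_range: tuple[float, float] = (70.3, 75.3)
    breath_voc_ppm: tuple[float, float] = (1.0, 0.08)  # mean, sd of lumped VOC
    channel_models: tuple[ChannelModel, ...] = field(
        default_factory=default_channel_models
    )
    sequence: InjectionSequence = field(default_factory=default_sequence)
    seed: int = 0
    pair_structure: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.n_breath <= 0 or self.n_reference <= 0:
            raise ValueError("sample counts must be > 0")
        if len(self.rh_purge_breath) != self.n_breath:
            raise ValueError(
                f"rh_purge_breath has {len(self.rh_purge_breath)} values for "
                f"{self.n_breath} breath measurements"
            )
        if len(self.rh_purge_reference) != self.n_reference:
            raise ValueError(
                f"rh_purge_reference has {len(self.rh_purge_reference)} values "
                f"for {self.n_reference} reference measurements"
            )
        if len(self.channel_models) != 3:
            raise ValueError("exactly 3 channel models required")
        if self.pair_structure is not None:
            for i, j in self.pair_structure:
                if not (0 <= i < self.n_breath and 0 <= j < self.n_breath):
                    raise ValueError(
                        f"pair_structure index ({i}, {j}) out of range for "
                        f"{self.n_breath} breath measurements"
                    )


def default_study_config(seed: int = 0) -> SimStudyConfig:
    """The study-replication fixture configuration."""
    return SimStudyConfig(seed=seed)


def scale_only_study_config(seed: int = 0) -> SimStudyConfig:
    """A variant whose waveforms differ only in amplitude (no compounds).

    Every waveform is then the same humidity-driven exponential scaled by
    h·Δrh, so min-max normalization removes the entire between-sample
    structure.  Noise and drift are switched off too — a noisy waveform no
    longer differs from another by a pure scale factor — which makes the
    scale-removal argument exactly testable.
    """
    channels = tuple(
        ChannelModel(
            name=ch.name,
            tau_sorb=ch.tau_sorb,
            tau_desorb=ch.tau_desorb,
            h=ch.h,
            vocsens={},
            drift_rate=0.0,
            noise_sd=0.0,
        )
        for ch in default_channel_models()
    )
    return SimStudyConfig(seed=seed, channel_models=channels)


def _iso_date(i: int) -> str:
    # spread measurements over consecutive days of a nominal year
    month = 1 + (i // 28) % 12
    day = 1 + i % 28
    return f"2020-{month:02d}-{day:02d}"


def simulate_study(config: SimStudyConfig) -> list[WaveformRecord]:
    """Generate the full synthetic study (breath + reference records).

    Deterministic under ``config.seed``: the same config yields bit-identical
    records.  Breath records carry the lumped endogenous compound; reference
    records are humidified gas only.
    """
    rng = np.random.default_rng(config.seed)
    rh_breath = list(config.rh_purge_breath)
    if config.pair_structure:
        for i, j in config.pair_structure:
            rh_breath[j] = min(100.0, rh_breath[i] + 0.05)
    lo, hi = config.rh_sample_range
    mean_voc, sd_voc = config.breath_voc_ppm

    records: list[WaveformRecord] = []
    for i, rh_purge in enumerate(rh_breath):
        sample = GasState(
            rh=float(rng.uniform(lo, hi)),
            temperature=29.8,
            voc_conc={"breath_voc": max(0.0, float(rng.normal(mean_voc, sd_voc)))},
        )
        purge = GasState(rh=float(rh_purge), temperature=29.8)
        records.append(
            simulate_record(
                f"breath_{i:03d}",
                "breath",
                config.channel_models,
                sample,
                purge,
                config.sequence,
                rng,
                metadata={"date": _iso_date(i)},
            )
        )
    for i, rh_purge in enumerate(config.rh_purge_reference):
        sample = GasState(rh=float(rng.uniform(lo, hi)), temperature=29.8)
        purge = GasState(rh=float(rh_purge), temperature=29.8)
        records.append(
            simulate_record(
                f"reference_{i:03d}",
                "reference",
                config.channel_models,
                sample,
                purge,
                config.sequence,
                rng,
                metadata={"date": _iso_date(config.n_breath + i)},
            )
        )
    return records


def simulate_alcohol_experiment(
    config: SimStudyConfig,
    n_subjects: int = 3,
    n_days: int = 3,
    ethanol_ppm_range: tuple[float, float] = (60.0, 120.0),
) -> list[WaveformRecord]:
    """Paired pre/post-ethanol breath records per subject and day.

    Post-ingestion records carry an ethanol concentration drawn uniformly
    from ``ethanol_ppm_range``; pre-ingestion records carry none.  Purge RH
    is uncontrolled room air (23.0–41.8 %RH).
    """
    if n_subjects < 1 or n_days < 1:
        raise ValueError("n_subjects and n_days must be >= 1")
    elo, ehi = ethanol_ppm_range
    if not (0.0 <= elo <= ehi <= 300.0):
        raise ValueError(f"ethanol range ({elo}, {ehi}) must be within [0, 300]")

    rng = np.random.default_rng(config.seed)
    lo, hi = 70.3, 73.6
    mean_voc, sd_voc = config.breath_voc_ppm
    records: list[WaveformRecord] = []
    for s in range(n_subjects):
        for d in range(n_days):
            for condition in ("pre_alcohol", "post_alcohol"):
                voc = {"breath_voc": max(0.0, float(rng.normal(mean_voc, sd_voc)))}
                if condition == "post_alcohol":
                    voc["ethanol"] = float(rng.uniform(elo, ehi))
                sample = GasState(
                    rh=float(rng.uniform(lo, hi)), temperature=29.8, voc_conc=voc
                )
                purge = GasState(
                    rh=float(rng.uniform(23.0, 41.8)), temperature=29.8
                )
                records.append(
                    simulate_record(
                        f"alc_s{s + 1}_d{d + 1}_{condition}",
                        "breath",
                        config.channel_models,
                        sample,
                        purge,
                        config.sequence,
                        rng,
                        metadata={
                            "subject": f"S{s + 1}",
                            "date": _iso_date(d),
                            "condition": condition,
                            "ethanol_ppm": voc.get("ethanol", 0.0),
                        },
                    )
                )
    return records
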