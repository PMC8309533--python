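"""YAML configuration loading for the command-line interface."""

from __future__ import annotations

from pathlib import Path

import yaml

from .features import ExtractionGrid
from .io import InjectionSequence
from .simulate import ChannelModel, SimStudyConfig, default_channel_models
from .stats import RHBinning

__all__ = ["load_sequence", "load_grid", "load_study_config", "load_binning"]


def _load(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def load_sequence(path: str | Path) -> InjectionSequence:
    """Sequence YAML: ``sampling_rate`` plus ``blocks`` as
    ``[[half_period_s, repetitions], ...]``."""
    data = _load(path)
    return InjectionSequence(
        sampling_rate=float(data.get("sampling_rate", 100.0)),
        blocks=tuple((float(hp), int(rep)) for hp, rep in data["blocks"]),
    )


def load_grid(path: str | Path) -> ExtractionGrid:
    data = _load(path)
    return ExtractionGrid(**data)


def load_binning(edges: list[float] | None) -> RHBinning:
    return RHBinning(tuple(edges)) if edges else RHBinning()


def load_study_config(path: str | Path, seed: int | None = None) -> SimStudyConfig:
    """Study YAML: any SimStudyConfig field; channels as a list of
    ChannelModel field mappings; sequence inline as for :func:`load_sequence`."""
    data = _load(path)
    kwargs: dict = {}
    for key in (
        "n_breath",
        "n_reference",
        "rh_sample_range",
        "breath_voc_ppm",
        "seed",
    ):
        if key in data:
            kwargs[key] = (
                tuple(data[key]) if isinstance(data[key], list) else data[key]
            )
    for key in ("rh_purge_breath", "rh_purge_reference", "pair_structure"):
        if key in data:
            kwargs[key] = tuple(
                tuple(v) if isinstance(v, list) else float(v) for v in data[key]
            )
    if "channels" in data:
        kwargs["channel_models"] = tuple(
            ChannelModel(**ch) for ch in data["channels"]
        )
    else:
        kwargs["channel_models"] = default_channel_models()
    if "sequence" in data:
        seq = data["sequence"]
        kwargs["sequence"] = InjectionSequence(
            sampling_rate=float(seq.get("sampling_rate", 100.0)),
            blocks=tuple((float(hp), int(rep)) for hp, rep in seq["blocks"]),
        )
    if seed is not None:
        kwargs["seed"] = seed
    return SimStudyConfig(**kwargs)
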