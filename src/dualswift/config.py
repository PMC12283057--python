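"""Experiment configuration: a flat, human-diffable YAML mapping mirroring
the parameter dataclasses field-for-field.  Unknown keys are rejected."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .phantom import IRFParams, Paradigm
from .preprocess import PreprocParams
from .recon import ReconParams
from .sequence import SequenceParams
from .stats import StatsParams

__all__ = ["PhantomConfig", "ExperimentConfig", "load_config", "save_config", "scaled_config"]


@dataclass(frozen=True)
class PhantomConfig:
    """Synthetic-object settings (geometry scales with the matrix size)."""

    effect_size: tuple[float, float] = (0.005, 0.010)   # peak fractional change
    noise_sd: float = 0.0002      # k-space complex noise SD / mean |DC|
    latency_shift: tuple[float, float] = (0.0, 9.0)     # s, per FOV
    motion_events: tuple = ()     # ((volume, (dx, dy, dz)), ...)


@dataclass(frozen=True)
class ExperimentConfig:
    sequence: SequenceParams = field(default_factory=SequenceParams)
    paradigm: Paradigm = field(default_factory=Paradigm)
    irf: IRFParams = field(default_factory=IRFParams)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    recon: ReconParams = field(default_factory=ReconParams)
    preproc: PreprocParams = field(default_factory=PreprocParams)
    stats: StatsParams = field(default_factory=StatsParams)
    seed: int = 0
    subject_seeds: tuple = (0,)
    output_dir: str = "dualswift_out"


_SECTIONS = {
    "sequence": SequenceParams,
    "paradigm": Paradigm,
    "irf": IRFParams,
    "phantom": PhantomConfig,
    "recon": ReconParams,
    "preproc": PreprocParams,
    "stats": StatsParams,
}
_SCALARS = {"seed", "subject_seeds", "output_dir"}


def _build_section(cls, mapping: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**{
        f.name: _deep_tuple(mapping[f.name]) for f in fields(cls) if f.name in mapping
    })


def _deep_tuple(v):
    if isinstance(v, list):
        return tuple(_deep_tuple(x) for x in v)
    return v


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_SECTIONS) - _SCALARS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build_section(cls, raw[name] or {})
    for name in _SCALARS:
        if name in raw:
            v = raw[name]
            kwargs[name] = tuple(v) if isinstance(v, list) else v
    return ExperimentConfig(**kwargs)


def save_config(config: ExperimentConfig, path) -> None:
    doc = {}
    for name in _SECTIONS:
        doc[name] = asdict(getattr(config, name))
    doc["seed"] = config.seed
    doc["subject_seeds"] = list(config.subject_seeds)
    doc["output_dir"] = config.output_dir
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


STANDARD_MOTION_EVENTS = ((80, (0, 0, 2)), (160, (0, 0, -2)))


def scaled_config(
    matrix_size: int = 32,
    n_spokes: int = 480,
    seed: int = 0,
    noise_sd: float | None = None,
    motion_events: tuple = STANDARD_MOTION_EVENTS,
) -> ExperimentConfig:
    """Desk-scale configuration preserving the study's temporal structure.

    The spoke count is reduced and the TR pair lengthened so the volume TR
    stays 3 s and the paradigm still spans 248 volumes; matrix size shrinks
    with the FOV unchanged.
    """
    seq = SequenceParams(
        matrix_size=matrix_size,
        n_spokes_per_volume=n_spokes,
        tr_pair=3000.0 / n_spokes,
        n_volumes=248,
        samples_per_gap=max(matrix_size // 4, 8),  # keeps 2x radial oversampling
    )
    ph = PhantomConfig(motion_events=motion_events)
    if noise_sd is not None:
        ph = PhantomConfig(noise_sd=noise_sd, motion_events=motion_events)
    return ExperimentConfig(sequence=seq, phantom=ph, seed=seed, subject_seeds=(seed,))
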