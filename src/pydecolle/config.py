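"""Experiment configuration: strict, YAML-round-trippable dataclasses.

Every constant that the experiments depend on lives here with its default, so
deviations from the defaults are auditable in one place.  Unknown keys are
rejected on load; a resolved copy of the configuration is written next to all
experiment outputs and reproduces the run bit-identically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .network import LayerSpec, TrainConfig
from .neurons import NeuronConfig

__all__ = ["DataConfig", "ExperimentConfig", "load_config", "save_config"]


def _strict(cls, d: dict):
    allowed = {f.name for f in fields(cls) if f.init}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**d)


@dataclass
class DataConfig:
    """Synthetic-data parameters for both tasks.

    Regression: ``n_inputs`` Poisson units at ``rate_hz`` for ``duration_ms``.
    Classification: ``n_classes`` moving-bar classes on a ``height x width``
    sensor, with bar ``speed`` (px/step), ``bar_width``, timestamp ``jitter``
    (ms) and per-pixel ``noise_rate`` (Hz); ``n_train``/``n_test`` sequences.
    """

    n_inputs: int = 100
    rate_hz: float = 50.0
    duration_ms: float = 500.0
    f_hi: float = 20.0
    f_lo: float = 2.0
    n_classes: int = 4
    width: int = 16
    height: int = 16
    speed: float = 1.0
    bar_width: int = 2
    jitter: float = 0.25
    noise_rate: float = 1.0
    n_train: int = 32
    n_test: int = 100


@dataclass
class ExperimentConfig:
    """Complete description of one experiment run."""

    task: str = "regression"
    seed: int = 1
    out_dir: str = "scratch/run"
    n_passes: int = 200
    batch_size: int = 16
    neuron: NeuronConfig = field(default_factory=NeuronConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    data: DataConfig = field(default_factory=DataConfig)
    layers: list = field(default_factory=list)  # list of LayerSpec

    def to_dict(self) -> dict:
        d = asdict(self)
        # derived decay factors are recomputed on load, not configuration
        for k in ("alpha", "beta", "gamma"):
            d["neuron"].pop(k, None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        allowed = {f.name for f in fields(cls) if f.init}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown keys for ExperimentConfig: {sorted(unknown)}")
        if "neuron" in d:
            d["neuron"] = _strict(NeuronConfig, d["neuron"])
        if "train" in d:
            d["train"] = _strict(TrainConfig, d["train"])
        if "data" in d:
            d["data"] = _strict(DataConfig, d["data"])
        if "layers" in d:
            d["layers"] = [_strict(LayerSpec, ld) for ld in d["layers"]]
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


def save_config(cfg: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write(cfg.to_yaml())


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        return ExperimentConfig.from_dict(yaml.safe_load(fh))
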