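"""Single-source pipeline configuration, serialized as YAML.

A :class:`PipelineConfig` collects the knobs of every stage: generator
(sample count, overlap dial, noise), preprocessing (Savitzky-Golay window),
split, kNN and PC counts, CNN hyper-parameters, and the output directory.
Loading fills defaults for absent keys, rejects unknown keys, and validates
every cross-stage invariant before any stage runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .baselines import CONCAT_SPECTRA_PC_NUMBER, PER_LED_PC_NUMBERS
from .errors import ConfigurationError

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    # generator
    n_per_class: int = 60
    seed: int = 0
    overlap: float = 1.0
    additive_sd: float = 0.01
    background_level: float = 0.05
    # preprocessing
    sg_window: int = 11
    sg_polyorder: int = 2
    split_fraction: float = 0.5
    # baselines
    knn_k: int = 5
    knn_metric: str = "euclidean"
    per_led_pc_numbers: tuple[int, ...] = PER_LED_PC_NUMBERS
    concat_pc_number: int = CONCAT_SPECTRA_PC_NUMBER
    # cnn
    cnn_epochs: int = 200
    cnn_hidden: tuple[int, ...] = (128,)
    cnn_batch_size: int = 18
    cnn_learning_rate: float = 0.1
    cnn_momentum: float = 0.0
    # report
    comparison_seeds: tuple[int, ...] = (0, 1, 2)
    out_dir: str = "teafluor_output"

    def validate(self) -> None:
        if self.n_per_class < 2:
            raise ConfigurationError("n_per_class: must be >= 2 (50/50 split needs 2 per class)")
        if self.overlap < 0:
            raise ConfigurationError("overlap: must be >= 0")
        if self.additive_sd < 0:
            raise ConfigurationError("additive_sd: must be >= 0")
        if self.sg_window % 2 == 0:
            raise ConfigurationError("sg_window: must be odd")
        if self.sg_window <= self.sg_polyorder:
            raise ConfigurationError("sg_window: must exceed sg_polyorder")
        if not 0 < self.split_fraction < 1:
            raise ConfigurationError("split_fraction: must lie strictly in (0, 1)")
        if self.knn_k < 1:
            raise ConfigurationError("knn_k: must be >= 1")
        if len(self.per_led_pc_numbers) != 7:
            raise ConfigurationError("per_led_pc_numbers: must hold exactly 7 counts")
        if any(p < 1 for p in self.per_led_pc_numbers):
            raise ConfigurationError("per_led_pc_numbers: counts must be >= 1")
        if self.cnn_epochs < 0 or self.cnn_learning_rate < 0:
            raise ConfigurationError("cnn_epochs / cnn_learning_rate: must be >= 0")
        if self.cnn_batch_size is not None and self.cnn_batch_size < 1:
            raise ConfigurationError("cnn_batch_size: must be >= 1 or null for full batch")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


_TUPLE_FIELDS = {"per_led_pc_numbers", "cnn_hidden", "comparison_seeds"}


def load_config(path) -> PipelineConfig:
    """Read YAML, fill defaults, reject unknown keys, validate."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown keys {sorted(unknown)}")
    for k in _TUPLE_FIELDS & set(data):
        data[k] = tuple(data[k])
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
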