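"""Experiment configuration: YAML blocks for data, model and training.

Every run is described by three blocks — ``data`` (source, window, filter
band, split fractions), ``model`` (architecture geometry) and ``training``
(loss, schedule, batch, patience, seed).  Unknown keys are rejected by name
so typos fail loudly, and each run writes its fully resolved configuration
beside its outputs for reproducibility.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .model import ModelConfig
from .signal_io import CLASSES, LabeledDataset, bandpass_filter, read_csv_dataset, segment_beats, split_dataset, zscore_normalize
from .synthetic import default_templates, generate_dataset, load_fixture, table2_like_counts
from .training import TrainingConfig
from . import wfdb_io

__all__ = ["DataConfig", "ExperimentConfig", "build_dataset"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class DataConfig:
    source: str = "synthetic"  # "synthetic", a fixture/CSV path, or WFDB records
    total: int = 2000  # synthetic dataset size
    window_len: int = 360
    noise_sd: float = 0.05
    jitter_sd: float = 0.01
    fs: float = 360.0
    filter_low: float = 0.5
    filter_high: float = 50.0
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    stratified: bool = True
    normalize: bool = True
    records: tuple[str, ...] = ()  # WFDB record paths (without extension)


def _from_mapping(cls, mapping: dict, block: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in {block!r} block: {sorted(unknown)}")
    kwargs = dict(mapping)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(f.default, tuple):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


@dataclass
class ExperimentConfig:
    data: DataConfig = field(default_factory=DataConfig)
    model: ModelConfig = field(default_factory=ModelConfig.reduced)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    class_vocabulary: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        if self.model.class_num != len(self.class_vocabulary):
            raise ConfigError(
                f"model.class_num={self.model.class_num} does not match the "
                f"{len(self.class_vocabulary)}-label class vocabulary"
            )
        if self.model.window_len != self.data.window_len:
            raise ConfigError("model.window_len must equal data.window_len")

    @staticmethod
    def from_dict(raw: dict) -> "ExperimentConfig":
        known_blocks = {"data", "model", "training", "class_vocabulary", "model_preset"}
        unknown = set(raw) - known_blocks
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
        vocab = tuple(raw.get("class_vocabulary", CLASSES))
        data = _from_mapping(DataConfig, raw.get("data", {}), "data")
        model_raw = dict(raw.get("model", {}))
        preset = raw.get("model_preset", "reduced")
        if preset not in ("reduced", "full"):
            raise ConfigError(f"model_preset must be 'reduced' or 'full', got {preset!r}")
        base = ModelConfig.reduced(len(vocab), data.window_len) if preset == "reduced" else ModelConfig(
            class_num=len(vocab), window_len=data.window_len
        )
        known = {f.name for f in dataclasses.fields(ModelConfig)}
        unknown = set(model_raw) - known
        if unknown:
            raise ConfigError(f"unknown key(s) in 'model' block: {sorted(unknown)}")
        if "channels" in model_raw:
            model_raw["channels"] = tuple(model_raw["channels"])
        model = dataclasses.replace(base, **model_raw)
        training = _from_mapping(TrainingConfig, raw.get("training", {}), "training")
        return ExperimentConfig(data=data, model=model, training=training, class_vocabulary=vocab)

    @staticmethod
    def from_yaml(path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return ExperimentConfig.from_dict(raw)

    def to_yaml(self, path) -> None:
        """Write the fully resolved configuration (every effective value)."""
        payload = {
            "class_vocabulary": list(self.class_vocabulary),
            "data": dataclasses.asdict(self.data),
            "model": dataclasses.asdict(self.model),
            "training": dataclasses.asdict(self.training),
        }
        payload["data"]["fractions"] = list(self.data.fractions)
        payload["model"]["channels"] = list(self.model.channels)
        payload["training"]["stretch_range"] = list(self.training.stretch_range)
        payload["training"]["scale_range"] = list(self.training.scale_range)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def build_dataset(config: ExperimentConfig, seed: int | None = None) -> LabeledDataset:
    """Materialize the configured dataset: generate or load, preprocess, split.

    Synthetic beats are generated with the class-imbalance preset; WFDB
    records are band-pass filtered (whole record, zero phase) and segmented
    around their annotated R-peaks.  Each beat is then z-scored individually
    and the dataset is split 70/10/20 (stratified by default).
    """
    d = config.data
    seed = config.training.seed if seed is None else seed
    if d.source == "synthetic":
        counts = table2_like_counts(d.total)
        counts = {c: counts.get(c, 0) for c in config.class_vocabulary}
        templates = default_templates(noise_sd=d.noise_sd, jitter_sd=d.jitter_sd)
        dataset = generate_dataset(counts, templates, window_len=d.window_len, rng_seed=seed)
    elif d.source == "wfdb":
        if not d.records:
            raise ConfigError("data.source='wfdb' requires data.records")
        beats = []
        for rec in d.records:
            signal, fs, _info = wfdb_io.read_record(rec)
            lead = bandpass_filter(signal[:, 0], fs, d.filter_low, d.filter_high)
            times, symbols = wfdb_io.read_annotations(rec + ".atr")
            result = segment_beats(lead, times, symbols, d.window_len, source_record=str(rec))
            beats.extend(result.segments)
        dataset = LabeledDataset(beats, list(config.class_vocabulary))
    elif d.source.endswith(".csv"):
        dataset = read_csv_dataset(d.source, config.class_vocabulary)
    elif d.source.endswith(".header") or d.source.endswith(".hdr"):
        matrix = d.source.rsplit(".", 1)[0] + ".matrix"
        dataset = load_fixture(d.source, matrix)
    else:
        raise ConfigError(f"unknown data source {d.source!r}")
    if d.normalize:
        for b in dataset.beats:
            b.samples = zscore_normalize(b.samples)
    return split_dataset(dataset, d.fractions, rng_seed=seed, stratified=d.stratified)
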