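"""Single-file pipeline configuration (``key = value`` lines).

Flags on the command line override file values.  Every run logs the
resolved configuration together with the global seed so results can be
reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

from .exceptions import ConfigError
from .model import TrainConfig


@dataclass
class PipelineConfig:
    """All stage parameters of the pipeline in one place."""

    # graph
    sim_threshold: float = 0.0
    # walks
    num_walks_per_node: int = 10
    walk_length: int = 80
    p: float = 1.0
    q: float = 1.0
    # skip-gram
    dim: int = 100
    window: int = 10
    negatives: int = 5
    epochs: int = 5
    # training / evaluation
    train: TrainConfig = field(default_factory=TrainConfig)
    repeats: int = 1
    workers: int = 1
    # prediction
    binary_threshold: float = 0.95
    label_threshold: float = 0.5
    seed: int = 0

    _INT_KEYS = {
        "num_walks_per_node", "walk_length", "dim", "window", "negatives",
        "epochs", "repeats", "workers", "seed",
    }
    _FLOAT_KEYS = {"sim_threshold", "p", "q", "binary_threshold", "label_threshold"}
    _TRAIN_INT = {"min_child_weight", "early_stopping_rounds", "n_estimators", "smote_k", "seed"}
    _TRAIN_FLOAT = {"learning_rate", "subsample", "gamma"}

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        cfg = cls()
        with open(path) as fh:
            for lineno, ln in enumerate(fh, start=1):
                ln = ln.split("#", 1)[0].strip()
                if not ln:
                    continue
                if "=" not in ln:
                    raise ConfigError(f"line {lineno}: expected 'key = value', got {ln!r}")
                key, _, value = ln.partition("=")
                cfg = cfg.with_option(key.strip(), value.strip())
        return cfg

    def with_option(self, key: str, value: str) -> "PipelineConfig":
        if key in self._INT_KEYS:
            return replace(self, **{key: int(value)})
        if key in self._FLOAT_KEYS:
            return replace(self, **{key: float(value)})
        if key.startswith("train."):
            sub = key[len("train."):]
            if sub == "depth_grid":
                grid = tuple(int(x) for x in value.split(","))
                return replace(self, train=replace(self.train, depth_grid=grid))
            if sub in self._TRAIN_INT:
                return replace(self, train=replace(self.train, **{sub: int(value)}))
            if sub in self._TRAIN_FLOAT:
                return replace(self, train=replace(self.train, **{sub: float(value)}))
        raise ConfigError(f"unknown configuration key {key!r}")

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            if f.name == "train":
                for tf in fields(TrainConfig):
                    val = getattr(self.train, tf.name)
                    if tf.name == "depth_grid":
                        val = ",".join(str(d) for d in val)
                    lines.append(f"train.{tf.name} = {val}")
            else:
                lines.append(f"{f.name} = {getattr(self, f.name)}")
        return "\n".join(lines)
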