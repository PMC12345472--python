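"""Run configuration: flat key/value config files with CLI overrides.

The config format is INI-style sections of ``key = value`` pairs (sections
``[train]``, ``[data]``, ``[output]``); unknown keys are rejected so typos
fail loudly.  Every run writes the fully resolved configuration, the root
seed and a version stamp next to its outputs, which together regenerate every
artifact bit-for-bit.
"""

from __future__ import annotations

import configparser
import dataclasses
import json
from pathlib import Path

from .train_eval import TrainingConfig

_TRAIN_FIELDS = {f.name: f.type for f in dataclasses.fields(TrainingConfig)}
_DATA_FIELDS = {"manifest", "root", "out_dir", "n_ids", "reps_per_cell",
                "protocol", "augment_train", "image_size"}


@dataclasses.dataclass
class RunConfig:
    train: TrainingConfig
    manifest: str | None = None
    root: str = "."
    out_dir: str = "runs"
    n_ids: int = 20
    reps_per_cell: int = 8
    protocol: str = "age_based"
    augment_train: bool = False
    image_size: int = 64

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["train"] = self.train.to_dict()
        return d


def _coerce(value: str, like):
    if isinstance(like, bool):
        return value.strip().lower() in ("1", "true", "yes", "on")
    if isinstance(like, int):
        return int(value)
    if isinstance(like, float):
        return float(value)
    return value


def load_run_config(path: str | Path | None = None,
                    overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from an optional file plus override pairs."""
    cfg = RunConfig(train=TrainingConfig())
    if path is not None:
        parser = configparser.ConfigParser()
        read = parser.read(path)
        if not read:
            raise FileNotFoundError(path)
        for section in parser.sections():
            if section not in ("train", "data", "output"):
                raise ValueError(f"unknown config section: [{section}]")
            for key, value in parser.items(section):
                _apply(cfg, key, value)
    for key, value in (overrides or {}).items():
        if value is not None:
            _apply(cfg, key, value)
    return cfg


def _apply(cfg: RunConfig, key: str, value) -> None:
    if key in _TRAIN_FIELDS:
        current = getattr(cfg.train, key)
        setattr(cfg.train, key, _coerce(str(value), current))
    elif key in _DATA_FIELDS:
        current = getattr(cfg, key)
        coerced = _coerce(str(value), current if current is not None else "")
        setattr(cfg, key, coerced)
    else:
        raise ValueError(f"unknown config key: {key}")


def write_run_stamp(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Persist the resolved config + seed + version next to run outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = {"config": cfg.to_dict(), "seed": cfg.train.seed,
             "version": __version__}
    path = out_dir / "run_config.json"
    path.write_text(json.dumps(stamp, indent=2, sort_keys=True) + "\n")
    return path
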