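"""Run configuration: YAML loading/validation, checkpoints, k-fold splits.

One config file drives every pipeline stage so ablation variants are
reproducible as config diffs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, is_dataclass

import numpy as np
import yaml

from .blocks import MDPConfig, MPConfig
from .io_prep import AugmentParams
from .losses import LossConfig
from .network import MSCDUNet, NetworkConfig, build_model
from .phantom import PhantomSpec
from .train import TrainConfig

__all__ = [
    "ConfigError",
    "InferenceConfig",
    "RunConfig",
    "load_config",
    "save_config",
    "kfold_split",
    "save_checkpoint",
    "load_checkpoint",
]


class ConfigError(ValueError):
    pass


@dataclass
class InferenceConfig:
    patch: int = None  # defaults to the network patch size
    stride: int = 8
    mode: str = "vote"


@dataclass
class RunConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    augment: AugmentParams = field(default_factory=AugmentParams)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    evaluation: list = field(default_factory=lambda: [1, 2, 3])
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.network.n_classes != len(self.loss.omega):
            raise ConfigError(
                f"loss.omega has {len(self.loss.omega)} entries but "
                f"network.n_classes is {self.network.n_classes}"
            )
        if self.network.n_classes != 4:
            raise ConfigError(
                "network.n_classes must be 4 to match the phantom tissue classes"
            )
        if self.network.n_modalities != self.phantom.n_modalities:
            raise ConfigError(
                f"network.n_modalities ({self.network.n_modalities}) must equal "
                f"phantom.n_modalities ({self.phantom.n_modalities})"
            )


def _normalize(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (tuple, list)):
        return [_normalize(v) for v in value]
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if is_dataclass(value) and not isinstance(value, type):
        return to_dict(value)
    return value


def to_dict(cfg):
    return {f.name: _normalize(getattr(cfg, f.name)) for f in fields(cfg)}


def _from_dict(cls, d, path):
    d = dict(d or {})
    names = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    unknown = sorted(set(d) - names)
    if unknown:
        raise ConfigError(f"{path}: unknown fields {unknown}")
    try:
        return cls(**d)
    except ConfigError:
        raise
    except (ValueError, TypeError) as e:
        raise ConfigError(f"{path}: {e}") from e


def _network_from_dict(d):
    d = dict(d or {})
    mp = _from_dict(MPConfig, d.pop("mp", {}), "network.mp")
    mdp = _from_dict(MDPConfig, d.pop("mdp", {}), "network.mdp")
    d["mp"], d["mdp"] = mp, mdp
    return _from_dict(NetworkConfig, d, "network")


def run_config_from_dict(d) -> RunConfig:
    d = dict(d or {})
    known = {
        "phantom",
        "network",
        "training",
        "loss",
        "augment",
        "inference",
        "evaluation",
        "paths",
    }
    unknown = sorted(set(d) - known)
    if unknown:
        raise ConfigError(f"unknown top-level sections {unknown}")
    try:
        return RunConfig(
            phantom=_from_dict(PhantomSpec, d.get("phantom"), "phantom"),
            network=_network_from_dict(d.get("network")),
            training=_from_dict(TrainConfig, d.get("training"), "training"),
            loss=_from_dict(LossConfig, d.get("loss"), "loss"),
            augment=_from_dict(AugmentParams, d.get("augment"), "augment"),
            inference=_from_dict(InferenceConfig, d.get("inference"), "inference"),
            evaluation=list(d.get("evaluation", [1, 2, 3])),
            paths=dict(d.get("paths", {})),
        )
    except ConfigError:
        raise
    except (ValueError, TypeError) as e:
        raise ConfigError(str(e)) from e


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (defaults filled in)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return run_config_from_dict(raw)


def save_config(path, cfg: RunConfig):
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(cfg), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# cross-validation splits

def kfold_split(subject_ids, k: int, seed: int):
    """k disjoint validation folds covering all subjects (sizes differ
    by at most 1), deterministic under ``seed``."""
    ids = list(subject_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k = {k} exceeds the {len(ids)} subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds = np.array_split(order, k)
    out = []
    for f in folds:
        val = [ids[i] for i in f]
        train = [ids[i] for i in order if ids[i] not in val]
        out.append((train, val))
    return out


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(path, model: MSCDUNet):
    """Write weights + the embedded network config as a .npz archive."""
    arrays = {name: arr for name, arr in model.state_arrays()}
    net = to_dict(model.cfg)
    arrays["__config__"] = np.frombuffer(
        json.dumps(net).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> MSCDUNet:
    with np.load(path) as data:
        cfg = _network_from_dict(
            json.loads(bytes(data["__config__"].tobytes()).decode())
        )
        model = build_model(cfg)
        arrays = {k: data[k] for k in data.files if k != "__config__"}
    model.load_state_arrays(arrays)
    return model.eval()
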