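"""Model and training configuration.

One flat dataclass holds every knob the architecture leaves open. The
full-scale defaults follow the reference settings (message-passing
depth 3, segment length 11, 15% masking, protein lengths up to 990 =
the largest multiple of 11 below the 1000-residue corpus cap); the
``toy()`` preset shrinks every dimension for CPU-scale tests and the
synthetic end-to-end pipeline.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["ModelConfig"]


@dataclass
class ModelConfig:
    # molecule encoder
    hidden_dim: int = 128
    depth: int = 3
    dropout_rate: float = 0.1
    # protein encoder
    segment_length: int = 11
    max_total_length: int = 990
    mask_rate: float = 0.15
    mlm_size: str = "base"                 # "base" | "large"
    mlm_overrides: dict | None = None      # explicit MLM dims instead of preset
    bert_mixing: bool = False
    cpc_steps: int = 1
    cpc_kwargs: dict = field(default_factory=dict)
    n_negatives: int = 8
    pretrain_min_len: int = 70
    pretrain_max_len: int = 1000
    pretrain_objective: str = "alternating"  # "alternating" | "joint"
    # fusion / head
    attention_dim: int = 32
    mlp_hidden: tuple[int, ...] = (64, 32)
    l2_coeff: float = 1e-4
    # optimisation
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 30
    seed: int = 0
    freeze_protein: bool = False

    def __post_init__(self):
        if self.depth < 1 or self.hidden_dim < 1:
            raise ConfigError("depth and hidden_dim must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.segment_length < 1 or self.max_total_length % self.segment_length:
            raise ConfigError(
                "max_total_length must be a positive multiple of segment_length")
        if not 0.0 < self.mask_rate < 1.0:
            raise ConfigError("mask_rate must be in (0, 1)")
        if self.mlm_size not in ("base", "large"):
            raise ConfigError("mlm_size must be 'base' or 'large'")
        if self.pretrain_objective not in ("alternating", "joint"):
            raise ConfigError("pretrain_objective must be 'alternating' or 'joint'")
        if min(self.learning_rate, self.batch_size, self.epochs,
               self.cpc_steps, self.attention_dim, self.n_negatives) <= 0:
            raise ConfigError("optimisation knobs must be positive")
        if self.l2_coeff < 0:
            raise ConfigError("l2_coeff must be >= 0")
        self.mlp_hidden = tuple(self.mlp_hidden)

    @classmethod
    def toy(cls, **overrides) -> "ModelConfig":
        """Small dimensions for CPU-scale runs on synthetic data."""
        base = dict(
            hidden_dim=16, depth=2, dropout_rate=0.0,
            segment_length=11, max_total_length=110,
            mlm_overrides=dict(d_model=16, n_layers=1, n_heads=2, d_ff=32),
            cpc_kwargs=dict(d_emb=8, channels=(16,), kernel_size=3, d_out=8),
            attention_dim=16, mlp_hidden=(32,),
            learning_rate=3e-3, batch_size=16, epochs=30,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        # json round-trip turns tuples into lists (YAML/JSON friendly)
        return json.loads(json.dumps(asdict(self)))

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path):
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "ModelConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
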