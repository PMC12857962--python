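"""Run configuration: every model, augmentation, and training hyperparameter.

Defaults follow the published configuration of the architecture this package
implements (hidden size 512, 6 layers, 8 heads, dropout 0.3, lr 1e-4, batch
256, contrastive temperature 0.1, loss weights alpha = 0.5 and beta = 1e-5,
augmentation ratios 0.15 / 0.10 / 0.75 / 0.05, three training phases of
50 / 100 / 25 epochs).  ``RunConfig.desk_scale()`` returns the reduced
configuration used for CPU-scale studies on synthetic data.

Ablation switches mirror the published component-removal variants; see
``ABLATION_VARIANTS``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml


@dataclass
class RunConfig:
    # -- encoder (graph transformer) --
    d_model: int = 512
    n_layers: int = 6
    n_heads: int = 8
    dropout: float = 0.3
    ffn_mult: int = 4
    pool_clusters: int | None = None      # None = auto: max(2, ceil(n/4)) cap 16
    pool_aux_weight: float = 0.0
    spatial_bias_on: bool = True
    scale_bias_inside: bool = True        # (QK^T + S)/sqrt(d_k) vs QK^T/sqrt(d_k) + S
    d_max: int = 8
    weight_scheme: str = "unit"
    use_hier_pool: bool = True            # False: mean-pool atom states directly
    standard_transformer_mode: bool = False   # no spatial bias, no hierarchy
    gcn_baseline_mode: bool = False       # adjacency message passing instead of attention

    # -- augmentation --
    mask_ratio: float = 0.15
    perturb_ratio: float = 0.10
    sample_ratio: float = 0.75
    hop_probability: float = 0.05
    importance_threshold: float = 0.5     # tau_imp
    ensemble_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    mask_mode: str = "token"              # "token" | "delete"

    # -- contrastive --
    temperature: float = 0.1
    alpha: float = 0.5                    # contrastive loss weight
    beta: float = 1e-5                    # L2 regularization weight
    projection_dim: int = 128
    denominator_mode: str = "with_positive"   # | "literal"
    use_hard_mining: bool = False
    hard_negative_k: int = 8
    use_contrastive: bool = True

    # -- cross-modal fusion --
    fusion_on: bool = True
    adaptive_fusion_on: bool = True       # False: fixed lambda = 0.5
    d_bert: int = 128
    seq_layers: int = 2
    seq_heads: int = 4
    seq_max_len: int = 128

    # -- prediction head --
    head_dims: tuple[int, int] = (1024, 256)
    symmetrize_inference: bool = True
    bce_reduction: str = "mean"           # | "sum" (literal printed objective)
    threshold: float = 0.5

    # -- optimization --
    learning_rate: float = 1e-4
    batch_size: int = 256
    grad_clip: float = 1.0
    early_stop_patience: int = 15
    phase1_epochs: int = 50
    phase2_epochs: int = 100
    phase3_epochs: int = 25
    phase3_lr_factor: float = 0.1
    precision: str = "float32"            # training dtype; analyses promote to float64
    seed: int = 0

    # -- splitting --
    split_mode: str = "transductive"      # | inductive_random | inductive_scaffold
    pair_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    drug_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for name in ("mask_ratio", "perturb_ratio", "sample_ratio",
                     "hop_probability"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads

    @classmethod
    def desk_scale(cls, **overrides) -> "RunConfig":
        """Reduced configuration for single-CPU studies on synthetic data."""
        base = dict(
            d_model=64, n_layers=2, n_heads=2, dropout=0.1, ffn_mult=2,
            d_bert=32,
            seq_layers=1, seq_heads=2, projection_dim=32, head_dims=(128, 64),
            batch_size=32, learning_rate=1e-3, phase1_epochs=5,
            phase2_epochs=20, phase3_epochs=5, hard_negative_k=4,
        )
        base.update(overrides)
        return cls(**base)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        fields = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - fields
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        for key in ("ensemble_weights", "head_dims", "pair_fractions",
                    "drug_fractions"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


# Published component-removal variants, as config deltas on a base config.
ABLATION_VARIANTS: dict[str, dict] = {
    "full_model": {},
    "wo_contrastive_learning": {"use_contrastive": False, "alpha": 0.0},
    "wo_hierarchical_pooling": {"use_hier_pool": False},
    "wo_cross_modal_fusion": {"fusion_on": False},
    "wo_spatial_encoding": {"spatial_bias_on": False},
    "wo_hard_negative_mining": {"use_hard_mining": False},
    "wo_adaptive_fusion": {"adaptive_fusion_on": False},
    "standard_transformer": {"standard_transformer_mode": True,
                             "spatial_bias_on": False, "use_hier_pool": False},
    "gcn_baseline": {"gcn_baseline_mode": True},
}
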