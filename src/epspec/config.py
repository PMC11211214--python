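"""Run configuration for the enhancer-promoter specificity pipeline.

Two configuration objects cover the whole analysis: :class:`PipelineConfig`
holds every threshold and structural parameter of the supervised pipeline
(candidate window, contact binning, label alpha, blocking gap, fold counts,
NMF rank, evaluation recall target, contact-strength cut-offs), and
:class:`SimConfig` (in :mod:`epspec.synth`) parameterizes the synthetic-data
generator.  Both round-trip through plain YAML mappings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Parameters of the EP-specificity analysis.

    Defaults follow the study design: candidate pairs within a 5-Mb window,
    positives called at adjusted p < 0.1 with down-regulation, blocking groups
    separated by >= 5 Mb, a 4x4 nested blocked cross-validation, NMF rank 12,
    model comparison at recall 0.70, and weak/strong contact cut-offs of
    0.002 (class comparison) and 0.005 (distribution comparison).
    """

    window_bp: int = 5_000_000
    bin_size: int = 5_000
    alpha_label: float = 0.1
    gap_bp: int = 5_000_000
    outer_folds: int = 4
    inner_folds: int = 4
    holdout_chroms: tuple[str, ...] = ("chr5", "chr10", "chr15", "chr20")
    nmf_k: int = 12
    recall_target: float = 0.70
    weak_contact_threshold: float = 0.002
    strong_contact_threshold: float = 0.005
    tss_flank_bp: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "window_bp",
            "bin_size",
            "gap_bp",
            "alpha_label",
            "recall_target",
            "weak_contact_threshold",
            "strong_contact_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        self.holdout_chroms = tuple(self.holdout_chroms)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["holdout_chroms"] = list(self.holdout_chroms)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class HyperParamBounds:
    """Declared search space for gradient-boosting hyper-parameters.

    Bounds bracket the library defaults; the positive-class weight upper
    bound is resolved against the observed class ratio at search time.
    """

    max_depth: tuple[int, int] = (2, 10)
    learning_rate: tuple[float, float] = (0.005, 0.3)  # log-uniform
    n_rounds_max: int = 2000
    min_child_weight: tuple[float, float] = (1.0, 16.0)  # log-uniform
    subsample: tuple[float, float] = (0.5, 1.0)
    colsample_bytree: tuple[float, float] = (0.5, 1.0)
    reg_alpha: tuple[float, float] = (1e-3, 10.0)  # log-uniform
    reg_lambda: tuple[float, float] = (1e-3, 10.0)  # log-uniform
    scale_pos_weight: tuple[float, float] | None = None  # (1, neg/pos) when None

    def resolved_pos_weight(self, n_pos: int, n_neg: int) -> tuple[float, float]:
        if self.scale_pos_weight is not None:
            return self.scale_pos_weight
        return (1.0, max(1.0, n_neg / max(n_pos, 1)))
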