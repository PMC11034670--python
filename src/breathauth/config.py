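"""Pipeline configuration: one validated source of truth for every knob."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunables of the authentication pipeline with their defaults.

    Values are validated on construction; unknown keys are rejected so a
    typo in a config file cannot silently fall back to a default.
    """

    # segmentation / normalization
    window_fraction: float = 1 / 10
    slide_fraction: float = 1 / 2
    normalize_scope: str = "segment"
    # MFDFA
    q_min: float = -5.0
    q_max: float = 5.0
    q_step: float = 0.25
    scale_min: int = 16
    n_scales: int = 10
    detrend_order: int = 1
    width_min: float = 0.05
    convexity_tol: float = 0.01
    # feature reduction
    variance_threshold: float = 0.01
    correlation_threshold: float = 0.8
    top_k: int = 10
    rf_seed: int = 0
    rf_trees: int = 100
    # splitting / evaluation
    train_frac: float = 0.6
    confirm_threshold: float = 50.0
    eta_t: float = 55.0
    weights: tuple[float, float] = (0.3, 0.7)
    alpha: float = 0.001
    n_shuffles: int = 66
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.window_fraction <= 1:
            raise ValueError("window_fraction must lie in (0, 1]")
        if not 0 < self.slide_fraction <= 1:
            raise ValueError("slide_fraction must lie in (0, 1]")
        if self.normalize_scope not in ("segment", "trial"):
            raise ValueError("normalize_scope must be 'segment' or 'trial'")
        if self.q_min >= self.q_max or self.q_step <= 0:
            raise ValueError("q grid must be increasing")
        if self.scale_min < 4 or self.n_scales < 3:
            raise ValueError("need scale_min >= 4 and n_scales >= 3")
        if self.detrend_order < 1:
            raise ValueError("detrend_order must be >= 1")
        if self.width_min < 0:
            raise ValueError("width_min must be >= 0")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must lie in (0, 1)")
        w = tuple(float(x) for x in self.weights)
        if len(w) != 2 or any(x < 0 for x in w) or abs(sum(w) - 1) > 1e-9:
            raise ValueError("weights must be two non-negatives summing to 1")
        self.weights = w
        for name in ("confirm_threshold", "eta_t"):
            v = getattr(self, name)
            if not 0 <= v <= 101:
                raise ValueError(f"{name} must be a percentage")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_shuffles < 1 or self.top_k < 1 or self.rf_trees < 1:
            raise ValueError("n_shuffles, top_k and rf_trees must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["weights"] = list(d["weights"])
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a key/value mapping")
        if "weights" in data:
            data["weights"] = tuple(data["weights"])
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))
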