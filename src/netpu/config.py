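"""Run configuration: every tunable of the pipeline in one validated record."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline tunables with their defaults.

    alpha:          restart weight of the label propagation, in (0, 1].
    tol:            L2 convergence tolerance of the propagation.
    q_w:            quantile threshold sparsifying the similarity matrix.
    rn_size:        number of reliable negatives (None -> |P|).
    fractions:      (f_LP, f_WN, f_LN) quantile cuts of the ranking, sum 1.
    t_heat/t_balanced:  diffusion times (dimensionless).
    penalization:   non-seed score penalty of the weighted-path feature.
    mixing:         seed-rank convex-combination weight of the ring feature.
    model:          classifier, one of rf/svm/mlp.
    test_fraction:  held-out fraction of the stratified split.
    cv:             folds of cross-validation.
    mask_fraction/n_folds:  seed-masking protocol.
    seed:           RNG seed for every stochastic step.
    Generator knobs (n, module_size, p_in, p_out, hidden_fraction,
    score_low, score_high) shape the synthetic instance.
    """

    alpha: float = 0.8
    tol: float = 1e-6
    max_iter: int = 10_000
    q_w: float = 0.75
    rn_size: int | None = None
    fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    t_heat: float = 0.005
    t_balanced: float = 0.005
    penalization: float = 0.5
    mixing: float = 0.5
    invert_netring: bool = True
    model: str = "rf"
    test_fraction: float = 0.3
    cv: int = 5
    mask_fraction: float = 0.2
    n_folds: int = 5
    seed: int = 0
    n: int = 300
    module_size: int = 30
    p_in: float = 0.3
    p_out: float = 0.01
    hidden_fraction: float = 0.3
    score_low: float = 0.3
    score_high: float = 1.0

    def __post_init__(self) -> None:
        self.fractions = tuple(float(x) for x in self.fractions)  # type: ignore[assignment]
        checks = [
            (0.0 < self.alpha <= 1.0, "alpha must be in (0, 1]"),
            (self.tol > 0, "tol must be positive"),
            (self.max_iter > 0, "max_iter must be positive"),
            (0.0 <= self.q_w < 1.0, "q_w must be in [0, 1)"),
            (self.rn_size is None or self.rn_size > 0, "rn_size must be positive"),
            (len(self.fractions) == 3 and all(f > 0 for f in self.fractions)
             and abs(sum(self.fractions) - 1.0) < 1e-9,
             "fractions must be three positives summing to 1"),
            (self.t_heat > 0 and self.t_balanced > 0, "diffusion times must be positive"),
            (self.penalization > 0, "penalization must be positive"),
            (0.0 <= self.mixing <= 1.0, "mixing must be in [0, 1]"),
            (self.model in ("rf", "svm", "mlp"), "model must be rf, svm or mlp"),
            (0.0 < self.test_fraction < 1.0, "test_fraction must be in (0, 1)"),
            (self.cv >= 2, "cv must be at least 2"),
            (0.0 <= self.mask_fraction and self.mask_fraction * self.n_folds <= 1.0 + 1e-9,
             "mask_fraction * n_folds must not exceed 1"),
            (self.n_folds >= 1, "n_folds must be at least 1"),
            (0 < self.module_size < self.n, "module_size must be in (0, n)"),
            (0.0 < self.p_out < self.p_in <= 1.0, "need 0 < p_out < p_in <= 1"),
            (0.0 <= self.hidden_fraction < 1.0, "hidden_fraction must be in [0, 1)"),
            (0.0 <= self.score_low < self.score_high <= 1.0,
             "scores must satisfy 0 <= low < high <= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat YAML document; unknown keys are rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["fractions"] = list(self.fractions)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def to_dict(self) -> dict:
        return asdict(self)
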