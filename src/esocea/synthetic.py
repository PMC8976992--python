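"""Synthetic parameter-set generation.

Every pipeline stage is testable without external input: the generator
draws structurally valid strategy parameter sets with the same shape as
the bundled base case — probabilities uniform within configurable
intervals (row-sum feasibility enforced by rejection), right-skewed
non-negative costs, utilities uniform within bounds.  Seeded runs are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import (
    ModelSettings,
    ParameterSet,
    StrategyParams,
    ValidationError,
    validate_params,
)

__all__ = ["GeneratorConfig", "sample_params", "sample_parameter_set", "perturb_fixture"]

#: Default sampling intervals, loosely spanning the bundled base-case
#: estimates across both stage groups.
DEFAULT_INTERVALS = {
    "p_complication_init": (0.03, 0.35),
    "p_death_init": (0.0, 0.111),
    "p_nr_to_lr": (0.003, 0.11),
    "p_nr_to_met": (0.002, 0.031),
    "p_nr_to_dead": (0.0, 0.13),
    "p_comp_to_dead": (0.0, 0.1),
    "p_lr_to_met": (0.1, 0.4),
    "p_lr_to_dead": (0.1, 0.3),
    "p_met_to_dead": (0.3, 0.7),
}

_MAX_REJECTIONS = 1000
_PROB_FIELDS_MUTABLE = (
    "p_complication_init",
    "p_death_init",
    "p_nr_to_lr",
    "p_nr_to_met",
    "p_nr_to_dead",
    "p_comp_to_dead",
    "p_lr_to_met",
    "p_lr_to_dead",
    "p_met_to_dead",
)


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_strategies: int = 3
    stage_group: str = "I"
    probability_intervals: dict = field(default_factory=lambda: dict(DEFAULT_INTERVALS))
    cost_scale: float = 3000.0
    utility_bounds: tuple[float, float] = (0.6, 0.9)

    def __post_init__(self) -> None:
        if self.n_strategies < 1:
            raise ValidationError("n_strategies must be at least 1")
        lo, hi = self.utility_bounds
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError("utility_bounds must satisfy 0 <= low <= high <= 1")
        if self.cost_scale < 0:
            raise ValidationError("cost_scale must be non-negative")
        for name, (a, b) in self.probability_intervals.items():
            if not (0.0 <= a <= b <= 1.0):
                raise ValidationError(f"interval for {name} must lie in [0, 1] with low <= high")


def _draw(rng: np.random.Generator, cfg: GeneratorConfig, name: str) -> StrategyParams:
    iv = cfg.probability_intervals
    for _ in range(_MAX_REJECTIONS):
        probs = {f: rng.uniform(*iv[f]) for f in _PROB_FIELDS_MUTABLE}
        if probs["p_complication_init"] + probs["p_death_init"] > 1.0:
            continue
        if probs["p_nr_to_lr"] + probs["p_nr_to_met"] + probs["p_nr_to_dead"] > 1.0:
            continue
        if probs["p_lr_to_met"] + probs["p_lr_to_dead"] > 1.0:
            continue
        u_lo, u_hi = cfg.utility_bounds
        u = rng.uniform(u_lo, u_hi)
        p = StrategyParams(
            name=name,
            stage_group=cfg.stage_group,
            cost_treatment=float(cfg.cost_scale * rng.lognormal(mean=0.0, sigma=0.5)),
            u_nr=u,
            u_comp=u,
            u_lr=u,
            u_met=float(rng.uniform(u_lo, u_hi)),
            **probs,
        )
        if not validate_params(p):
            return p
    raise ValidationError(
        f"could not sample a feasible parameter set for {name!r} in "
        f"{_MAX_REJECTIONS} attempts; intervals force a row sum above 1"
    )


def sample_params(cfg: GeneratorConfig) -> list[StrategyParams]:
    """Draw ``cfg.n_strategies`` valid strategy parameter sets."""
    rng = np.random.default_rng(cfg.seed)
    return [_draw(rng, cfg, f"synthetic_{i + 1}") for i in range(cfg.n_strategies)]


def sample_parameter_set(cfg: GeneratorConfig, settings: ModelSettings | None = None) -> ParameterSet:
    """Sampled strategies wrapped as a loadable/writable parameter set."""
    strategies = {p.name: p for p in sample_params(cfg)}
    return ParameterSet(cfg.stage_group, strategies, settings or ModelSettings())


def perturb_fixture(p: StrategyParams, relative_noise: float, seed: int) -> StrategyParams:
    """Multiply each probability by a factor in [1-noise, 1+noise].

    Results are clipped to [0, 1] and resampled (bounded retries) if a
    row-sum invariant is still violated.  Costs and utilities are left
    untouched.  Used by property tests as a validity-preserving probe.
    """
    if not 0.0 <= relative_noise < 1.0:
        raise ValidationError("relative_noise must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        factors = rng.uniform(1.0 - relative_noise, 1.0 + relative_noise, len(_PROB_FIELDS_MUTABLE))
        changes = {
            f: float(np.clip(getattr(p, f) * k, 0.0, 1.0))
            for f, k in zip(_PROB_FIELDS_MUTABLE, factors)
        }
        candidate = p.replace(**changes)
        if not validate_params(candidate):
            return candidate
    raise ValidationError(f"could not perturb {p.name!r} into a valid parameter set")
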