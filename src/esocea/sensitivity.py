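"""Deterministic sensitivity analysis.

One-way analysis reruns the full pipeline (cohort trace, outcome
accumulation, incremental analysis) with a single parameter set to its
low and high bound, everything else at base case, and reports the
preferred strategy at each endpoint.  When the endpoints disagree, the
switch value is located by bisection.  The two-way cost analysis sweeps
two strategies' one-time treatment costs over a grid and labels each
cell with the preferred strategy, locating the breakeven treatment cost
along each axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cea import ON_FRONTIER, incremental_analysis, preferred_strategy
from .engine import accumulate_outcomes, run_cohort, run_strategy
from .parameters import (
    ALL_STRATEGIES,
    ModelSettings,
    ParameterRange,
    ParameterSet,
    ValidationError,
    validate_params,
)

__all__ = ["OneWayResult", "CostGridResult", "one_way_sa", "cost_threshold_analysis"]

_BISECT_REL_TOL = 1e-6
_BISECT_MAX_ITER = 80


@dataclass(frozen=True)
class OneWayResult:
    """Outcome of varying one parameter over its low/high bounds."""

    strategy: str
    parameter: str
    value_low: float
    value_high: float
    preferred_low: str
    preferred_high: str
    icer_low: Optional[float]
    icer_high: Optional[float]
    switch_value: Optional[float]


@dataclass(frozen=True)
class CostGridResult:
    """Preferred-strategy labels over a two-strategy treatment-cost grid."""

    strategy_a: str
    strategy_b: str
    axis_a: np.ndarray
    axis_b: np.ndarray
    labels: np.ndarray  # shape (len(axis_a), len(axis_b)), dtype object
    boundary_a: Optional[float]
    boundary_b: Optional[float]


def _with_value(base: ParameterSet, r: ParameterRange, value: float) -> ParameterSet:
    """Parameter set with one range's parameter set to ``value``."""
    ps = base
    targets = (
        list(base.strategies) if r.strategy == ALL_STRATEGIES else [r.strategy]
    )
    for name in targets:
        if name not in base.strategies:
            raise ValidationError(f"range refers to unknown strategy {name!r}")
        p = ps.strategies[name]
        p = p.replace(**{f: value for f in r.target_fields()})
        violations = validate_params(p)
        if violations:
            raise ValidationError("; ".join(violations))
        ps = ps.replace_strategy(p)
    return ps


def _evaluate(ps: ParameterSet, s: ModelSettings, r: ParameterRange, value: float):
    """Preferred strategy and the varied strategy's ICER at one value."""
    varied = _with_value(ps, r, value)
    outcomes = [run_strategy(p, s) for p in varied]
    preferred = preferred_strategy(outcomes, s)
    results = {res.strategy: res for res in incremental_analysis(outcomes, s)}
    probe = preferred if r.strategy == ALL_STRATEGIES else r.strategy
    icer = results[probe].icer_per_qaly if probe in results else None
    return preferred, icer


def one_way_sa(
    base: ParameterSet, ranges: Sequence[ParameterRange], s: Optional[ModelSettings] = None
) -> list[OneWayResult]:
    """One-way deterministic sensitivity analysis over a set of ranges.

    Ranges for other stage groups are ignored, so the full bundled
    ranges document can be passed against either stage-group base case.
    """
    s = s or base.settings
    results = []
    for r in ranges:
        if r.stage_group != base.stage_group:
            continue
        preferred_low, icer_low = _evaluate(base, s, r, r.low)
        preferred_high, icer_high = _evaluate(base, s, r, r.high)
        switch = None
        if preferred_low != preferred_high:
            switch = _bisect_switch(base, s, r, preferred_low)
        results.append(
            OneWayResult(
                strategy=r.strategy,
                parameter=r.parameter,
                value_low=r.low,
                value_high=r.high,
                preferred_low=preferred_low,
                preferred_high=preferred_high,
                icer_low=icer_low,
                icer_high=icer_high,
                switch_value=switch,
            )
        )
    return results


def _bisect_switch(
    base: ParameterSet, s: ModelSettings, r: ParameterRange, preferred_low: str
) -> float:
    """Parameter value at which the preferred strategy first changes."""
    lo, hi = r.low, r.high
    for _ in range(_BISECT_MAX_ITER):
        mid = 0.5 * (lo + hi)
        if hi - lo <= _BISECT_REL_TOL * max(abs(mid), 1e-12):
            break
        preferred_mid, _ = _evaluate(base, s, r, mid)
        if preferred_mid == preferred_low:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def cost_threshold_analysis(
    base: ParameterSet,
    varied: tuple[str, str],
    cost_grid: tuple[Sequence[float], Sequence[float]],
    s: Optional[ModelSettings] = None,
) -> CostGridResult:
    """Two-way sweep of two strategies' one-time treatment costs.

    Traces do not depend on costs, so they are computed once and only
    the reward accumulation is repeated per grid cell.  The breakeven
    along each axis (other strategy's cost at base case) is the cost at
    which the axis strategy first becomes preferred, refined by
    bisection between the bracketing cells; ``None`` when the strategy
    is never preferred on its axis.
    """
    s = s or base.settings
    name_a, name_b = varied
    for name in varied:
        if name not in base.strategies:
            raise ValidationError(f"varied strategy {name!r} absent from parameter set")
    axis_a = np.asarray(cost_grid[0], dtype=float)
    axis_b = np.asarray(cost_grid[1], dtype=float)
    for label, axis in (("a", axis_a), ("b", axis_b)):
        if (axis < 0).any():
            raise ValidationError(f"cost grid axis {label} must be non-negative")
        if len(axis) > 1 and (np.diff(axis) <= 0).any():
            raise ValidationError(f"cost grid axis {label} must be strictly increasing")

    traces = {p.name: run_cohort(p, s) for p in base}

    def outcomes_at(cost_a: float, cost_b: float):
        outs = []
        for p in base:
            if p.name == name_a:
                p = p.replace(cost_treatment=cost_a)
            elif p.name == name_b:
                p = p.replace(cost_treatment=cost_b)
            outs.append(accumulate_outcomes(traces[p.name], p, s))
        return outs

    labels = np.empty((len(axis_a), len(axis_b)), dtype=object)
    for i, ca in enumerate(axis_a):
        for j, cb in enumerate(axis_b):
            labels[i, j] = preferred_strategy(outcomes_at(ca, cb), s)

    base_a = base.strategies[name_a].cost_treatment
    base_b = base.strategies[name_b].cost_treatment

    def breakeven(axis, name, prefers):
        """Largest cost at which ``name`` is preferred along its axis."""
        wins = [prefers(c) == name for c in axis]
        if not any(wins):
            return None
        if all(wins):
            return float(axis[-1])
        # strategies get less attractive as their cost rises: find the
        # win/lose bracket and bisect inside it
        k = max(i for i, w in enumerate(wins) if w)
        if k == len(axis) - 1:
            return float(axis[-1])
        lo, hi = float(axis[k]), float(axis[k + 1])
        for _ in range(_BISECT_MAX_ITER):
            mid = 0.5 * (lo + hi)
            if hi - lo <= _BISECT_REL_TOL * max(abs(mid), 1.0):
                break
            if prefers(mid) == name:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    boundary_a = breakeven(
        axis_a, name_a, lambda c: preferred_strategy(outcomes_at(c, base_b), s)
    )
    boundary_b = breakeven(
        axis_b, name_b, lambda c: preferred_strategy(outcomes_at(base_a, c), s)
    )
    return CostGridResult(
        strategy_a=name_a,
        strategy_b=name_b,
        axis_a=axis_a,
        axis_b=axis_b,
        labels=labels,
        boundary_a=boundary_a,
        boundary_b=boundary_b,
    )
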