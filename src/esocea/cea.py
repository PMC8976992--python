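"""Incremental cost-effectiveness analysis.

Strategies within a stage group are compared on discounted cost and
discounted QALYs: strongly dominated strategies (another strategy costs
no more and yields no less effect, one inequality strict) are removed
first, then extended dominance prunes frontier candidates whose
incremental cost-effectiveness ratio (ICER) exceeds that of a more
effective alternative.  ICERs are computed between adjacent members of
the resulting efficiency frontier and classified against the 1x / 3x
GDP-per-capita willingness-to-pay thresholds.

The module also provides the downstream-cost calibration: published
total lifetime costs exceed one-time treatment costs because they
include diagnosis, follow-up and terminal care.  Total cost is affine in
a uniform alive-state per-cycle cost ``c``, so the ``c`` reproducing a
given total is a closed-form linear solve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .engine import StrategyOutcome, _reward_weights, run_cohort, run_strategy
from .parameters import ModelSettings, ParameterSet, StrategyParams, ValidationError

__all__ = [
    "IncrementalResult",
    "incremental_analysis",
    "classify_cost_effectiveness",
    "fit_downstream_costs",
    "calibrate_parameter_set",
    "preferred_strategy",
]

# status values
REFERENCE = "reference"
ON_FRONTIER = "on_frontier"
STRONGLY_DOMINATED = "strongly_dominated"
EXTENDED_DOMINATED = "extended_dominated"

# classification values
COST_EFFECTIVE_1X = "cost_effective_1x"
COST_EFFECTIVE_3X = "cost_effective_3x"
NOT_COST_EFFECTIVE = "not_cost_effective"
DOMINANT = "dominant"
DOMINATED = "dominated"


@dataclass(frozen=True)
class IncrementalResult:
    """One strategy's position in the incremental analysis.

    ``comparator`` is the adjacent cheaper frontier member (or the
    dominating strategy for strongly dominated entries; ``None`` for the
    reference).  An undefined ICER (zero effect difference) is carried
    as ``None``, never as a sentinel number.
    """

    strategy: str
    comparator: Optional[str]
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer_per_qaly: Optional[float]
    icer_per_ly: Optional[float]
    status: str
    classification: str


def _ratio(dc: float, de: float) -> Optional[float]:
    return None if de == 0 else dc / de


def classify_cost_effectiveness(icer_per_qaly: float, s: ModelSettings) -> str:
    """Classify an ICER against the willingness-to-pay thresholds.

    Bounds are inclusive; a negative ICER (cost saving with a QALY gain)
    is ``dominant``.
    """
    if icer_per_qaly < 0:
        return DOMINANT
    if icer_per_qaly <= s.wtp_low:
        return COST_EFFECTIVE_1X
    if icer_per_qaly <= s.wtp_high:
        return COST_EFFECTIVE_3X
    return NOT_COST_EFFECTIVE


def incremental_analysis(
    outcomes: Sequence[StrategyOutcome], s: ModelSettings
) -> list[IncrementalResult]:
    """Full dominance / frontier / ICER analysis of competing strategies.

    Returns one :class:`IncrementalResult` per input strategy, frontier
    members sorted by increasing QALY first, dominated strategies after.
    """
    if len(outcomes) < 2:
        raise ValidationError("incremental analysis needs at least two strategies")
    names = [o.strategy for o in outcomes]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate strategy names in {names}")

    def dominates(a: StrategyOutcome, b: StrategyOutcome) -> bool:
        return (
            a.total_cost_disc <= b.total_cost_disc
            and a.qaly_disc >= b.qaly_disc
            and (a.total_cost_disc < b.total_cost_disc or a.qaly_disc > b.qaly_disc)
        )

    strong: dict[str, StrategyOutcome] = {}
    for o in outcomes:
        for other in outcomes:
            if other is not o and dominates(other, o):
                strong[o.strategy] = other
                break

    candidates = sorted(
        (o for o in outcomes if o.strategy not in strong),
        key=lambda o: (o.qaly_disc, o.total_cost_disc, o.strategy),
    )

    # extended dominance: drop members whose ICER vs the previous frontier
    # member exceeds the ICER of the next member vs themselves, until the
    # frontier ICER sequence is non-decreasing
    extended: set[str] = set()
    frontier = list(candidates)
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            lo, mid, hi = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_mid = _ratio(mid.total_cost_disc - lo.total_cost_disc, mid.qaly_disc - lo.qaly_disc)
            icer_hi = _ratio(hi.total_cost_disc - mid.total_cost_disc, hi.qaly_disc - mid.qaly_disc)
            if icer_mid is not None and icer_hi is not None and icer_mid >= icer_hi:
                extended.add(mid.strategy)
                frontier.pop(i)
                changed = True
                break

    by_name = {o.strategy: o for o in outcomes}
    results: list[IncrementalResult] = []
    all_others_strongly_dominated = len(strong) == len(outcomes) - 1

    for i, o in enumerate(frontier):
        if i == 0:
            classification = DOMINANT if all_others_strongly_dominated else COST_EFFECTIVE_1X
            results.append(
                IncrementalResult(o.strategy, None, 0.0, 0.0, 0.0, None, None, REFERENCE, classification)
            )
            continue
        prev = frontier[i - 1]
        dc = o.total_cost_disc - prev.total_cost_disc
        dq = o.qaly_disc - prev.qaly_disc
        dl = o.ly_disc - prev.ly_disc
        icer_q = _ratio(dc, dq)
        icer_l = _ratio(dc, dl)
        classification = (
            classify_cost_effectiveness(icer_q, s) if icer_q is not None else NOT_COST_EFFECTIVE
        )
        results.append(
            IncrementalResult(o.strategy, prev.strategy, dc, dq, dl, icer_q, icer_l, ON_FRONTIER, classification)
        )

    for o in outcomes:
        if o.strategy in strong:
            ref = strong[o.strategy]
            results.append(
                IncrementalResult(
                    o.strategy,
                    ref.strategy,
                    o.total_cost_disc - ref.total_cost_disc,
                    o.qaly_disc - ref.qaly_disc,
                    o.ly_disc - ref.ly_disc,
                    None,
                    None,
                    STRONGLY_DOMINATED,
                    DOMINATED,
                )
            )
        elif o.strategy in extended:
            nxt = next(f for f in frontier if f.qaly_disc >= o.qaly_disc)
            results.append(
                IncrementalResult(
                    o.strategy,
                    nxt.strategy,
                    o.total_cost_disc - nxt.total_cost_disc,
                    o.qaly_disc - nxt.qaly_disc,
                    o.ly_disc - nxt.ly_disc,
                    None,
                    None,
                    EXTENDED_DOMINATED,
                    DOMINATED,
                )
            )
    frontier_names = [f.strategy for f in frontier]
    icers = [r.icer_per_qaly for r in results if r.status == ON_FRONTIER]
    if any(
        a is not None and b is not None and b <= a for a, b in zip(icers, icers[1:])
    ):
        raise AssertionError(f"frontier ICERs not strictly increasing along {frontier_names}")
    return results


def preferred_strategy(outcomes: Sequence[StrategyOutcome], s: ModelSettings) -> str:
    """Preferred strategy at the lower willingness-to-pay threshold.

    Rule: walk the efficiency frontier in order of increasing QALY,
    accepting each member whose ICER against the previous accepted member
    is at most ``wtp_low``; the preferred strategy is the most effective
    accepted member (the cheapest frontier member when none qualifies).
    """
    results = incremental_analysis(outcomes, s)
    preferred = results[0].strategy
    for r in results:
        if r.status == ON_FRONTIER and r.icer_per_qaly is not None and r.icer_per_qaly <= s.wtp_low:
            preferred = r.strategy
        elif r.status == ON_FRONTIER:
            break
    return preferred


def fit_downstream_costs(
    p: StrategyParams, s: ModelSettings, target_total_cost_disc: float
) -> float:
    """Uniform alive-state per-cycle cost reproducing a target total cost.

    Solves ``fixed + c * sum_t df(t) * alive(t) = target`` where ``fixed``
    is the strategy's total discounted cost with all per-cycle costs
    zeroed (treatment plus any terminal-care cost).
    """
    zeroed = p.replace(cost_cycle_nr=0.0, cost_cycle_lr=0.0, cost_cycle_met=0.0, cost_cycle_comp=0.0)
    fixed = run_strategy(zeroed, s).total_cost_disc
    if target_total_cost_disc < fixed - 1e-9:
        raise ValidationError(
            f"{p.name}: target total {target_total_cost_disc} below initial cost {fixed}"
        )
    trace = run_cohort(p, s)
    weights, df = _reward_weights(trace, s)
    alive_discounted = float(df @ weights[:, :4].sum(axis=1))
    if alive_discounted == 0:
        raise ValidationError(f"{p.name}: cohort accrues no alive time; cannot calibrate")
    c = (target_total_cost_disc - fixed) / alive_discounted
    return max(c, 0.0)


def calibrate_parameter_set(ps: ParameterSet, totals: dict[str, float]) -> ParameterSet:
    """Apply :func:`fit_downstream_costs` to every strategy of a set.

    ``totals`` maps strategy name to target discounted total cost; the
    fitted per-cycle cost is written to all four alive-state cost fields.
    """
    out = ps
    for name, p in ps.strategies.items():
        if name not in totals:
            raise ValidationError(f"no calibration total for strategy {name!r}")
        c = fit_downstream_costs(p, ps.settings, totals[name])
        out = out.replace_strategy(
            p.replace(cost_cycle_nr=c, cost_cycle_lr=c, cost_cycle_met=c, cost_cycle_comp=c)
        )
    return out


def round_icer(icer: Optional[float]) -> Optional[float]:
    """Presentation rounding: one decimal (comparisons use unrounded values)."""
    return None if icer is None else math.floor(icer * 10 + 0.5) / 10
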