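"""Deterministic Markov cohort engine.

A cohort of patients is distributed over five health states —
no-recurrence, local recurrence, metastasis, complication, dead — and
redistributed every 6-month cycle by a row-stochastic transition matrix
built from the strategy's per-cycle probabilities.  The trace of
state-occupancy fractions is then folded into discounted and undiscounted
totals: cost per patient, life-years and quality-adjusted life-years.

Model structure
---------------
* The complication state is transient: occupants leave after one cycle,
  to no-recurrence with probability ``1 - p_comp_to_dead`` and to dead
  otherwise.  This captures a treatment episode's morbidity without
  inventing long-run complication dynamics.
* The no-recurrence state feeds local recurrence, metastasis and dead;
  the residual is the stay probability.
* Local recurrence progresses to metastasis or dies; metastasis dies;
  dead is absorbing.  The per-cycle probabilities for these downstream
  states are structural defaults (see ``parameters.STRUCTURAL_DEFAULTS``),
  not published estimates, and are overridable per strategy.
* Rewards (costs, life-years, QALYs) accrue at cycle start on the
  occupancy entering the cycle; an optional half-cycle correction
  averages adjacent occupancies and discounts at mid-cycle instead.
* The one-time treatment cost falls at cycle 0 undiscounted; a terminal
  care cost, when configured, attaches to each cycle's new entrants to
  the dead state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import STATES, ModelSettings, StrategyParams, ValidationError

__all__ = [
    "TransitionMatrix",
    "CohortTrace",
    "StrategyOutcome",
    "initial_distribution",
    "build_transition_matrix",
    "discount_factor",
    "run_cohort",
    "accumulate_outcomes",
    "run_strategy",
    "prob_to_rate",
    "rate_to_prob",
]

_NR, _LR, _MET, _COMP, _DEAD = range(5)

_ROW_SUM_TOL = 1e-12
_TRACE_ROW_TOL = 1e-10


@dataclass(frozen=True)
class TransitionMatrix:
    """A 5x5 per-cycle transition probability matrix (row-stochastic)."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=float)
        if m.shape != (5, 5):
            raise ValidationError(f"transition matrix must be 5x5, got {m.shape}")
        if (m < -_ROW_SUM_TOL).any() or (m > 1 + _ROW_SUM_TOL).any():
            raise ValidationError("transition probabilities must lie in [0, 1]")
        rowsums = m.sum(axis=1)
        if np.abs(rowsums - 1.0).max() > _ROW_SUM_TOL:
            raise ValidationError(f"rows must sum to 1; sums = {rowsums}")
        if not np.array_equal(m[_DEAD], np.eye(5)[_DEAD]):
            raise ValidationError("dead must be absorbing")
        object.__setattr__(self, "entries", m)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.entries, dtype=dtype)


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy fractions at each cycle boundary.

    ``occupancy`` has shape (n_cycles + 1, 5); row ``t`` is the cohort
    distribution entering cycle ``t``.
    """

    occupancy: np.ndarray
    cycle_length_years: float

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != 5:
            raise ValidationError(f"trace must have 5 state columns, got shape {occ.shape}")
        if np.abs(occ.sum(axis=1) - 1.0).max() > _TRACE_ROW_TOL:
            raise ValidationError("trace rows must each sum to 1")
        if (np.diff(occ[:, _DEAD]) < -_TRACE_ROW_TOL).any():
            raise ValidationError("dead occupancy must be non-decreasing")
        object.__setattr__(self, "occupancy", occ)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def dead_fraction_end(self) -> float:
        return float(self.occupancy[-1, _DEAD])

    def alive_fraction(self) -> np.ndarray:
        """Alive fraction at each cycle boundary (1 - dead occupancy)."""
        return 1.0 - self.occupancy[:, _DEAD]


@dataclass(frozen=True)
class StrategyOutcome:
    """Per-patient totals for one strategy over the model horizon."""

    strategy: str
    total_cost_disc: float
    total_cost_undisc: float
    ly_disc: float
    ly_undisc: float
    qaly_disc: float
    qaly_undisc: float
    dead_fraction_end: float


def initial_distribution(p: StrategyParams) -> np.ndarray:
    """Cohort distribution at model entry.

    The treatment episode immediately sends ``p_death_init`` of patients
    to dead (perioperative/treatment death) and ``p_complication_init``
    to the complication state; everyone else starts in no-recurrence.
    Local recurrence and metastasis start empty.
    """
    if p.p_complication_init + p.p_death_init > 1.0:
        raise ValidationError(
            f"{p.name}: initial complication + death probability exceeds 1"
        )
    dist = np.zeros(5)
    dist[_COMP] = p.p_complication_init
    dist[_DEAD] = p.p_death_init
    dist[_NR] = 1.0 - p.p_complication_init - p.p_death_init
    return dist


def build_transition_matrix(p: StrategyParams) -> TransitionMatrix:
    """Assemble the per-cycle transition matrix for one strategy."""
    for label, total in (
        ("no-recurrence", p.p_nr_to_lr + p.p_nr_to_met + p.p_nr_to_dead),
        ("local-recurrence", p.p_lr_to_met + p.p_lr_to_dead),
        ("metastasis", p.p_met_to_dead),
        ("complication", p.p_comp_to_dead),
    ):
        if total > 1.0 + _ROW_SUM_TOL:
            raise ValidationError(f"{p.name}: {label} exit probabilities sum to {total} > 1")
    m = np.zeros((5, 5))
    m[_NR] = (
        1.0 - p.p_nr_to_lr - p.p_nr_to_met - p.p_nr_to_dead,
        p.p_nr_to_lr,
        p.p_nr_to_met,
        0.0,
        p.p_nr_to_dead,
    )
    m[_LR] = (0.0, 1.0 - p.p_lr_to_met - p.p_lr_to_dead, p.p_lr_to_met, 0.0, p.p_lr_to_dead)
    m[_MET] = (0.0, 0.0, 1.0 - p.p_met_to_dead, 0.0, p.p_met_to_dead)
    # transient complication: back to no-recurrence unless fatal
    m[_COMP] = (1.0 - p.p_comp_to_dead, 0.0, 0.0, 0.0, p.p_comp_to_dead)
    m[_DEAD, _DEAD] = 1.0
    return TransitionMatrix(m)


def discount_factor(cycle_index, s: ModelSettings):
    """Discount factor at a cycle boundary: (1+r)^(-t * cycle_length).

    Accepts a scalar or an array of cycle indices.
    """
    idx = np.asarray(cycle_index, dtype=float)
    if (idx < 0).any():
        raise ValueError("cycle_index must be non-negative")
    out = (1.0 + s.annual_discount_rate) ** (-idx * s.cycle_length_years)
    return float(out) if np.isscalar(cycle_index) or idx.ndim == 0 else out


def run_cohort(p: StrategyParams, s: ModelSettings) -> CohortTrace:
    """Propagate the cohort through ``s.n_cycles`` transitions."""
    matrix = build_transition_matrix(p).entries
    n = s.n_cycles
    occ = np.empty((n + 1, 5))
    occ[0] = initial_distribution(p)
    for t in range(n):
        occ[t + 1] = occ[t] @ matrix
    return CohortTrace(occupancy=occ, cycle_length_years=s.cycle_length_years)


def _reward_weights(trace: CohortTrace, s: ModelSettings):
    """Per-cycle occupancy used for reward accrual and its discount factors.

    Default: occupancy entering each cycle, discounted at the cycle-start
    boundary.  With half-cycle correction: the mean of the occupancies at
    the two boundaries, discounted at mid-cycle.
    """
    occ = trace.occupancy
    t = np.arange(trace.n_cycles)
    if s.half_cycle_correction:
        weights = 0.5 * (occ[:-1] + occ[1:])
        df = discount_factor(t + 0.5, s)
    else:
        weights = occ[:-1]
        df = discount_factor(t, s)
    return weights, df


def accumulate_outcomes(trace: CohortTrace, p: StrategyParams, s: ModelSettings) -> StrategyOutcome:
    """Fold a cohort trace into discounted/undiscounted totals per patient."""
    if trace.occupancy.shape[1] != 5:
        raise ValidationError("trace state count does not match the five-state model")
    if trace.n_cycles != s.n_cycles:
        raise ValidationError(
            f"trace has {trace.n_cycles} cycles but settings specify {s.n_cycles}"
        )
    weights, df = _reward_weights(trace, s)
    ones = np.ones_like(df)

    cycle_costs = np.array(
        [p.cost_cycle_nr, p.cost_cycle_lr, p.cost_cycle_met, p.cost_cycle_comp, 0.0]
    )
    utilities = np.array([p.u_nr, p.u_lr, p.u_met, p.u_comp, 0.0])
    alive = weights[:, [_NR, _LR, _MET, _COMP]].sum(axis=1)
    cost_per_cycle = weights @ cycle_costs
    qaly_per_cycle = weights @ utilities

    # new entrants to dead: perioperative deaths at t=0, then per-cycle deltas
    dead = trace.occupancy[:, _DEAD]
    entrant_cost = dead[0] * p.cost_terminal
    entrants = np.diff(dead)
    df_entry = discount_factor(np.arange(1, trace.n_cycles + 1), s)

    def total_cost(factors, entry_factors):
        return (
            p.cost_treatment
            + float(factors @ cost_per_cycle)
            + entrant_cost
            + float(entry_factors @ entrants) * p.cost_terminal
        )

    cl = trace.cycle_length_years
    return StrategyOutcome(
        strategy=p.name,
        total_cost_disc=total_cost(df, df_entry),
        total_cost_undisc=total_cost(ones, np.ones_like(df_entry)),
        ly_disc=float(df @ alive) * cl,
        ly_undisc=float(alive.sum()) * cl,
        qaly_disc=float(df @ qaly_per_cycle) * cl,
        qaly_undisc=float(qaly_per_cycle.sum()) * cl,
        dead_fraction_end=trace.dead_fraction_end,
    )


def run_strategy(p: StrategyParams, s: ModelSettings) -> StrategyOutcome:
    """Convenience: trace plus accumulation in one call."""
    return accumulate_outcomes(run_cohort(p, s), p, s)


def prob_to_rate(p: float, t: float) -> float:
    """Convert a probability over duration ``t`` to an instantaneous rate.

    Provided for sensitivity explorations; the base-case inputs are used
    directly as per-cycle probabilities without conversion.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError("probability must lie in [0, 1)")
    return -np.log1p(-p) / t


def rate_to_prob(r: float, t: float) -> float:
    """Convert an instantaneous rate to a probability over duration ``t``."""
    if r < 0:
        raise ValueError("rate must be non-negative")
    return float(-np.expm1(-r * t))
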