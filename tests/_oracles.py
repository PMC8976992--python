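"""Independent oracles used by the test suite.

Both are deliberately written without reference to the package's cohort
engine or frontier algorithm:

* ``microsim`` samples individual patient state paths (Monte Carlo
  microsimulation) and estimates state occupancies and undiscounted
  life-years from them; the transition rows are re-derived inline from
  the parameter fields.
* ``brute_force_frontier`` identifies the efficiency frontier by
  exhaustive pairwise mixture enumeration: a strategy is off the
  frontier iff some other strategy, or some convex combination of two
  other strategies, attains at least its QALY at strictly lower cost
  (or more QALY at no more cost).
"""

from itertools import combinations

import numpy as np


def microsim(p, s, n_patients, seed):
    """Monte Carlo microsimulation of one strategy.

    Returns (occupancy, ly_undisc_mean, ly_undisc_se) where occupancy has
    shape (n_cycles+1, 5) in state order (no_recurrence, local_recurrence,
    metastasis, complication, dead).
    """
    rng = np.random.default_rng(seed)
    n_cycles = int(round(s.horizon_years / s.cycle_length_years))

    # transition rows, re-derived from the parameter fields
    m = np.zeros((5, 5))
    m[0] = [1 - p.p_nr_to_lr - p.p_nr_to_met - p.p_nr_to_dead,
            p.p_nr_to_lr, p.p_nr_to_met, 0.0, p.p_nr_to_dead]
    m[1] = [0.0, 1 - p.p_lr_to_met - p.p_lr_to_dead, p.p_lr_to_met, 0.0, p.p_lr_to_dead]
    m[2] = [0.0, 0.0, 1 - p.p_met_to_dead, 0.0, p.p_met_to_dead]
    m[3] = [1 - p.p_comp_to_dead, 0.0, 0.0, 0.0, p.p_comp_to_dead]
    m[4] = [0.0, 0.0, 0.0, 0.0, 1.0]
    cum = np.cumsum(m, axis=1)

    init = np.array([1 - p.p_complication_init - p.p_death_init,
                     0.0, 0.0, p.p_complication_init, p.p_death_init])
    states = np.searchsorted(np.cumsum(init), rng.random(n_patients), side="right")

    occupancy = np.empty((n_cycles + 1, 5))
    cycles_alive = np.zeros(n_patients)
    for t in range(n_cycles + 1):
        occupancy[t] = np.bincount(states, minlength=5) / n_patients
        if t == n_cycles:
            break
        cycles_alive += states != 4
        u = rng.random(n_patients)
        states = (u[:, None] > cum[states]).sum(axis=1)

    ly = cycles_alive * s.cycle_length_years
    return occupancy, float(ly.mean()), float(ly.std(ddof=1) / np.sqrt(n_patients))


def brute_force_frontier(points):
    """Frontier strategy names from [(name, cost, qaly), ...] by enumeration."""
    frontier = []
    for name, c, q in points:
        dominated = False
        for name2, c2, q2 in points:
            if name2 != name and c2 <= c and q2 >= q and (c2 < c or q2 > q):
                dominated = True
                break
        if not dominated:
            others = [pt for pt in points if pt[0] != name]
            for (_, c1, q1), (_, c2, q2) in combinations(others, 2):
                if q1 > q2:
                    (c1, q1), (c2, q2) = (c2, q2), (c1, q1)
                if q1 <= q <= q2 and q2 > q1:
                    mix_cost = c1 + (c2 - c1) * (q - q1) / (q2 - q1)
                    if mix_cost < c - 1e-12:
                        dominated = True
                        break
        if not dominated:
            frontier.append(name)
    return set(frontier)
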