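"""Two-stage cohort simulation: year-1 decision tree, then an annual Markov chain.

The decision tree deposits the whole cohort into the five diabetes states
at the end of year 1 according to each strategy arm's outcome
probabilities; the surgery arm additionally incurs the one-time surgery
fee at entry.  From year 2 onward an annual-cycle Markov chain with a
row-stochastic transition matrix moves probability mass between states up
to the time horizon.

Accounting conventions (end-of-cycle accrual):

* cycle ``t`` runs over ``1..T``; the cycle-1 occupancy is the decision
  tree's output,
* costs and effects accrued in cycle ``t`` are discounted by
  ``(1 + r) ** -t`` — the year-1 outputs, including the surgery fee, are
  discounted at exponent 1,
* no half-cycle correction by default; when enabled, cycles 2..T accrue on
  the mean of the cycle's start and end occupancy.

The simulation is a deterministic expected-value cohort trace; no random
numbers are involved.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .config_io import ModelConfig, validate_transition_matrix
from .states import ALIVE, STATE_NAMES, validate_occupancy


def discount_factor(t: int | np.ndarray, r: float) -> float | np.ndarray:
    """Discount factor ``(1 + r) ** -t`` for cycle ``t`` at annual rate ``r``."""
    t = np.asarray(t)
    if (t < 0).any():
        raise ValueError("cycle index must be >= 0")
    if r < 0:
        raise ValueError("discount rate must be >= 0")
    out = (1.0 + r) ** (-t.astype(float))
    return float(out) if out.ndim == 0 else out


def decision_tree_year1(config: ModelConfig, arm: str) -> tuple[np.ndarray, float]:
    """Year-1 state distribution and undiscounted year-1 cost for one arm.

    The cost is the arm's one-time entry cost (surgery fee, if any) plus
    the expected state annual costs under the year-1 distribution.
    """
    if arm not in config.arm_probabilities:
        raise KeyError(f"unknown strategy arm '{arm}' (have {list(config.arms)})")
    occupancy = validate_occupancy(config.arm_probabilities[arm])
    cost = config.entry_costs.get(arm, 0.0) + float(occupancy @ config.state_costs)
    return occupancy, cost


@dataclasses.dataclass
class MarkovTrace:
    """Per-cycle occupancy and discounted accruals for one strategy arm.

    Arrays are indexed by cycle 1..T (``cycles[i]`` labels row ``i``).
    ``cost``, ``life_years`` and ``qalys`` are per-cycle *discounted*
    accruals; ``cum_*`` are their running totals.
    """

    arm: str
    cycles: np.ndarray
    occupancy: np.ndarray
    cost: np.ndarray
    life_years: np.ndarray
    qalys: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.cost.sum())

    @property
    def total_life_years(self) -> float:
        return float(self.life_years.sum())

    @property
    def total_qalys(self) -> float:
        return float(self.qalys.sum())

    @property
    def cum_cost(self) -> np.ndarray:
        return np.cumsum(self.cost)

    @property
    def cum_life_years(self) -> np.ndarray:
        return np.cumsum(self.life_years)

    @property
    def cum_qalys(self) -> np.ndarray:
        return np.cumsum(self.qalys)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.occupancy, columns=list(STATE_NAMES))
        frame.insert(0, "cycle", self.cycles)
        frame["discounted_cost"] = self.cost
        frame["discounted_life_years"] = self.life_years
        frame["discounted_qalys"] = self.qalys
        frame["cum_discounted_cost"] = self.cum_cost
        frame["cum_discounted_life_years"] = self.cum_life_years
        frame["cum_discounted_qalys"] = self.cum_qalys
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_markov(
    config: ModelConfig, arm: str, initial: np.ndarray | None = None
) -> MarkovTrace:
    """Simulate one strategy arm from year 1 to the horizon.

    ``initial`` overrides the decision tree's year-1 distribution (the
    entry cost is then omitted, since the cohort did not pass through the
    arm's entry node).
    """
    matrix = validate_transition_matrix(
        config.transition_matrices[arm], where=f"annual_transition.{arm}"
    )
    if initial is None:
        occupancy_1, year1_cost = decision_tree_year1(config, arm)
    else:
        occupancy_1 = validate_occupancy(initial)
        year1_cost = float(occupancy_1 @ config.state_costs)

    T = config.horizon_years
    occupancy = np.empty((T, len(STATE_NAMES)))
    occupancy[0] = occupancy_1
    for i in range(1, T):
        occupancy[i] = occupancy[i - 1] @ matrix

    accrual = occupancy
    if config.half_cycle_correction and T > 1:
        accrual = occupancy.copy()
        accrual[1:] = 0.5 * (occupancy[:-1] + occupancy[1:])

    cycles = np.arange(1, T + 1)
    cost_df = discount_factor(cycles, config.discount_rate)
    effect_df = discount_factor(cycles, config.effect_discount_rate)

    undiscounted_cost = accrual @ config.state_costs
    undiscounted_cost[0] = year1_cost  # includes the one-time entry cost
    return MarkovTrace(
        arm=arm,
        cycles=cycles,
        occupancy=occupancy,
        cost=undiscounted_cost * cost_df,
        life_years=(accrual @ ALIVE.astype(float)) * effect_df,
        qalys=(accrual @ config.utilities) * effect_df,
    )
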