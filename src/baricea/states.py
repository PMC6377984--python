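"""The five diabetes outcome states shared by every stage of the model.

State ordering is fixed package-wide: every probability vector, utility
vector, cost vector and transition matrix is indexed (remission, improved,
persistent, uncontrolled, dead).  DEAD is absorbing in the Markov engine
and carries zero utility and zero annual cost.
"""

from __future__ import annotations

import enum

import numpy as np


class DiabetesState(enum.IntEnum):
    """One-year diabetes outcome, following the ADA-derived definitions.

    REMISSION     HbA1C < 6.5 % off all glucose-lowering agents
    IMPROVED      HbA1C < 6.5 % on metformin monotherapy
    PERSISTENT    on metformin plus one other antidiabetic class
    UNCONTROLLED  on more than two antidiabetic classes
    DEAD          deceased (absorbing)
    """

    REMISSION = 0
    IMPROVED = 1
    PERSISTENT = 2
    UNCONTROLLED = 3
    DEAD = 4


#: canonical lower-case state names, in index order
STATE_NAMES: tuple[str, ...] = tuple(s.name.lower() for s in DiabetesState)

N_STATES = len(STATE_NAMES)

#: mask selecting the alive states
ALIVE = np.array([True, True, True, True, False])


def validate_occupancy(vector: np.ndarray, *, tol: float = 1e-9) -> np.ndarray:
    """Check that ``vector`` is a valid state-occupancy distribution.

    Returns the vector as a float array; raises ``ValueError`` if it has
    the wrong length, a negative entry, or does not sum to 1 within ``tol``.
    """
    v = np.asarray(vector, dtype=float)
    if v.shape != (N_STATES,):
        raise ValueError(f"occupancy vector must have length {N_STATES}, got shape {v.shape}")
    if (v < 0).any():
        raise ValueError("occupancy vector has negative mass")
    if abs(v.sum() - 1.0) > tol:
        raise ValueError(f"occupancy vector sums to {v.sum():.12f}, not 1 within {tol}")
    return v
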