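"""Read, validate and write model configurations.

The configuration file is a single JSON document holding every numeric
parameter of the cost-utility model: the two strategy arms' year-1 outcome
probabilities, the years-2+ annual transition dynamics, healthcare costs
(THB), state utilities, the discount rate, the time horizon and the
willingness-to-pay band.  All monetary amounts are Thai baht (THB) as plain
decimals; probabilities and utilities are decimals in [0, 1], never
percentages.

State-level annual costs are *composed* at load time from the drug-price
table so the Markov engine sees a flat per-state cost vector:

* remission      — vitamin/calcium supplementation only (the one-time
                   surgery fee is charged separately at model entry),
* improved       — metformin monotherapy,
* persistent     — metformin plus one configurable second agent,
* uncontrolled   — a configurable multi-drug regimen plus annual
                   complication management,
* dead           — zero.

Year-1 outcome vectors whose printed values do not sum exactly to 1 (the
surgery arm's published vector sums to 1.0100) are renormalized when the
discrepancy is within ``PROBABILITY_SUM_TOL`` of 1, with a logged warning;
larger discrepancies are rejected.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .states import DiabetesState, N_STATES, STATE_NAMES

logger = logging.getLogger(__name__)

#: arm vectors within this distance of summing to 1 are renormalized
PROBABILITY_SUM_TOL = 0.015

#: row-stochasticity tolerance for transition matrices after load
ROW_SUM_TOL = 1e-9

#: antidiabetic drug classes the cost table may price
DRUG_CLASSES = (
    "metformin",
    "sulfonylurea",
    "thiazolidinedione",
    "alpha_glucosidase_inhibitor",
    "insulin",
)

_REQUIRED_FIELDS = (
    "arm_probabilities",
    "costs",
    "utilities",
    "discount_rate",
    "horizon_years",
    "wtp_band",
)


class ConfigError(ValueError):
    """A configuration file failed validation."""


@dataclasses.dataclass
class ModelConfig:
    """A fully validated model configuration.

    Attributes
    ----------
    arm_probabilities
        Strategy arm -> year-1 state distribution (renormalized, sums to 1).
    transition_matrices
        Strategy arm -> 5x5 row-stochastic matrix applied for cycles 2..T.
    state_costs
        Annual cost of occupying each state, THB/year (dead = 0).
    entry_costs
        Strategy arm -> one-time cost charged at model entry (the surgery
        fee for the surgery arm, 0 elsewhere).
    utilities
        Per-state utility weight in [0, 1] (dead = 0).
    discount_rate
        Annual discount rate applied to costs (proportion, e.g. 0.03).
    effect_discount_rate
        Annual discount rate applied to life-years and QALYs; defaults to
        ``discount_rate``.
    horizon_years
        Number of annual cycles simulated.
    wtp_band
        (low, high) willingness-to-pay in THB per QALY.
    cpi_base_year
        Calendar year all costs are expressed in.
    half_cycle_correction
        When True, state occupancy used for accrual in cycles 2..T is the
        mean of the cycle's start and end distributions.
    parameter_ranges
        Dotted-path parameter name -> (low, high) range for one-way DSA.
    raw
        The validated raw document (deep copy); ``write_config`` emits it
        and the sensitivity module mutates copies of it for DSA re-runs.
    """

    arm_probabilities: dict[str, np.ndarray]
    transition_matrices: dict[str, np.ndarray]
    state_costs: np.ndarray
    entry_costs: dict[str, float]
    utilities: np.ndarray
    discount_rate: float
    effect_discount_rate: float
    horizon_years: int
    wtp_band: tuple[float, float]
    cpi_base_year: int
    half_cycle_correction: bool
    parameter_ranges: dict[str, tuple[float, float]]
    raw: dict[str, Any]

    @property
    def arms(self) -> tuple[str, ...]:
        return tuple(self.arm_probabilities)

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "ModelConfig":
        """Validate a raw configuration document and compose derived vectors."""
        raw = copy.deepcopy(dict(doc))
        for field in _REQUIRED_FIELDS:
            if field not in raw:
                raise ConfigError(f"missing required field '{field}'")

        arm_probabilities = {
            arm: _load_arm_vector(arm, vec)
            for arm, vec in raw["arm_probabilities"].items()
        }
        if not arm_probabilities:
            raise ConfigError("arm_probabilities must define at least one strategy arm")

        state_costs, entry_costs = _compose_costs(raw["costs"], tuple(arm_probabilities))
        utilities = _load_utilities(raw["utilities"])
        transition_matrices = _load_transitions(raw, tuple(arm_probabilities))

        discount_rate = float(raw["discount_rate"])
        if discount_rate < 0:
            raise ConfigError("discount_rate must be >= 0")
        effect_discount_rate = float(raw.get("effect_discount_rate") or discount_rate)
        if effect_discount_rate < 0:
            raise ConfigError("effect_discount_rate must be >= 0")

        horizon_years = int(raw["horizon_years"])
        if horizon_years < 1:
            raise ConfigError("horizon_years must be >= 1")

        wtp = raw["wtp_band"]
        if len(wtp) != 2 or float(wtp[0]) > float(wtp[1]):
            raise ConfigError("wtp_band must be (low, high) with low <= high")
        wtp_band = (float(wtp[0]), float(wtp[1]))

        config = cls(
            arm_probabilities=arm_probabilities,
            transition_matrices=transition_matrices,
            state_costs=state_costs,
            entry_costs=entry_costs,
            utilities=utilities,
            discount_rate=discount_rate,
            effect_discount_rate=effect_discount_rate,
            horizon_years=horizon_years,
            wtp_band=wtp_band,
            cpi_base_year=int(raw.get("cpi_base_year", 2017)),
            half_cycle_correction=bool(raw.get("half_cycle_correction", False)),
            parameter_ranges={},
            raw=raw,
        )
        config.parameter_ranges = _load_parameter_ranges(raw)
        _check_ranges_bracket_baseline(config)
        return config

    def to_dict(self) -> dict[str, Any]:
        """Return a deep copy of the raw document this config was built from."""
        return copy.deepcopy(self.raw)


# ---------------------------------------------------------------------------
# field loaders

def _state_map_to_vector(mapping: Mapping[str, float], what: str) -> np.ndarray:
    vec = np.empty(N_STATES)
    for i, name in enumerate(STATE_NAMES):
        if name not in mapping:
            raise ConfigError(f"missing required field '{what}.{name}'")
        vec[i] = float(mapping[name])
    unknown = set(mapping) - set(STATE_NAMES)
    if unknown:
        raise ConfigError(f"unknown state name(s) in {what}: {sorted(unknown)}")
    return vec


def _load_arm_vector(arm: str, mapping: Mapping[str, float]) -> np.ndarray:
    vec = _state_map_to_vector(mapping, f"arm_probabilities.{arm}")
    if (vec < 0).any() or (vec > 1).any():
        raise ConfigError(f"arm_probabilities.{arm} has entries outside [0, 1]")
    total = vec.sum()
    if abs(total - 1.0) > PROBABILITY_SUM_TOL:
        raise ConfigError(
            f"arm_probabilities.{arm} sums to {total:.4f}, outside the accepted "
            f"band 1 ± {PROBABILITY_SUM_TOL}: {vec.tolist()}"
        )
    if total != 1.0:
        logger.warning(
            "arm_probabilities.%s sums to %.4f; renormalizing to 1", arm, total
        )
        vec = vec / total
    return vec


def _medication_cost(prices: Mapping[str, float], drug: str, where: str) -> float:
    if drug not in DRUG_CLASSES:
        raise ConfigError(f"unknown drug class '{drug}' in {where}")
    if drug not in prices:
        raise ConfigError(f"missing required field 'costs.medication.{drug}'")
    return float(prices[drug])


def _compose_costs(
    costs: Mapping[str, Any], arms: tuple[str, ...]
) -> tuple[np.ndarray, dict[str, float]]:
    for field in ("surgery_one_time", "medication", "supplementation", "complication_management"):
        if field not in costs:
            raise ConfigError(f"missing required field 'costs.{field}'")
    prices = costs["medication"]
    second_agent = costs.get("persistent_second_agent", "sulfonylurea")
    regimen = costs.get("uncontrolled_regimen", ["metformin", "sulfonylurea", "insulin"])
    if len(set(regimen)) < 3:
        raise ConfigError(
            "costs.uncontrolled_regimen must name at least three distinct drug "
            "classes (uncontrolled diabetes means more than two agents)"
        )
    if second_agent == "metformin":
        raise ConfigError("costs.persistent_second_agent must differ from metformin")

    state_costs = np.zeros(N_STATES)
    state_costs[DiabetesState.REMISSION] = float(costs["supplementation"])
    state_costs[DiabetesState.IMPROVED] = _medication_cost(prices, "metformin", "improved state")
    state_costs[DiabetesState.PERSISTENT] = state_costs[DiabetesState.IMPROVED] + _medication_cost(
        prices, second_agent, "costs.persistent_second_agent"
    )
    state_costs[DiabetesState.UNCONTROLLED] = sum(
        _medication_cost(prices, drug, "costs.uncontrolled_regimen") for drug in set(regimen)
    ) + float(costs["complication_management"])
    state_costs[DiabetesState.DEAD] = 0.0
    if (state_costs < 0).any():
        raise ConfigError("state annual costs must all be >= 0")

    surgery_fee = float(costs["surgery_one_time"])
    if surgery_fee < 0:
        raise ConfigError("costs.surgery_one_time must be >= 0")
    entry_costs = {arm: (surgery_fee if arm == "surgery" else 0.0) for arm in arms}
    return state_costs, entry_costs


def _load_utilities(mapping: Mapping[str, float]) -> np.ndarray:
    utilities = _state_map_to_vector(mapping, "utilities")
    if (utilities < 0).any() or (utilities > 1).any():
        raise ConfigError("utilities must lie in [0, 1]")
    if utilities[DiabetesState.DEAD] != 0.0:
        raise ConfigError("the dead state must have utility 0")
    return utilities


def build_transition_matrix(
    relapse_probability: float, death_probability: float
) -> np.ndarray:
    """Build the default annual transition matrix for cycles 2..T.

    Alive states persist, except that remission relapses to improved
    diabetes with ``relapse_probability`` per year, and every alive state
    dies with a flat ``death_probability`` per year.  Dead is absorbing.
    """
    p, d = float(relapse_probability), float(death_probability)
    if not 0 <= p <= 1 or not 0 <= d <= 1 or p + d > 1:
        raise ConfigError(
            f"transition parameters must satisfy 0 <= relapse + death <= 1 "
            f"(got relapse={p}, death={d})"
        )
    m = np.zeros((N_STATES, N_STATES))
    for s in (DiabetesState.IMPROVED, DiabetesState.PERSISTENT, DiabetesState.UNCONTROLLED):
        m[s, s] = 1.0 - d
        m[s, DiabetesState.DEAD] = d
    m[DiabetesState.REMISSION, DiabetesState.REMISSION] = 1.0 - p - d
    m[DiabetesState.REMISSION, DiabetesState.IMPROVED] = p
    m[DiabetesState.REMISSION, DiabetesState.DEAD] = d
    m[DiabetesState.DEAD, DiabetesState.DEAD] = 1.0
    return m


def validate_transition_matrix(matrix: np.ndarray, *, where: str = "annual_transition") -> np.ndarray:
    """Validate a row-stochastic 5x5 matrix with an absorbing dead state."""
    m = np.asarray(matrix, dtype=float)
    if m.shape != (N_STATES, N_STATES):
        raise ConfigError(f"{where} must be a {N_STATES}x{N_STATES} matrix, got {m.shape}")
    if (m < 0).any() or (m > 1).any():
        raise ConfigError(f"{where} has entries outside [0, 1]")
    row_sums = m.sum(axis=1)
    if np.abs(row_sums - 1.0).max() > ROW_SUM_TOL:
        raise ConfigError(f"{where} rows must sum to 1 within {ROW_SUM_TOL}; got {row_sums}")
    dead_row = np.zeros(N_STATES)
    dead_row[DiabetesState.DEAD] = 1.0
    if not np.array_equal(m[DiabetesState.DEAD], dead_row):
        raise ConfigError(f"{where} dead row must be absorbing (0, 0, 0, 0, 1)")
    return m


def _load_transitions(raw: Mapping[str, Any], arms: tuple[str, ...]) -> dict[str, np.ndarray]:
    explicit = raw.get("annual_transition") or {}
    parametric = raw.get("transition") or {}
    matrices: dict[str, np.ndarray] = {}
    for arm in arms:
        if arm in explicit:
            matrices[arm] = validate_transition_matrix(
                np.array(explicit[arm]), where=f"annual_transition.{arm}"
            )
        elif arm in parametric:
            spec = parametric[arm]
            matrices[arm] = build_transition_matrix(
                spec.get("relapse_probability", 0.0),
                spec.get("death_probability", 0.0),
            )
        else:
            raise ConfigError(
                f"no annual transition dynamics for arm '{arm}': provide either "
                f"annual_transition.{arm} (explicit matrix) or transition.{arm} "
                f"(relapse_probability/death_probability)"
            )
    return matrices


def _load_parameter_ranges(raw: Mapping[str, Any]) -> dict[str, tuple[float, float]]:
    ranges = {}
    for name, bounds in (raw.get("parameter_ranges") or {}).items():
        if len(bounds) != 2:
            raise ConfigError(f"parameter_ranges['{name}'] must be a (low, high) pair")
        low, high = float(bounds[0]), float(bounds[1])
        if low > high:
            raise ConfigError(f"parameter_ranges['{name}'] has low {low} > high {high}")
        ranges[name] = (low, high)
    return ranges


def _check_ranges_bracket_baseline(config: ModelConfig) -> None:
    for name, (low, high) in config.parameter_ranges.items():
        baseline = resolve_parameter(config.raw, name)
        if not low <= baseline <= high:
            raise ConfigError(
                f"parameter_ranges['{name}'] = ({low}, {high}) does not bracket "
                f"the baseline value {baseline}"
            )


# ---------------------------------------------------------------------------
# dotted-path parameter access (shared with the sensitivity module)

def resolve_parameter(raw: Mapping[str, Any], path: str) -> float:
    """Resolve a dotted path like ``costs.medication.metformin`` to its value."""
    node: Any = raw
    for key in path.split("."):
        try:
            node = node[key]
        except (KeyError, TypeError):
            raise ConfigError(f"cannot resolve parameter path '{path}' (at '{key}')")
    if not isinstance(node, (int, float)):
        raise ConfigError(f"parameter path '{path}' is not a numeric value")
    return float(node)


def set_parameter(raw: dict[str, Any], path: str, value: float) -> None:
    """Set a dotted-path value in a raw document, in place.

    Setting one entry of an arm's year-1 probability vector rescales the
    remaining entries proportionally so the vector still sums to its
    original total, preserving their relative composition.
    """
    keys = path.split(".")
    resolve_parameter(raw, path)  # raises if the path is bad
    node: Any = raw
    for key in keys[:-1]:
        node = node[key]
    if keys[0] == "arm_probabilities" and len(keys) == 3:
        _, _, state = keys
        total = sum(float(v) for v in node.values())
        others = total - float(node[state])
        if value > total:
            raise ConfigError(
                f"cannot set {path} to {value}: exceeds the vector total {total}"
            )
        scale = (total - value) / others if others > 0 else 0.0
        for other_state in node:
            if other_state != state:
                node[other_state] = float(node[other_state]) * scale
        node[state] = float(value)
    else:
        node[keys[-1]] = float(value)


# ---------------------------------------------------------------------------
# file I/O

def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a JSON model configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"config file {path} is not valid JSON: {exc}") from exc
    return ModelConfig.from_dict(doc)


def write_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration back to JSON (round-trips through load_config)."""
    Path(path).write_text(json.dumps(config.raw, indent=2, sort_keys=True) + "\n")


def baseline_config() -> ModelConfig:
    """The bundled baseline configuration for the Thai bariatric-surgery model.

    Carries the published year-1 outcome probabilities, the KCMH surgery fee
    and national median drug prices (2017 THB), the state utilities, a 3%
    annual discount rate, a 50-year horizon and the 150,000-200,000 THB/QALY
    willingness-to-pay band, plus default one-way-DSA ranges.
    """
    from importlib import resources

    with resources.files("baricea.data").joinpath("thailand_baseline.json").open() as fh:
        return ModelConfig.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# consumer price index adjustment

def load_cpi_table(path: str | Path) -> dict[int, float]:
    """Read a two-column CSV (year, index) into a CPI lookup table."""
    frame = pd.read_csv(path)
    expected = ["year", "index"]
    if list(frame.columns[:2]) != expected:
        raise ConfigError(f"CPI table must have columns {expected}, got {list(frame.columns)}")
    table = {int(y): float(v) for y, v in zip(frame["year"], frame["index"])}
    if any(v <= 0 for v in table.values()):
        raise ConfigError("CPI index values must all be > 0")
    return table


def cpi_adjust(
    amount: float, from_year: int, cpi: Mapping[int, float], base_year: int
) -> float:
    """Rescale ``amount`` from ``from_year`` prices to ``base_year`` prices.

    Returns ``amount * index(base_year) / index(from_year)``.
    """
    for year in (from_year, base_year):
        if year not in cpi:
            raise ConfigError(f"year {year} missing from the CPI table")
    return float(amount) * cpi[base_year] / cpi[from_year]
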