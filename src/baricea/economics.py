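"""Incremental cost-effectiveness measures and willingness-to-pay verdicts.

Given two strategy arms, the incremental cost-effectiveness ratio is
ICER = (C_new - C_ref) / (E_new - E_ref), with effectiveness in life-years
or clinical units; measured in QALYs the same ratio is the incremental
cost-utility ratio (ICUR).  When one strategy is cheaper and at least as
effective it *dominates*: no ratio is reported, only the dominance label
(a signed ratio is uninterpretable).

The willingness-to-pay verdict compares a QALY-denominated ratio against
the Thai health-technology-assessment band of 1-3x GDP per capita
(150,000-200,000 THB/QALY by default); a ratio exactly on a boundary
counts as cost-effective (<= convention).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import pandas as pd

from .config_io import ModelConfig
from .cohort_stats import ClinicalSummary
from .markov_engine import MarkovTrace, run_markov

#: verdict labels
DOMINANT = "dominant"
DOMINATED = "dominated"
COST_EFFECTIVE_LOW = "cost-effective at low WTP"
COST_EFFECTIVE_HIGH_ONLY = "cost-effective at high WTP only"
NOT_COST_EFFECTIVE = "not cost-effective"
INDIFFERENT = "indifferent"


@dataclasses.dataclass
class CEAResult:
    """Incremental comparison of a new strategy against a reference.

    ``ratio`` is THB per effect unit and is None exactly when the
    comparison is dominance (or both increments are zero); ``verdict``
    starts as the dominance label (or None) and is finalized against a
    willingness-to-pay band by :func:`verdict_against_wtp`.

    Note the south-west quadrant (cheaper *and* less effective) yields a
    positive ratio whose interpretation is savings per effect unit
    forgone, not cost per unit gained.
    """

    incremental_cost: float
    incremental_effect: float
    effect_label: str
    ratio: float | None = None
    verdict: str | None = None

    def rounded_ratio(self) -> float | None:
        """The ratio at reporting precision (2 decimal places of THB)."""
        return None if self.ratio is None else round(self.ratio, 2)


def icer(
    cost_new: float,
    cost_ref: float,
    effect_new: float,
    effect_ref: float,
    effect_label: str = "QALY",
) -> CEAResult:
    """Incremental cost-effectiveness of a new strategy vs. a reference.

    Every sign combination maps to a defined outcome: a ratio where one is
    meaningful, otherwise the dominance label (``dominant`` when the new
    strategy is cheaper and at least as effective, ``dominated`` in the
    mirror case, ``indifferent`` when both increments are zero).
    """
    d_cost = cost_new - cost_ref
    d_effect = effect_new - effect_ref
    result = CEAResult(
        incremental_cost=d_cost, incremental_effect=d_effect, effect_label=effect_label
    )
    if (d_cost <= 0 and d_effect > 0) or (d_cost < 0 and d_effect >= 0):
        result.verdict = DOMINANT
    elif (d_cost >= 0 and d_effect < 0) or (d_cost > 0 and d_effect <= 0):
        result.verdict = DOMINATED
    elif d_cost == 0 and d_effect == 0:
        result.verdict = INDIFFERENT
    else:
        result.ratio = d_cost / d_effect
    return result


def verdict_against_wtp(
    result: CEAResult, wtp_band: tuple[float, float] | None = None
) -> str:
    """Judge a QALY-denominated result against a (low, high) WTP band.

    Dominance labels pass through unchanged (``dominated`` is reported as
    not cost-effective).  The result's ``verdict`` field is updated.
    """
    if result.effect_label != "QALY":
        raise ValueError(
            f"willingness-to-pay verdicts require a QALY-denominated result, "
            f"got effect label '{result.effect_label}'"
        )
    if result.verdict == DOMINANT:
        return DOMINANT
    if result.verdict in (DOMINATED, INDIFFERENT):
        result.verdict = NOT_COST_EFFECTIVE if result.verdict == DOMINATED else result.verdict
        return result.verdict
    low, high = wtp_band if wtp_band is not None else (150000.0, 200000.0)
    assert result.ratio is not None
    if result.ratio <= low:
        result.verdict = COST_EFFECTIVE_LOW
    elif result.ratio <= high:
        result.verdict = COST_EFFECTIVE_HIGH_ONLY
    else:
        result.verdict = NOT_COST_EFFECTIVE
    return result.verdict


def one_year_clinical_icers(
    summaries: Mapping[str, ClinicalSummary], incremental_cost: float
) -> dict[str, CEAResult]:
    """Cost per unit of one-year clinical improvement (HbA1C %, BMI kg/m2).

    The effect for each endpoint is its mean baseline-to-year-1 reduction;
    the same incremental cost (THB) is spread over each endpoint's effect.
    A zero cost over a positive effect gives ratio 0 (a free improvement,
    also flagged dominant); a zero effect falls back to the dominance
    handling of :func:`icer`.
    """
    labels = {"hba1c": "HbA1C %", "bmi": "BMI kg/m2"}
    results = {}
    for endpoint, summary in summaries.items():
        result = icer(
            incremental_cost,
            0.0,
            summary.mean_reduction,
            0.0,
            effect_label=labels.get(endpoint, endpoint),
        )
        if incremental_cost == 0 and summary.mean_reduction > 0:
            result.ratio = 0.0
        results[endpoint] = result
    return results


@dataclasses.dataclass
class ArmComparison:
    """Lifetime two-arm comparison: traces plus QALY- and LY-based results."""

    new_arm: str
    ref_arm: str
    traces: dict[str, MarkovTrace]
    icur: CEAResult  # QALY-denominated
    icer_ly: CEAResult  # life-year-denominated

    def to_frame(self) -> pd.DataFrame:
        new, ref = self.traces[self.new_arm], self.traces[self.ref_arm]
        rows = [
            {
                "measure": "total discounted cost (THB)",
                self.new_arm: round(new.total_cost, 2),
                self.ref_arm: round(ref.total_cost, 2),
                "incremental": round(new.total_cost - ref.total_cost, 2),
            },
            {
                "measure": "total discounted life-years",
                self.new_arm: round(new.total_life_years, 2),
                self.ref_arm: round(ref.total_life_years, 2),
                "incremental": round(new.total_life_years - ref.total_life_years, 2),
            },
            {
                "measure": "total discounted QALYs",
                self.new_arm: round(new.total_qalys, 2),
                self.ref_arm: round(ref.total_qalys, 2),
                "incremental": round(new.total_qalys - ref.total_qalys, 2),
            },
        ]
        return pd.DataFrame(rows)


def compare_arms(
    config: ModelConfig, new_arm: str = "surgery", ref_arm: str = "no_surgery"
) -> ArmComparison:
    """Run both arms to the horizon and compute lifetime ICUR and ICER.

    The QALY-denominated result carries the willingness-to-pay verdict
    from the config's band.
    """
    traces = {arm: run_markov(config, arm) for arm in (new_arm, ref_arm)}
    new, ref = traces[new_arm], traces[ref_arm]
    icur = icer(new.total_cost, ref.total_cost, new.total_qalys, ref.total_qalys, "QALY")
    verdict_against_wtp(icur, config.wtp_band)
    icer_ly = icer(
        new.total_cost,
        ref.total_cost,
        new.total_life_years,
        ref.total_life_years,
        "life-year",
    )
    return ArmComparison(
        new_arm=new_arm, ref_arm=ref_arm, traces=traces, icur=icur, icer_ly=icer_ly
    )


def results_frame(results: Sequence[CEAResult]) -> pd.DataFrame:
    """Tabulate CEA results (one row each) for CSV export."""
    rows = []
    for r in results:
        rows.append(
            {
                "effect_label": r.effect_label,
                "incremental_cost": round(r.incremental_cost, 2),
                "incremental_effect": r.incremental_effect,
                "ratio": "" if r.ratio is None else round(r.ratio, 2),
                "verdict": r.verdict or "",
            }
        )
    return pd.DataFrame(rows)
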