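"""One-way deterministic sensitivity analysis and time-horizon threshold analysis.

The one-way DSA perturbs each named parameter to the low and high end of
its range — all other parameters held at baseline — reruns the full
two-arm model, and records the resulting incremental cost-utility ratios.
Rows ordered by *swing* (the absolute difference between the two ends'
ratios) form the tornado diagram.  The threshold analysis asks at which
horizon year the cumulative incremental cost per cumulative incremental
QALY first drops to the willingness-to-pay level.

Conventions for dominance inside the DSA: a dominant end (surgery cheaper
and no less effective) is recorded with no ratio and counts as below any
threshold; for swing purposes a dominant end contributes ratio 0 and a
dominated end is excluded (a row with fewer than two usable ends has
swing 0).

The whole analysis is deterministic: identical configurations produce
identical result tables.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .config_io import ConfigError, ModelConfig, resolve_parameter, set_parameter
from .economics import DOMINANT, DOMINATED, CEAResult, compare_arms

#: parameters whose ranges come straight from the published cost table
COST_PARAMETER_PREFIX = "costs."


def perturbed_config(config: ModelConfig, path: str, value: float) -> ModelConfig:
    """A new validated config with one dotted-path parameter set to ``value``."""
    raw = config.to_dict()
    set_parameter(raw, path, value)
    return ModelConfig.from_dict(raw)


@dataclasses.dataclass
class DsaRow:
    """One parameter's one-way sensitivity result.

    ``icur_low``/``icur_high`` are the ratios with the parameter at each
    end of its range (NaN under dominance; see ``verdict_low``/``verdict_high``).
    """

    parameter: str
    baseline_value: float
    low: float
    high: float
    icur_low: float
    icur_high: float
    verdict_low: str
    verdict_high: str
    swing: float


def _end_summary(result: CEAResult) -> tuple[float, str]:
    if result.ratio is None:
        return math.nan, result.verdict or ""
    return result.ratio, result.verdict or ""


def _swing(rows_ends: Sequence[tuple[float, str]]) -> float:
    usable = [
        0.0 if verdict == DOMINANT else ratio
        for ratio, verdict in rows_ends
        if verdict == DOMINANT or not math.isnan(ratio)
    ]
    if len(usable) < 2:
        return 0.0
    return abs(usable[0] - usable[1])


def one_way_dsa(
    config: ModelConfig, parameters: Sequence[str] | None = None
) -> list[DsaRow]:
    """Run the one-way DSA over ``parameters`` (default: every configured range).

    Each parameter is set to the low then the high end of its range with
    everything else at baseline, and the lifetime two-arm model is rerun.
    """
    if parameters is None:
        parameters = list(config.parameter_ranges)
    baseline_icur = compare_arms(config).icur  # evaluated once, reused at ends == baseline
    rows = []
    for name in parameters:
        if name not in config.parameter_ranges:
            raise ConfigError(f"no DSA range configured for parameter '{name}'")
        low, high = config.parameter_ranges[name]
        baseline = resolve_parameter(config.raw, name)
        ends = []
        for value in (low, high):
            if value == baseline:
                result = baseline_icur
            else:
                result = compare_arms(perturbed_config(config, name, value)).icur
            ends.append(_end_summary(result))
        (icur_low, verdict_low), (icur_high, verdict_high) = ends
        rows.append(
            DsaRow(
                parameter=name,
                baseline_value=baseline,
                low=low,
                high=high,
                icur_low=icur_low,
                icur_high=icur_high,
                verdict_low=verdict_low,
                verdict_high=verdict_high,
                swing=_swing(ends),
            )
        )
    return rows


def tornado_order(rows: Sequence[DsaRow]) -> list[DsaRow]:
    """Rows sorted by swing descending; ties broken by parameter name."""
    return sorted(rows, key=lambda r: (-r.swing, r.parameter))


def dsa_threshold_check(rows: Sequence[DsaRow], wtp: float) -> dict[str, bool]:
    """For each row, whether both ends stay within the willingness-to-pay level.

    A dominant end counts as below any threshold; a dominated end never
    does; a ratio end passes iff ratio <= wtp.
    """

    def end_ok(ratio: float, verdict: str) -> bool:
        if verdict == DOMINANT:
            return True
        if verdict == DOMINATED:
            return False
        return not math.isnan(ratio) and ratio <= wtp

    return {
        row.parameter: end_ok(row.icur_low, row.verdict_low)
        and end_ok(row.icur_high, row.verdict_high)
        for row in rows
    }


def dsa_frame(rows: Sequence[DsaRow], wtp: float | None = None) -> pd.DataFrame:
    """Tabulate DSA rows for CSV export (tornado order)."""
    ordered = tornado_order(rows)
    frame = pd.DataFrame([dataclasses.asdict(r) for r in ordered])
    if wtp is not None:
        checks = dsa_threshold_check(ordered, wtp)
        frame["below_threshold"] = [checks[r.parameter] for r in ordered]
    return frame


# ---------------------------------------------------------------------------
# time-horizon threshold analysis

@dataclasses.dataclass
class ThresholdCurve:
    """Cumulative incrementals and their ratio at every candidate horizon.

    ``icur[h-1]`` is cumulative incremental cost over cumulative
    incremental QALYs through cycle ``h`` (NaN while the QALY increment is
    not positive).  ``first_cost_effective_year`` is the smallest horizon
    whose ratio is at or below the willingness-to-pay level with a
    positive QALY gain, or None if no horizon qualifies.
    """

    years: np.ndarray
    cum_delta_cost: np.ndarray
    cum_delta_qaly: np.ndarray
    icur: np.ndarray
    below_wtp: np.ndarray
    wtp: float
    first_cost_effective_year: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "horizon_year": self.years,
                "cum_delta_cost": self.cum_delta_cost,
                "cum_delta_qaly": self.cum_delta_qaly,
                "icur": self.icur,
                "below_wtp": self.below_wtp,
            }
        )


def threshold_year(
    config: ModelConfig,
    wtp: float | None = None,
    new_arm: str = "surgery",
    ref_arm: str = "no_surgery",
) -> ThresholdCurve:
    """Find the earliest horizon at which the new arm becomes cost-effective.

    Uses the config's low willingness-to-pay bound unless ``wtp`` is given.
    The scan is ascending over horizons 1..T, so the reported year is the
    minimum qualifying one by construction.
    """
    if wtp is None:
        wtp = config.wtp_band[0]
    comparison = compare_arms(config, new_arm=new_arm, ref_arm=ref_arm)
    new, ref = comparison.traces[new_arm], comparison.traces[ref_arm]
    cum_dc = new.cum_cost - ref.cum_cost
    cum_dq = new.cum_qalys - ref.cum_qalys
    with np.errstate(divide="ignore", invalid="ignore"):
        icur = np.where(cum_dq > 0, cum_dc / cum_dq, math.nan)
    below = (cum_dq > 0) & (icur <= wtp)
    qualifying = np.flatnonzero(below)
    return ThresholdCurve(
        years=new.cycles.copy(),
        cum_delta_cost=cum_dc,
        cum_delta_qaly=cum_dq,
        icur=icur,
        below_wtp=below,
        wtp=float(wtp),
        first_cost_effective_year=int(new.cycles[qualifying[0]]) if qualifying.size else None,
    )


def tornado_plot(dsa_csv: str, out_path: str, wtp: float | None = None) -> None:
    """Render a tornado diagram from a DSA result CSV (derived artifact only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = pd.read_csv(dsa_csv)
    frame = frame.sort_values("swing")  # widest bar on top
    lows = frame["icur_low"].fillna(0.0)
    highs = frame["icur_high"].fillna(0.0)
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(frame) + 1.5))
    y = np.arange(len(frame))
    ax.barh(y, highs - lows, left=lows, color="#4878b0")
    ax.set_yticks(y)
    ax.set_yticklabels(frame["parameter"])
    ax.set_xlabel("ICUR (THB per QALY)")
    if wtp is not None:
        ax.axvline(wtp, color="crimson", linestyle="--", label=f"WTP {wtp:,.0f}")
        ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
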