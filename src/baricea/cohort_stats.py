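"""Patient-level outcome classification and cohort summaries.

Maps each patient's one-year clinical record (HbA1C, antidiabetic drug
classes, vital status) to one of the five diabetes outcome states, tallies
state frequencies into the year-1 outcome probability vector, and produces
the paired baseline-vs-year-1 clinical effectiveness summary (BMI, HbA1C)
with a two-sided paired t-test.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .states import DiabetesState, N_STATES, STATE_NAMES

logger = logging.getLogger(__name__)

#: closed vocabulary of antidiabetic drug-class labels on patient records
MEDICATION_VOCABULARY = frozenset(
    {
        "metformin",
        "sulfonylurea",
        "thiazolidinedione",
        "alpha_glucosidase_inhibitor",
        "insulin",
        "other",
    }
)

_COHORT_COLUMNS = [
    "id",
    "sex",
    "age",
    "baseline_bmi",
    "year1_bmi",
    "baseline_hba1c",
    "year1_hba1c",
    "year1_medications",
    "deceased_by_year1",
]


@dataclasses.dataclass(frozen=True)
class PatientRecord:
    """One patient: baseline and one-year clinical values plus medications.

    ``year1_medications`` holds antidiabetic drug-class labels from
    ``MEDICATION_VOCABULARY``.  Year-1 clinical values may be NaN for
    patients deceased by year 1.
    """

    id: str
    sex: str
    age: float
    baseline_bmi: float
    year1_bmi: float
    baseline_hba1c: float
    year1_hba1c: float
    year1_medications: tuple[str, ...] = ()
    deceased_by_year1: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got '{self.sex}'")
        for field in ("baseline_bmi", "baseline_hba1c"):
            if not getattr(self, field) > 0:
                raise ValueError(f"{field} must be strictly positive")
        if not self.deceased_by_year1:
            for field in ("year1_bmi", "year1_hba1c"):
                if not getattr(self, field) > 0:
                    raise ValueError(f"{field} must be strictly positive for living patients")
        for label in self.year1_medications:
            if label not in MEDICATION_VOCABULARY:
                raise ValueError(f"unknown drug class '{label}'")


def classify_status(
    hba1c: float, medications: Sequence[str], deceased: bool = False
) -> DiabetesState:
    """Classify a one-year outcome into one of the five diabetes states.

    Rules, applied in order (distinct drug classes counted):

    1. deceased                                    -> DEAD
    2. HbA1C < 6.5 % and no antidiabetic agent     -> REMISSION
    3. HbA1C < 6.5 % and metformin monotherapy     -> IMPROVED
    4. exactly two classes including metformin     -> PERSISTENT
    5. more than two classes                       -> UNCONTROLLED
    6. anything else (e.g. HbA1C >= 6.5 % with at most one agent, or a
       two-class regimen without metformin)        -> PERSISTENT, logged

    The published definitions leave case 6 open; assigning it to the
    persistent state is the conservative (more-diseased) choice and every
    such fallback is logged.
    """
    if deceased:
        return DiabetesState.DEAD
    classes = set(medications)
    unknown = classes - MEDICATION_VOCABULARY
    if unknown:
        raise ValueError(f"unknown drug class '{sorted(unknown)[0]}'")
    if not hba1c > 0:
        raise ValueError("hba1c must be strictly positive for living patients")
    if hba1c < 6.5 and not classes:
        return DiabetesState.REMISSION
    if hba1c < 6.5 and classes == {"metformin"}:
        return DiabetesState.IMPROVED
    if len(classes) == 2 and "metformin" in classes:
        return DiabetesState.PERSISTENT
    if len(classes) > 2:
        return DiabetesState.UNCONTROLLED
    logger.info(
        "fallback classification to PERSISTENT (hba1c=%.2f, classes=%s)",
        hba1c,
        sorted(classes),
    )
    return DiabetesState.PERSISTENT


def classify_record(record: PatientRecord) -> DiabetesState:
    """Classify a full patient record's one-year outcome."""
    return classify_status(
        record.year1_hba1c, record.year1_medications, record.deceased_by_year1
    )


@dataclasses.dataclass(frozen=True)
class OutcomeEstimate:
    """State counts and the corresponding year-1 outcome probability vector."""

    counts: np.ndarray
    probabilities: np.ndarray
    n: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": STATE_NAMES,
                "count": self.counts,
                "probability": np.round(self.probabilities, 4),
                "percent": np.round(100 * self.probabilities, 1),
            }
        )


def estimate_outcome_probabilities(cohort: Sequence[PatientRecord]) -> OutcomeEstimate:
    """Tally classified states into counts and a probability vector (counts/N)."""
    if not cohort:
        raise ValueError("cannot estimate outcome probabilities from an empty cohort")
    counts = np.zeros(N_STATES, dtype=int)
    for record in cohort:
        counts[classify_record(record)] += 1
    return OutcomeEstimate(counts=counts, probabilities=counts / len(cohort), n=len(cohort))


@dataclasses.dataclass(frozen=True)
class ClinicalSummary:
    """Paired baseline vs. year-1 summary for one clinical endpoint.

    ``mean_reduction`` is baseline minus year 1 (positive = improvement).
    ``p_value`` is from a two-sided paired t-test; with zero-variance
    differences it is NaN (all differences zero) or 0 (a nonzero constant
    shift, which a t-test cannot scale).
    """

    endpoint: str
    n: int
    baseline_mean: float
    baseline_sd: float
    year1_mean: float
    year1_sd: float
    mean_reduction: float
    p_value: float


def _summarize_endpoint(
    endpoint: str, baseline: np.ndarray, year1: np.ndarray
) -> ClinicalSummary:
    diffs = baseline - year1
    if np.std(diffs, ddof=1) == 0:
        p_value = math.nan if diffs[0] == 0 else 0.0
    else:
        p_value = float(stats.ttest_rel(baseline, year1).pvalue)
    return ClinicalSummary(
        endpoint=endpoint,
        n=len(baseline),
        baseline_mean=float(np.mean(baseline)),
        baseline_sd=float(np.std(baseline, ddof=1)),
        year1_mean=float(np.mean(year1)),
        year1_sd=float(np.std(year1, ddof=1)),
        mean_reduction=float(np.mean(diffs)),
        p_value=p_value,
    )


def summarize_clinical(cohort: Sequence[PatientRecord]) -> dict[str, ClinicalSummary]:
    """Paired summaries for BMI and HbA1C over patients alive at year 1.

    Sample standard deviations use the n-1 convention.  Requires at least
    two patients with both timepoints.
    """
    alive = [r for r in cohort if not r.deceased_by_year1]
    if len(alive) < 2:
        raise ValueError("need at least two patients with both timepoints")
    return {
        "bmi": _summarize_endpoint(
            "bmi",
            np.array([r.baseline_bmi for r in alive]),
            np.array([r.year1_bmi for r in alive]),
        ),
        "hba1c": _summarize_endpoint(
            "hba1c",
            np.array([r.baseline_hba1c for r in alive]),
            np.array([r.year1_hba1c for r in alive]),
        ),
    }


def clinical_summary_frame(summaries: dict[str, ClinicalSummary]) -> pd.DataFrame:
    """Tabulate clinical summaries, one row per endpoint."""
    return pd.DataFrame([dataclasses.asdict(s) for s in summaries.values()])


# ---------------------------------------------------------------------------
# cohort CSV dialect

def write_cohort_csv(cohort: Iterable[PatientRecord], path: str | Path) -> None:
    """Write patient records to CSV (medications semicolon-separated)."""
    rows = []
    for r in cohort:
        row = dataclasses.asdict(r)
        row["year1_medications"] = ";".join(r.year1_medications)
        row["deceased_by_year1"] = "true" if r.deceased_by_year1 else "false"
        rows.append(row)
    pd.DataFrame(rows, columns=_COHORT_COLUMNS).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    """Read the cohort CSV dialect back into patient records."""
    frame = pd.read_csv(path, dtype={"id": str, "year1_medications": str})
    missing = set(_COHORT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"cohort CSV is missing column(s): {sorted(missing)}")
    cohort = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        meds = row.year1_medications
        med_tuple = tuple(m for m in str(meds).split(";") if m) if pd.notna(meds) else ()
        deceased = str(row.deceased_by_year1).strip().lower() in ("true", "1", "yes")
        try:
            cohort.append(
                PatientRecord(
                    id=str(row.id),
                    sex=str(row.sex),
                    age=float(row.age),
                    baseline_bmi=float(row.baseline_bmi),
                    year1_bmi=float(row.year1_bmi),
                    baseline_hba1c=float(row.baseline_hba1c),
                    year1_hba1c=float(row.year1_hba1c),
                    year1_medications=med_tuple,
                    deceased_by_year1=deceased,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"invalid patient record at CSV row {i}: {exc}") from exc
    return cohort
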