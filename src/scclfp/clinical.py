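"""Clinical outcome definitions for the DBS cohort.

Response is defined on the 17-item Hamilton Depression Rating Scale
(HDRS-17, range 0-52): a patient is a responder when the follow-up
score has dropped by at least 50% from baseline.  Time to *stable*
response is the first week starting a run of three consecutive weeks
that each meet the 50% rule.  ``load_reference_cohort`` ships the
14-patient study cohort's printed scores as packaged data so the
summary statistics are reproducible without any recordings.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np

from .errors import UndefinedBaselineError
from .io import ClinicalRecord, read_clinical_table

HDRS_MAX = 52.0
RESPONSE_FRACTION = 0.5
STABLE_RUN_WEEKS = 3


def classify_response(baseline: float, followup: float) -> bool:
    """True iff the follow-up score dropped >= 50% from baseline.

    The boundary counts: exactly a 50% decrease is a response.
    """
    for name, score in (("baseline", baseline), ("followup", followup)):
        if not (0 <= score <= HDRS_MAX):
            raise ValueError(f"{name} HDRS17 score {score} outside [0, {HDRS_MAX}]")
    if baseline == 0:
        raise UndefinedBaselineError("percent decrease undefined at baseline 0")
    return (baseline - followup) / baseline >= RESPONSE_FRACTION


def time_to_stable_response(
    weekly_series: dict[int, float] | None, baseline: float
) -> int | None:
    """First week w such that weeks w, w+1, w+2 all meet the 50% rule.

    Returns None (NA) when no such run exists or the series is shorter
    than three weeks.  Weeks must be consecutive to count as a run.
    """
    if not weekly_series or len(weekly_series) < STABLE_RUN_WEEKS:
        return None
    ok = {
        w: classify_response(baseline, score)
        for w, score in weekly_series.items()
    }
    for w in sorted(ok):
        if all(ok.get(w + k, False) for k in range(STABLE_RUN_WEEKS)):
            return w
    return None


@dataclass
class PatientOutcome:
    """One patient's clinical trajectory and derived outcome flags."""

    patient_id: str
    baseline_hdrs17: float
    month6_hdrs17: float
    weekly_hdrs17: dict[int, float] | None
    responder_6mo: bool
    time_to_stable_weeks: float | None


def outcome_from_record(record: ClinicalRecord) -> PatientOutcome:
    """Derive the responder flag and (if possible) time-to-stable from
    a raw clinical row.  An explicit time_to_stable_weeks column wins
    over derivation from the weekly series."""
    ttr = record.time_to_stable_weeks
    if ttr is None and record.weekly_hdrs17:
        ttr = time_to_stable_response(record.weekly_hdrs17, record.baseline_hdrs17)
    return PatientOutcome(
        patient_id=record.patient_id,
        baseline_hdrs17=record.baseline_hdrs17,
        month6_hdrs17=record.month6_hdrs17,
        weekly_hdrs17=record.weekly_hdrs17,
        responder_6mo=classify_response(record.baseline_hdrs17, record.month6_hdrs17),
        time_to_stable_weeks=ttr,
    )


def cohort_summary(outcomes: list[PatientOutcome]) -> dict:
    """Column means/sds (sample sd, NA-excluded) and the responder count.

    ``rounded`` mirrors the precision conventions of a clinical
    characteristics table (1 decimal for scores, sd of weeks to 2
    significant figures).
    """
    def col(values: list[float]) -> dict:
        arr = np.asarray([v for v in values if v is not None and np.isfinite(v)], dtype=float)
        return {
            "n": int(arr.size),
            "mean": float(arr.mean()) if arr.size else None,
            "sd": float(arr.std(ddof=1)) if arr.size >= 2 else None,
        }

    baseline = col([o.baseline_hdrs17 for o in outcomes])
    month6 = col([o.month6_hdrs17 for o in outcomes])
    ttr = col([o.time_to_stable_weeks for o in outcomes])
    summary = {
        "n_patients": len(outcomes),
        "n_responders": sum(o.responder_6mo for o in outcomes),
        "baseline_hdrs17": baseline,
        "month6_hdrs17": month6,
        "time_to_stable_weeks": ttr,
        "rounded": {
            "baseline_mean": round(baseline["mean"], 1) if baseline["mean"] is not None else None,
            "baseline_sd": round(baseline["sd"], 1) if baseline["sd"] is not None else None,
            "month6_mean": round(month6["mean"], 1) if month6["mean"] is not None else None,
            "month6_sd": round(month6["sd"], 1) if month6["sd"] is not None else None,
            "ttr_mean": round(ttr["mean"], 1) if ttr["mean"] is not None else None,
            "ttr_sd": float(f"{ttr['sd']:.2g}") if ttr["sd"] is not None else None,
        },
    }
    return summary


def load_reference_cohort() -> list[PatientOutcome]:
    """The published 14-patient cohort's clinical scores (packaged CSV)."""
    ref = importlib.resources.files("scclfp.data") / "cohort_clinical.csv"
    with importlib.resources.as_file(ref) as path:
        records = read_clinical_table(path)
    return [outcome_from_record(r) for r in records]
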