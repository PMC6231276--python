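"""Cohort identification and selection funnel.

A patient enters the cohort if (1) at least one medical event during the
identification window carries an asthma ICD-10 code (J45/J46, any sub-code)
and (2) their enrollment spans cover every day of the cost-analysis year
with no gap.  The funnel counts at each step are retained — with claims
data they are the only audit trail of selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import StudyWindows

__all__ = [
    "identify_asthma_patients",
    "filter_continuous_enrollment",
    "count_exacerbations",
    "exacerbation_counts",
    "build_cohort",
    "CohortResult",
]

logger = logging.getLogger(__name__)

#: event types counted as exacerbations
EXACERBATION_TYPES = ("ed_visit", "hospitalization")

_ASTHMA_PREFIXES = ("J45", "J46")


def _code_matches(codes: object, prefixes=_ASTHMA_PREFIXES) -> bool:
    if not isinstance(codes, str):
        return False
    return any(
        tok.strip().upper().startswith(prefixes) for tok in codes.split(";") if tok.strip()
    )


def identify_asthma_patients(
    events: pd.DataFrame,
    windows: StudyWindows,
    allowed_prefixes: tuple[str, ...] = _ASTHMA_PREFIXES,
) -> set:
    """Patients with >=1 asthma-coded event inside the identification window.

    Matching is prefix-based on the three-character stems so that four- and
    five-character sub-codes (J45.0, ...) qualify.  Codes that are not
    strings are logged and treated as non-matching. ``allowed_prefixes`` is
    the mechanical stand-in for chart review: restricting it narrows what
    counts as an asthma-related event.
    """
    dates = pd.to_datetime(events["date"])
    in_window = (dates >= pd.Timestamp(windows.identification_start)) & (
        dates <= pd.Timestamp(windows.identification_end)
    )
    codes = events["icd10_codes"]
    bad = codes.isna() | ~codes.map(lambda c: isinstance(c, str))
    if bad.any():
        logger.warning("%d events with malformed ICD-10 codes ignored", int(bad.sum()))
    match = codes.map(lambda c: _code_matches(c, allowed_prefixes))
    return set(events.loc[in_window & match, "patient_id"])


def filter_continuous_enrollment(
    candidates: set,
    spans: pd.DataFrame,
    windows: StudyWindows,
) -> set:
    """Keep candidates whose merged spans cover the whole analysis window.

    Adjacent spans (one ends the day before the next starts) merge; any
    uncovered day excludes the patient.  Patients without spans are simply
    excluded.
    """
    a = pd.Timestamp(windows.analysis_start)
    b = pd.Timestamp(windows.analysis_end)
    sub = spans[spans["patient_id"].isin(candidates)].copy()
    sub["start"] = pd.to_datetime(sub["start"])
    sub["end"] = pd.to_datetime(sub["end"])
    if (sub["start"] > sub["end"]).any():
        raise ValueError("enrollment span with start > end")
    sub = sub[(sub["end"] >= a) & (sub["start"] <= b)]
    sub = sub.sort_values(["patient_id", "start"], kind="stable")
    one_day = pd.Timedelta(days=1)

    kept = set()
    for pid, grp in sub.groupby("patient_id", sort=False):
        cover_end = None
        for start, end in zip(grp["start"], grp["end"]):
            if cover_end is None:
                if start > a:
                    break
                cover_end = end
            elif start <= cover_end + one_day:
                cover_end = max(cover_end, end)
            else:
                break
            if cover_end >= b:
                kept.add(pid)
                break
    return kept


def exacerbation_counts(events: pd.DataFrame, windows: StudyWindows) -> pd.Series:
    """Exacerbations (ED visits + hospitalizations in the analysis window) per patient.

    Same-day ED visit and hospitalization count as two events.
    """
    dates = pd.to_datetime(events["date"])
    mask = (
        events["event_type"].isin(EXACERBATION_TYPES)
        & (dates >= pd.Timestamp(windows.analysis_start))
        & (dates <= pd.Timestamp(windows.analysis_end))
    )
    return events.loc[mask].groupby("patient_id").size()


def count_exacerbations(events: pd.DataFrame, windows: StudyWindows) -> int:
    """Exacerbation count for a single patient's events."""
    if events["patient_id"].nunique() > 1:
        raise ValueError("count_exacerbations expects one patient's events")
    counts = exacerbation_counts(events, windows)
    return int(counts.iloc[0]) if len(counts) else 0


@dataclass
class CohortResult:
    """Selected cohort plus the selection funnel counts."""

    patient_ids: set
    funnel: dict = field(default_factory=dict)


def build_cohort(
    events: pd.DataFrame,
    spans: pd.DataFrame,
    windows: StudyWindows,
    demographics: pd.DataFrame | None = None,
) -> CohortResult:
    """Run the identification/selection funnel and log counts at each step."""
    n_total = (
        int(demographics["patient_id"].nunique())
        if demographics is not None
        else int(
            pd.concat([events["patient_id"], spans["patient_id"]]).nunique()
        )
    )
    identified = identify_asthma_patients(events, windows)
    enrolled = filter_continuous_enrollment(identified, spans, windows)
    funnel = {
        "patients_in_database": n_total,
        "asthma_identified": len(identified),
        "continuously_enrolled": len(enrolled),
        "final_cohort": len(enrolled),
    }
    logger.info("cohort funnel: %s", funnel)
    return CohortResult(patient_ids=enrolled, funnel=funnel)
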