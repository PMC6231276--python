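"""Claims-based asthma severity grading.

Grades a patient-year into one of four ordered categories — mild
intermittent < mild persistent < moderate persistent < severe persistent —
from three administrative counts: SABA (short-acting beta-2-agonist) fills,
oral corticosteroid (OCS) fills, and exacerbations (emergency-department
visits or hospitalizations) during the analysis year.  The rules are a
Leidy-type claims algorithm: medication counts give one grade, exacerbation
counts give another, and the patient receives the worse of the two so that
severity is never under-assessed.

The medication grid as printed in the source rule set leaves one cell
uncovered (SABA <= 3 with exactly 2 OCS fills) and one rule garbled ("three
or more" fills for severe at any SABA count, which can only refer to OCS
fills).  Both repairs are the smallest completion that keeps the grid total
and monotone; :func:`truth_table` dumps the full grid for audit.
"""

from __future__ import annotations

import enum
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Severity",
    "classify_medication",
    "classify_exacerbation",
    "classify_severity",
    "classify_frame",
    "rule_region",
    "truth_table",
]


class Severity(enum.IntEnum):
    """Ordered four-level asthma severity category."""

    MILD_INTERMITTENT = 1
    MILD_PERSISTENT = 2
    MODERATE_PERSISTENT = 3
    SEVERE_PERSISTENT = 4

    @property
    def label(self) -> str:
        return self.name.lower()


def _check_counts(*counts: np.ndarray) -> None:
    for c in counts:
        if np.any(c < 0):
            raise ValueError("fill/exacerbation counts must be nonnegative")


def _medication_levels(saba: np.ndarray, ocs: np.ndarray) -> np.ndarray:
    """Vectorised medication grid, evaluated severe -> mild, first match wins."""
    severe = ((saba > 6) & (ocs >= 2)) | (ocs >= 3)
    moderate = (
        ((saba > 6) & (ocs < 2))
        | ((saba >= 4) & (saba <= 6) & (ocs >= 1) & (ocs <= 2))
        | ((saba <= 3) & (ocs == 2))  # gap completion, see module docstring
    )
    mild_persistent = (
        ((saba >= 4) & (saba <= 6) & (ocs == 0))
        | ((saba >= 2) & (saba <= 3) & (ocs <= 1))
        | ((saba <= 1) & (ocs == 1))
    )
    return np.select(
        [severe, moderate, mild_persistent], [4, 3, 2], default=1
    ).astype(np.int64)


def _exacerbation_levels(n: np.ndarray) -> np.ndarray:
    return np.select([n >= 4, n >= 2, n >= 1], [4, 3, 2], default=1).astype(np.int64)


def classify_medication(saba_fills: int, ocs_fills: int) -> Severity:
    """Severity implied by annual SABA and OCS fill counts alone."""
    saba = np.asarray(saba_fills)
    ocs = np.asarray(ocs_fills)
    _check_counts(saba, ocs)
    return Severity(int(_medication_levels(saba, ocs)))


def classify_exacerbation(n_exacerbations: int) -> Severity:
    """Severity implied by the annual exacerbation count alone.

    0 -> mild intermittent, 1 -> mild persistent, 2-3 -> moderate persistent,
    >=4 -> severe persistent.
    """
    n = np.asarray(n_exacerbations)
    _check_counts(n)
    return Severity(int(_exacerbation_levels(n)))


def classify_severity(
    saba_fills: int, ocs_fills: int, n_exacerbations: int
) -> Severity:
    """Combined grade: the maximum of the medication and exacerbation grades."""
    saba = np.asarray(saba_fills)
    ocs = np.asarray(ocs_fills)
    exac = np.asarray(n_exacerbations)
    _check_counts(saba, ocs, exac)
    return Severity(
        int(np.maximum(_medication_levels(saba, ocs), _exacerbation_levels(exac)))
    )


def classify_frame(
    profiles: pd.DataFrame,
    saba_col: str = "saba_fills",
    ocs_col: str = "ocs_fills",
    exac_col: str = "exacerbations",
) -> pd.Series:
    """Vectorised severity for a patient-year profile table (integer codes 1-4)."""
    saba = profiles[saba_col].to_numpy()
    ocs = profiles[ocs_col].to_numpy()
    exac = profiles[exac_col].to_numpy()
    _check_counts(saba, ocs, exac)
    levels = np.maximum(_medication_levels(saba, ocs), _exacerbation_levels(exac))
    return pd.Series(levels, index=profiles.index, name="severity")


def rule_region(
    level: int | Severity,
    saba_cap: int = 12,
    ocs_cap: int = 6,
    exac_cap: int = 6,
) -> np.ndarray:
    """All (saba, ocs, exacerbation) triples on the capped grid mapping to ``level``.

    The caps bound the enumeration only; the classifier itself is total on all
    of N^3.  Returns an (m, 3) integer array.
    """
    grid = truth_table(saba_cap, ocs_cap, exac_cap)
    sub = grid[grid["severity"] == int(level)]
    return sub[["saba_fills", "ocs_fills", "exacerbations"]].to_numpy()


def truth_table(
    saba_cap: int = 12, ocs_cap: int = 6, exac_cap: int = 6
) -> pd.DataFrame:
    """Exhaustive classification grid, for audit and for rule-region sampling."""
    saba, ocs, exac = np.meshgrid(
        np.arange(saba_cap + 1),
        np.arange(ocs_cap + 1),
        np.arange(exac_cap + 1),
        indexing="ij",
    )
    saba, ocs, exac = saba.ravel(), ocs.ravel(), exac.ravel()
    levels = np.maximum(_medication_levels(saba, ocs), _exacerbation_levels(exac))
    return pd.DataFrame(
        {
            "saba_fills": saba,
            "ocs_fills": ocs,
            "exacerbations": exac,
            "severity": levels,
            "label": [Severity(v).label for v in levels],
        }
    )
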