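"""Per-patient and per-stratum cost and utilization aggregation.

Costs are accumulated in COP (the billing currency) and converted to 2015
International Dollars once, at reporting time, by dividing by the PPP
exchange rate (1203.9 COP per I$ by default).  Mean costs are reported on
two bases: over *all* members of a severity stratum (zero-utilization
patients count in the denominator) and over users only.  ED visits and
hospitalizations are structurally impossible for mild-intermittent patients
(the classification requires zero exacerbations), so those cells carry a
structural-zero marker rather than a numeric zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import calibration as cal
from .config import ConfigurationError, StudyWindows
from .severity import Severity

__all__ = [
    "to_international_dollars",
    "build_patient_profiles",
    "category_cost_table",
    "utilization_table",
    "cost_distribution_shares",
    "sensitivity_exclusion",
    "overall_mean_from_cells",
    "total_annual_cost",
    "component_share",
    "category_contribution",
    "category_shares",
]

#: marker for cells that are structurally empty (not merely unobserved)
STRUCTURAL_ZERO = "-"

SERVICE_COMPONENTS = list(cal.SERVICE_TYPES)
MEDICATION_COMPONENTS = list(cal.MEDICATION_CLASSES)
ALL_COMPONENTS = SERVICE_COMPONENTS + MEDICATION_COMPONENTS

#: structurally-zero (component, severity-level) cells
_STRUCTURAL = {("ed_visit", 1), ("hospitalization", 1)}


def to_international_dollars(cost_cop, ppp_rate: float = cal.PPP_RATE_COP_PER_IUSD):
    """Convert COP amounts to International Dollars (linear, order-preserving)."""
    if ppp_rate <= 0:
        raise ConfigurationError("ppp_rate must be positive")
    return np.asarray(cost_cop, dtype=float) / ppp_rate if np.ndim(cost_cop) else float(cost_cop) / ppp_rate


def build_patient_profiles(
    events: pd.DataFrame,
    fills: pd.DataFrame,
    severity: pd.Series,
    windows: StudyWindows,
    ppp_rate: float = cal.PPP_RATE_COP_PER_IUSD,
) -> pd.DataFrame:
    """One patient-year profile per cohort patient.

    ``severity`` is an integer Series (1-4) indexed by patient id; its index
    defines the cohort.  Events/fills outside the analysis window or
    referencing non-cohort patients are dropped (the latter are logged by
    count in the returned frame's ``attrs``).  Zero-utilization patients get
    explicit zero counts and costs.

    Returns a DataFrame indexed by patient id with ``n_<component>`` count
    columns, ``cost_<component>`` columns (I$), ``saba_fills``,
    ``ocs_fills``, ``exacerbations``, ``any_service_cost``,
    ``any_medication_cost`` and ``total_cost`` (I$).
    """
    cohort = severity.index
    a, b = pd.Timestamp(windows.analysis_start), pd.Timestamp(windows.analysis_end)

    def _window(df):
        d = pd.to_datetime(df["date"])
        return df[(d >= a) & (d <= b)]

    ev = _window(events)
    fl = _window(fills)
    n_foreign = int((~ev["patient_id"].isin(cohort)).sum()) + int(
        (~fl["patient_id"].isin(cohort)).sum()
    )
    ev = ev[ev["patient_id"].isin(cohort)]
    fl = fl[fl["patient_id"].isin(cohort)]

    prof = pd.DataFrame(index=pd.Index(cohort, name="patient_id"))
    prof["severity"] = severity.astype(int)

    def _agg(df, type_col, components):
        cnt = (
            df.pivot_table(
                index="patient_id", columns=type_col, values="cost_cop",
                aggfunc="size", fill_value=0,
            )
            .reindex(index=cohort, columns=components, fill_value=0)
        )
        cop = (
            df.pivot_table(
                index="patient_id", columns=type_col, values="cost_cop",
                aggfunc="sum", fill_value=0.0,
            )
            .reindex(index=cohort, columns=components, fill_value=0.0)
        )
        return cnt, cop

    ev_cnt, ev_cop = _agg(ev, "event_type", SERVICE_COMPONENTS)
    fl_cnt, fl_cop = _agg(fl, "med_class", MEDICATION_COMPONENTS)

    for comp in SERVICE_COMPONENTS:
        prof[f"n_{comp}"] = ev_cnt[comp].astype(int)
    for comp in MEDICATION_COMPONENTS:
        prof[f"n_{comp}"] = fl_cnt[comp].astype(int)
    # convert once, after summation in COP
    for comp in SERVICE_COMPONENTS:
        prof[f"cost_{comp}"] = ev_cop[comp] / ppp_rate
    for comp in MEDICATION_COMPONENTS:
        prof[f"cost_{comp}"] = fl_cop[comp] / ppp_rate

    prof["saba_fills"] = prof["n_SABA"]
    prof["ocs_fills"] = prof["n_OCS"]
    prof["exacerbations"] = prof["n_ed_visit"] + prof["n_hospitalization"]
    prof["any_service_cost"] = sum(prof[f"cost_{c}"] for c in SERVICE_COMPONENTS)
    prof["any_medication_cost"] = sum(prof[f"cost_{c}"] for c in MEDICATION_COMPONENTS)
    prof["total_cost"] = prof["any_service_cost"] + prof["any_medication_cost"]
    prof.attrs["n_foreign_records_skipped"] = n_foreign
    return prof


def _stats(values: np.ndarray) -> dict:
    if len(values) == 0:
        return {"mean": np.nan, "sd": np.nan, "median": np.nan, "iqr": np.nan}
    q75, q25 = np.percentile(values, [75, 25])
    return {
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        "median": float(np.median(values)),
        "iqr": float(q75 - q25),
    }


_SUMMARY_ROWS = (
    ("any_service", "any_service_cost"),
    ("any_medication", "any_medication_cost"),
    ("total", "total_cost"),
)


def category_cost_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-(component x severity) cost cells, all-members and users-only.

    Rows: each service, each medication class, plus per-patient sums
    ``any_service``, ``any_medication`` and ``total``.  Empty strata yield
    NaN cells; structurally impossible cells are flagged.
    """
    rows = []
    strata = [(int(s), grp) for s, grp in profiles.groupby("severity")]
    strata.append(("all", profiles))
    for comp in ALL_COMPONENTS + [name for name, _ in _SUMMARY_ROWS]:
        col = dict(_SUMMARY_ROWS).get(comp, f"cost_{comp}")
        user_col = f"n_{comp}" if comp in ALL_COMPONENTS else None
        for s, grp in strata:
            vals = grp[col].to_numpy()
            if user_col is not None:
                users = grp[grp[user_col] > 0][col].to_numpy()
            else:
                users = grp[grp[col] > 0][col].to_numpy()
            rec = {
                "component": comp,
                "severity": s,
                "n": len(grp),
                "n_users": int(len(users)),
                "structural_zero": (comp, s) in _STRUCTURAL,
            }
            rec.update({f"{k}_all": v for k, v in _stats(vals).items()})
            rec.update({f"{k}_users": v for k, v in _stats(users).items()})
            rows.append(rec)
    return pd.DataFrame(rows)


def utilization_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Users, user percentage and events-per-user per (component x severity).

    Percentages use the stratum size as denominator; event counts are
    summarised among users only.
    """
    rows = []
    strata = [(int(s), grp) for s, grp in profiles.groupby("severity")]
    strata.append(("all", profiles))
    for comp in ALL_COMPONENTS:
        for s, grp in strata:
            n = len(grp)
            counts = grp[f"n_{comp}"].to_numpy()
            users = counts[counts > 0]
            rows.append(
                {
                    "component": comp,
                    "severity": s,
                    "n": n,
                    "n_users": int(len(users)),
                    "pct_users": 100.0 * len(users) / n if n else np.nan,
                    "mean_events_users": float(users.mean()) if len(users) else np.nan,
                    "sd_events_users": float(users.std(ddof=1)) if len(users) > 1 else (0.0 if len(users) else np.nan),
                    "structural_zero": (comp, s) in _STRUCTURAL,
                }
            )
    return pd.DataFrame(rows)


def cost_distribution_shares(table: pd.DataFrame) -> pd.DataFrame:
    """Percentage of total cost per component, within stratum and overall.

    Input is the output of :func:`category_cost_table`.  Shares over the
    twelve elementary components sum to 100 within rounding; a zero-total
    stratum yields NaN shares.
    """
    out = []
    for s in table["severity"].unique():
        sub = table[table["severity"] == s].set_index("component")
        total = sub.loc["total", "mean_all"] * sub.loc["total", "n"]
        for comp in ALL_COMPONENTS:
            contrib = sub.loc[comp, "mean_all"] * sub.loc[comp, "n"]
            out.append(
                {
                    "severity": s,
                    "component": comp,
                    "share_pct": 100.0 * contrib / total if total else np.nan,
                }
            )
    return pd.DataFrame(out)


def sensitivity_exclusion(
    profiles: pd.DataFrame,
    demographics: pd.DataFrame,
    excluded_comorbidities: tuple = ("rhinitis", "atopic_eczema", "acute_bronchitis", "emphysema", "copd"),
    age_bands: tuple = ((45, 59), (60, 200), (0, 4)),
) -> dict:
    """Comorbidity-exclusion sensitivity analysis.

    Drops every patient carrying any of the listed comorbidity flags,
    recomputes the total and per-age-band mean costs, and reports absolute
    and percentage changes.  An empty reduced cohort is flagged rather than
    an error.
    """
    demo = demographics.set_index("patient_id").reindex(profiles.index)
    flags = [c for c in excluded_comorbidities if c in demo.columns]
    excluded = demo[flags].fillna(0).astype(float).sum(axis=1) > 0 if flags else pd.Series(False, index=profiles.index)
    reduced = profiles[~excluded.to_numpy()]

    total_before = float(profiles["total_cost"].sum())
    total_after = float(reduced["total_cost"].sum())
    report = {
        "n_before": len(profiles),
        "n_after": len(reduced),
        "n_excluded": int(excluded.sum()),
        "total_before": total_before,
        "total_after": total_after,
        "total_change_pct": (
            100.0 * (total_after - total_before) / total_before if total_before else np.nan
        ),
        "empty_cohort": len(reduced) == 0,
        "age_subgroups": [],
    }
    ages = demo["age"]
    for lo, hi in age_bands:
        band = (ages >= lo) & (ages < hi + 1)
        before = profiles.loc[band.to_numpy(), "total_cost"]
        after = profiles.loc[(band & ~excluded).to_numpy(), "total_cost"]
        mb = float(before.mean()) if len(before) else np.nan
        ma = float(after.mean()) if len(after) else np.nan
        report["age_subgroups"].append(
            {
                "band": f"{lo}-{hi}",
                "mean_before": mb,
                "mean_after": ma,
                "mean_change_pct": 100.0 * (ma - mb) / mb if mb else np.nan,
            }
        )
    return report


# ---------------------------------------------------------------------------
# Printed-table identity routines: aggregates recomputable from stratum sizes
# and per-stratum means alone (weighted-mean identities).
# ---------------------------------------------------------------------------

def overall_mean_from_cells(sizes, means) -> float:
    """Overall mean from stratum sizes and stratum means: sum(n*m)/sum(n)."""
    sizes = np.asarray(sizes, dtype=float)
    means = np.asarray(means, dtype=float)
    return float((sizes * means).sum() / sizes.sum())


def total_annual_cost(sizes, means) -> float:
    """Cohort-wide annual cost: sum of stratum size x stratum mean."""
    sizes = np.asarray(sizes, dtype=float)
    means = np.asarray(means, dtype=float)
    return float((sizes * means).sum())


def component_share(sizes, component_means, total_means) -> float:
    """Component's percentage of total cohort cost."""
    return 100.0 * total_annual_cost(sizes, component_means) / total_annual_cost(
        sizes, total_means
    )


def category_contribution(sizes, total_means, level: int | Severity) -> float:
    """One stratum's percentage contribution to total cohort cost."""
    sizes = np.asarray(sizes, dtype=float)
    means = np.asarray(total_means, dtype=float)
    i = int(level) - 1
    return float(100.0 * sizes[i] * means[i] / (sizes * means).sum())


def category_shares(sizes) -> np.ndarray:
    """Stratum shares of the cohort, in percent."""
    sizes = np.asarray(sizes, dtype=float)
    return 100.0 * sizes / sizes.sum()
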