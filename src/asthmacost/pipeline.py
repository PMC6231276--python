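"""End-to-end orchestration: simulate -> select -> classify -> cost -> stats.

Each stage is a pure function of its inputs plus the configuration; the run
directory receives every intermediate table as CSV so any stage can be
re-run and audited independently, plus a machine-readable ``manifest.json``
that is byte-identical across runs with the same config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import costs as cost_engine
from . import stats as st
from .cohort import build_cohort, exacerbation_counts
from .config import PipelineConfig
from .model import AsthmaCostModel, univariate_screen
from .severity import classify_frame
from .simulate import generate_cohort, write_claims_tables

__all__ = ["run_pipeline", "PipelineResult"]


@dataclass
class PipelineResult:
    output_dir: Path
    funnel: dict
    profiles: pd.DataFrame
    demographics: pd.DataFrame
    cost_table: pd.DataFrame
    utilization: pd.DataFrame
    shares: pd.DataFrame
    glm_results: object
    sensitivity: dict
    manifest: dict


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write the report bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # 1. simulate
    pop = generate_cohort(config.generator)
    write_claims_tables(pop, out / "claims")

    # 2. cohort selection
    windows = config.windows
    cohort = build_cohort(pop.events, pop.enrollment, windows, pop.demographics)
    ids = sorted(cohort.patient_ids)

    # 3. classification from observed analysis-year counts
    fills = pop.fills[pop.fills["patient_id"].isin(cohort.patient_ids)]
    in_year = (
        (pd.to_datetime(fills["date"]) >= pd.Timestamp(windows.analysis_start))
        & (pd.to_datetime(fills["date"]) <= pd.Timestamp(windows.analysis_end))
    )
    fl = fills[in_year.to_numpy()]
    counts = pd.DataFrame(index=pd.Index(ids, name="patient_id"))
    by_class = fl.groupby(["patient_id", "med_class"]).size().unstack(fill_value=0)
    counts["saba_fills"] = by_class.get("SABA", 0)
    counts["ocs_fills"] = by_class.get("OCS", 0)
    counts = counts.fillna(0).astype(int)
    counts["exacerbations"] = (
        exacerbation_counts(
            pop.events[pop.events["patient_id"].isin(cohort.patient_ids)], windows
        )
        .reindex(counts.index)
        .fillna(0)
        .astype(int)
    )
    severity = classify_frame(counts)

    # 4. cost engine
    profiles = cost_engine.build_patient_profiles(
        pop.events, pop.fills, severity, windows, config.ppp_rate
    )
    cost_table = cost_engine.category_cost_table(profiles)
    utilization = cost_engine.utilization_table(profiles)
    shares = cost_engine.cost_distribution_shares(cost_table)

    # 5. statistics
    groups = [
        profiles.loc[profiles["severity"] == s, "total_cost"].to_numpy()
        for s in (1, 2, 3, 4)
        if (profiles["severity"] == s).sum() >= 2
    ]
    omnibus = st.welch_anova(groups) if len(groups) >= 2 else None
    posthoc = st.games_howell(groups) if len(groups) >= 2 else None

    model = AsthmaCostModel.from_profiles(
        profiles, pop.demographics, covariates=config.glm_covariates
    )
    glm = model.fit()
    screen = univariate_screen(
        model.data,
        candidates=[c for c in config.glm_covariates if c not in ("age", "female", "sisben_level1")]
        + ["severity"],
        alpha=config.screen_alpha,
    )

    # 6. sensitivity
    sensitivity = cost_engine.sensitivity_exclusion(
        profiles, pop.demographics, config.excluded_comorbidities
    )

    # 7. report bundle
    profiles.to_csv(out / "profiles.csv")
    cost_table.to_csv(out / "cost_table.csv", index=False)
    utilization.to_csv(out / "utilization_table.csv", index=False)
    shares.to_csv(out / "cost_shares.csv", index=False)
    glm.cost_ratios.to_csv(out / "glm_cost_ratios.csv")
    screen.table.to_csv(out / "univariate_screen.csv", index=False)
    (out / "funnel.json").write_text(json.dumps(_jsonable(cohort.funnel), indent=2))
    (out / "sensitivity.json").write_text(json.dumps(_jsonable(sensitivity), indent=2))
    if config.make_plots:
        from .plots import plot_cost_shares

        plot_cost_shares(shares, out / "cost_shares.png")

    sizes = profiles["severity"].value_counts().sort_index()
    total_row = cost_table[(cost_table["component"] == "total")]
    manifest = {
        "seed": config.seed,
        "n_generated": config.generator.n_patients,
        "funnel": cohort.funnel,
        "category_sizes": {int(s): int(c) for s, c in sizes.items()},
        "category_shares_pct": {
            int(s): float(100.0 * c / sizes.sum()) for s, c in sizes.items()
        },
        "category_mean_total_cost": {
            int(r["severity"]): float(r["mean_all"])
            for _, r in total_row.iterrows()
            if r["severity"] != "all"
        },
        "overall_mean_total_cost": float(
            total_row.loc[total_row["severity"] == "all", "mean_all"].iloc[0]
        ),
        "welch_anova": dict(omnibus._asdict()) if omnibus else None,
        "glm_cost_ratios": {
            term: float(v)
            for term, v in glm.cost_ratios["cost_ratio"].items()
        },
        "glm_n_used": glm.n_used,
        "glm_exclusions": glm.exclusions,
        "sensitivity_total_change_pct": sensitivity["total_change_pct"],
    }
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True))

    return PipelineResult(
        output_dir=out,
        funnel=cohort.funnel,
        profiles=profiles,
        demographics=pop.demographics,
        cost_table=cost_table,
        utilization=utilization,
        shares=shares,
        glm_results=glm,
        sensitivity=sensitivity,
        manifest=manifest,
    )
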