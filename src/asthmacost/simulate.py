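"""Synthetic insurance-claims generator.

Emulates the person-level claims extract of a subsidized-regime insurer for
a single cost-analysis year: demographics, enrollment spans, billed medical
events and medication fills, plus a held-out true-labels table for recovery
tests.  The real billing database is proprietary, so every downstream stage
of the pipeline is exercised against this generator.

Design in brief
---------------
* Each patient draws a severity category from the configured mixture, then a
  (SABA fills, OCS fills, exacerbations) triple uniformly from that
  category's *rule region* — the set of count triples the classifier maps to
  the category — so classification round-trips exactly.
* Utilization of the remaining services and medication classes is
  Bernoulli(p) per component with count 1 + Poisson(lambda) among users.
* Costs are generated at event level from gamma distributions whose
  parameters are solved by method of moments so that the *patient-year*
  component totals reproduce the configured per-(severity x component) cost
  cells in mean and (where the count process allows) SD.
* A multiplicative covariate effect structure (comorbidities, residency,
  socio-economic level, sex) is embedded as the ground truth of the
  positive-cost conditional mean, anchored so the severe-persistent
  stratum's all-members mean total cost equals its configured value; see
  docs/methods.md for why a multiplicative process cannot pin all four
  unadjusted category means and the adjusted ratios simultaneously.

Everything is deterministic for a fixed config + seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigurationError, GeneratorConfig
from . import calibration as cal
from .severity import rule_region

__all__ = [
    "Calibration",
    "SyntheticPopulation",
    "generate_cohort",
    "write_claims_tables",
    "read_claims_tables",
]

_ICD_CODES = np.array(["J45.0", "J45.1", "J45.8", "J45.9", "J46"])
_ICD_WEIGHTS = np.array([0.15, 0.15, 0.10, 0.50, 0.10])

#: components whose counts come from the severity rule region
_REGION_COMPONENTS = ("SABA", "OCS", "ed_visit", "hospitalization")


def _bern_poisson_moments(p: float, lam: float) -> tuple[float, float]:
    """Mean/variance of N = Bernoulli(p) * (1 + Poisson(lam))."""
    m1 = 1.0 + lam
    m2 = lam + m1 * m1  # E[(1+P)^2]
    mean = p * m1
    return mean, p * m2 - mean * mean


@dataclass
class Calibration:
    """Analytic quantities derived from a :class:`GeneratorConfig`.

    Computed once per generation: rule regions, count moments per
    (severity, component), per-event gamma parameters, the expected
    covariate cost multiplier per stratum, the probability of a positive
    annual total, and the per-stratum scale factors that anchor the effect
    structure (see module docstring).
    """

    config: GeneratorConfig

    def __post_init__(self) -> None:
        cfg = self.config
        self.regions = [
            rule_region(s, cfg.saba_cap, cfg.ocs_cap, cfg.exac_cap) for s in (1, 2, 3, 4)
        ]
        self.count_moments: list[dict] = []
        for s in range(4):
            reg = self.regions[s]
            q = cfg.ed_fraction_of_exacerbations[s]
            saba, ocs, exac = reg[:, 0], reg[:, 1], reg[:, 2]
            mom = {
                "SABA": (saba.mean(), saba.var()),
                "OCS": (ocs.mean(), ocs.var()),
                "ed_visit": (
                    q * exac.mean(),
                    q * q * exac.var() + q * (1 - q) * exac.mean(),
                ),
                "hospitalization": (
                    (1 - q) * exac.mean(),
                    (1 - q) ** 2 * exac.var() + q * (1 - q) * exac.mean(),
                ),
            }
            for comp, probs in cfg.utilization_probs.items():
                mom[comp] = _bern_poisson_moments(
                    probs[s], cfg.extra_events_poisson_mean
                )
            self.count_moments.append(mom)

        self.mean_ratio = np.array(
            [self._expected_multiplier(s) for s in range(4)]
        )
        self.p_positive = np.array([self._positive_prob(s) for s in range(4)])
        self.base_totals = np.array(
            [sum(c[s][0] for c in cfg.cost_cells.values()) for s in range(4)]
        )
        if getattr(cfg, "calibrate_effects", True):
            ratios = np.asarray(cfg.severity_ratios, dtype=float)
            anchor = 3  # severe persistent stratum anchors the scale
            beta0 = self.base_totals[anchor] / (
                ratios[anchor] * self.mean_ratio[anchor] * self.p_positive[anchor]
            )
            targets = beta0 * ratios * self.mean_ratio * self.p_positive
            with np.errstate(invalid="ignore", divide="ignore"):
                self.scale = np.where(
                    self.base_totals > 0, targets / self.base_totals, 1.0
                )
            self.category_mean_targets = targets
        else:
            self.scale = np.ones(4)
            self.category_mean_targets = self.base_totals.copy()
        self._event_params = {
            (s, comp): self._per_event_params(s, comp)
            for s in range(4)
            for comp in cfg.cost_cells
        }

    # -- effect structure ---------------------------------------------------

    def _age_factor(self, s: int) -> float:
        rho = self.config.effect_ratios.get("age", 1.0)
        if rho == 1.0:
            return 1.0
        bands = cal.age_band_matrix()[:, s]
        total = 0.0
        for (a, b), p in zip(cal.AGE_BANDS, bands):
            hi = b + 1.0
            total += p * (rho**hi - rho**a) / ((hi - a) * math.log(rho))
        return total

    def _expected_multiplier(self, s: int) -> float:
        """E[covariate cost multiplier | severity s] under the generator."""
        cfg = self.config
        r = self._age_factor(s)
        er = cfg.effect_ratios

        def bern(p, rho):
            return 1.0 + (rho - 1.0) * p

        r *= bern(cfg.female_prob[s], er.get("female", 1.0))
        r *= bern(cfg.urban_prob[s], er.get("urban", 1.0))
        _, sis = cal.sisben_matrix()
        levels = list(cfg.sisben_probs)
        p1 = np.array([cfg.sisben_probs[k][s] for k in levels], dtype=float)
        p1 = p1 / p1.sum()
        p_level1 = p1[levels.index("1")] if "1" in levels else 0.0
        r *= bern(p_level1, er.get("sisben_level1", 1.0))
        for name, prev in cfg.comorbidity_prevalence.items():
            r *= bern(prev[s], er.get(name, 1.0))
        return r

    def _positive_prob(self, s: int) -> float:
        """P(annual total cost > 0 | severity s)."""
        cfg = self.config
        reg = self.regions[s]
        cells = cfg.cost_cells
        saba_costed = cells["SABA"][s][0] > 0
        ocs_costed = cells["OCS"][s][0] > 0
        exac_costed = cells["ed_visit"][s][0] > 0 or cells["hospitalization"][s][0] > 0
        row_zero = (
            ((reg[:, 0] == 0) | (not saba_costed))
            & ((reg[:, 1] == 0) | (not ocs_costed))
            & ((reg[:, 2] == 0) | (not exac_costed))
        )
        p0 = row_zero.mean()
        for comp, probs in cfg.utilization_probs.items():
            if cells[comp][s][0] > 0:
                p0 *= 1.0 - probs[s]
        return 1.0 - p0

    # -- per-event gamma parameters ----------------------------------------

    def _per_event_params(self, s: int, comp: str):
        """(mu_event, sd_event) calibrated so patient-year moments match."""
        cfg = self.config
        mean, sd = cfg.cost_cells[comp][s]
        mean, sd = mean * self.scale[s], sd * self.scale[s]
        basis = getattr(cfg, "cost_cell_basis", "patient_year")
        if basis == "per_event":
            return mean, sd
        en, vn = self.count_moments[s][comp]
        if mean == 0:
            return 0.0, 0.0
        if en == 0:
            raise ConfigurationError(
                f"component {comp!r} has positive cost but zero expected "
                f"utilization in stratum {s + 1}"
            )
        mu_e = mean / en
        if sd == 0:
            return mu_e, 0.0
        var_e = (sd * sd - vn * mu_e * mu_e) / en
        var_e = max(var_e, (0.2 * mu_e) ** 2)  # CV floor when counts dominate
        return mu_e, math.sqrt(var_e)

    def event_params(self, severity: int, comp: str):
        """Per-event (mean, SD) in I$ for a severity level 1-4."""
        return self._event_params[(severity - 1, comp)]

    def effective_cell_mean(self, severity: int, comp: str) -> float:
        """Configured cell mean after stratum anchoring (I$, all-members)."""
        return self.config.cost_cells[comp][severity - 1][0] * self.scale[severity - 1]


@dataclass
class SyntheticPopulation:
    """A generated population plus its held-out ground truth."""

    demographics: pd.DataFrame
    enrollment: pd.DataFrame
    events: pd.DataFrame
    fills: pd.DataFrame
    true_labels: pd.DataFrame
    config: GeneratorConfig
    calibration: Calibration

    def validate(self) -> None:
        ids = set(self.demographics["patient_id"])
        for name in ("events", "fills", "enrollment", "true_labels"):
            tab = getattr(self, name)
            if not set(tab["patient_id"]).issubset(ids):
                raise ValueError(f"{name} references unknown patient ids")
        if len(self.true_labels) != len(ids):
            raise ValueError("true_labels must cover every patient exactly once")


def _year_start(year: int) -> np.datetime64:
    return np.datetime64(f"{year}-01-01")


def _days_in(year0: int, year1: int) -> int:
    return (date(year1 + 1, 1, 1) - date(year0, 1, 1)).days


def _draw_costs(rng, mu: float, sd: float, n: int) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    if mu == 0:
        return np.zeros(n)
    if sd == 0:
        return np.full(n, mu)
    shape = (mu / sd) ** 2
    return rng.gamma(shape, sd * sd / mu, size=n)


def generate_cohort(config: GeneratorConfig) -> SyntheticPopulation:
    """Generate a synthetic population per the configured study conditions."""
    config.validate()
    calib = Calibration(config)
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    width = max(6, len(str(n)))
    pids = np.array([f"P{i:0{width}d}" for i in range(1, n + 1)])

    sev = rng.choice(4, size=n, p=np.asarray(config.severity_mixture)) + 1

    # counts from the rule region: classification round-trips by construction
    saba = np.zeros(n, dtype=np.int64)
    ocs = np.zeros(n, dtype=np.int64)
    exac = np.zeros(n, dtype=np.int64)
    for s in range(4):
        mask = sev == s + 1
        reg = calib.regions[s]
        idx = rng.integers(0, len(reg), size=int(mask.sum()))
        saba[mask], ocs[mask], exac[mask] = reg[idx].T

    # demographics
    age = np.empty(n)
    band_mat = cal.age_band_matrix()
    bands = np.asarray(cal.AGE_BANDS, dtype=float)
    for s in range(4):
        mask = sev == s + 1
        k = int(mask.sum())
        bi = rng.choice(len(bands), size=k, p=band_mat[:, s])
        lo, hi = bands[bi, 0], bands[bi, 1] + 1.0
        age[mask] = np.round(lo + rng.random(k) * (hi - lo), 1)
    female = (rng.random(n) < np.asarray(config.female_prob)[sev - 1]).astype(float)
    urban = (rng.random(n) < np.asarray(config.urban_prob)[sev - 1]).astype(int)
    sis_levels = list(config.sisben_probs)
    sis_mat = np.array([config.sisben_probs[k] for k in sis_levels], dtype=float)
    sis_mat = sis_mat / sis_mat.sum(axis=0, keepdims=True)
    sisben = np.empty(n, dtype=object)
    for s in range(4):
        mask = sev == s + 1
        sisben[mask] = np.array(sis_levels, dtype=object)[
            rng.choice(len(sis_levels), size=int(mask.sum()), p=sis_mat[:, s])
        ]
    comorb = {
        name: (rng.random(n) < np.asarray(prev)[sev - 1]).astype(int)
        for name, prev in config.comorbidity_prevalence.items()
    }
    sex_missing = rng.random(n) < config.missing_sex_fraction

    # ground-truth multiplicative cost multiplier
    er = config.effect_ratios
    r = np.ones(n)
    r *= er.get("age", 1.0) ** age
    r *= np.where(female == 1, er.get("female", 1.0), 1.0)
    r *= np.where(urban == 1, er.get("urban", 1.0), 1.0)
    r *= np.where(sisben == "1", er.get("sisben_level1", 1.0), 1.0)
    for name, flags in comorb.items():
        r *= np.where(flags == 1, er.get(name, 1.0), 1.0)
    # stratum anchoring (calib.scale) is already folded into the per-event
    # cost parameters; g carries only the patient-level covariate effect
    if config.calibrate_effects:
        g = r / calib.mean_ratio[sev - 1]
    else:
        g = r.copy()

    # eligibility: a stated fraction fails selection (coverage gap or no
    # identification-window asthma event), split evenly between the two modes
    inel = rng.random(n) < config.ineligible_fraction
    gap_mode = rng.random(n) < 0.5
    has_gap = inel & gap_mode
    no_id = inel & ~gap_mode
    eligible = ~inel
    split_span = eligible & (rng.random(n) < config.split_span_fraction)

    # per-patient counts for Bernoulli-Poisson components
    counts: dict[str, np.ndarray] = {}
    for comp, probs in config.utilization_probs.items():
        user = rng.random(n) < np.asarray(probs)[sev - 1]
        extra = rng.poisson(config.extra_events_poisson_mean, size=n)
        counts[comp] = np.where(user, 1 + extra, 0).astype(np.int64)
    q = np.asarray(config.ed_fraction_of_exacerbations)[sev - 1]
    counts["ed_visit"] = rng.binomial(exac, q)
    counts["hospitalization"] = exac - counts["ed_visit"]
    counts["SABA"] = saba
    counts["OCS"] = ocs

    # event/fill emission, in I$ then stored as COP
    year = config.analysis_year
    ydays = _days_in(year, year)
    y0 = _year_start(year)
    ev_parts, fill_parts = [], []
    for comp in config.cost_cells:
        is_service = comp in cal.SERVICE_TYPES
        for s in range(4):
            mask = sev == s + 1
            c = counts[comp][mask]
            total = int(c.sum())
            if total == 0:
                continue
            mu_e, sd_e = calib.event_params(s + 1, comp)
            costs = _draw_costs(rng, mu_e, sd_e, total) * np.repeat(g[mask], c)
            dates = y0 + rng.integers(0, ydays, size=total).astype("timedelta64[D]")
            part = pd.DataFrame(
                {
                    "patient_id": np.repeat(pids[mask], c),
                    "date": dates,
                    "cost_cop": costs * config.ppp_rate,
                }
            )
            if is_service:
                part["event_type"] = comp
                part["icd10_codes"] = rng.choice(
                    _ICD_CODES, size=total, p=_ICD_WEIGHTS
                )
                ev_parts.append(part)
            else:
                part["med_class"] = comp
                fill_parts.append(part)

    # identification-window event (absent for the 'no_id' ineligible mode,
    # who instead carry a pre-window record the cohort builder must reject)
    id0, id1 = config.identification_years
    id_days = _days_in(id0, id1)
    id_dates = _year_start(id0) + rng.integers(0, id_days, size=n).astype(
        "timedelta64[D]"
    )
    id_dates = np.where(
        no_id, np.datetime64(f"{id0 - 1}-06-15"), id_dates
    )
    id_cost = _draw_costs(rng, 25.0, 15.0, n) * config.ppp_rate
    id_events = pd.DataFrame(
        {
            "patient_id": pids,
            "date": id_dates,
            "cost_cop": id_cost,
            "event_type": "general_physician_visit",
            "icd10_codes": rng.choice(_ICD_CODES, size=n, p=_ICD_WEIGHTS),
        }
    )
    ev_parts.append(id_events)

    events = pd.concat(ev_parts, ignore_index=True) if ev_parts else pd.DataFrame(
        columns=["patient_id", "date", "cost_cop", "event_type", "icd10_codes"]
    )
    events = events[["patient_id", "date", "event_type", "icd10_codes", "cost_cop"]]
    fills = (
        pd.concat(fill_parts, ignore_index=True)
        if fill_parts
        else pd.DataFrame(columns=["patient_id", "date", "cost_cop", "med_class"])
    )
    fills = fills[["patient_id", "date", "med_class", "cost_cop"]]
    events = events.sort_values(["patient_id", "date", "event_type"], kind="stable").reset_index(drop=True)
    fills = fills.sort_values(["patient_id", "date", "med_class"], kind="stable").reset_index(drop=True)

    # enrollment spans: full coverage of the analysis year, optionally split
    # into adjacent spans; the 'gap' ineligible mode loses June
    cov_start = np.datetime64(f"{year - 1}-01-01")
    cov_end = np.datetime64(f"{year}-12-31")
    june_pre = np.datetime64(f"{year}-05-31")
    july = np.datetime64(f"{year}-07-01")
    june_full = np.datetime64(f"{year}-06-30")
    spans = []
    one = ~(has_gap | split_span)
    spans.append(pd.DataFrame({"patient_id": pids[one], "start": cov_start, "end": cov_end}))
    spans.append(pd.DataFrame({"patient_id": pids[split_span], "start": cov_start, "end": june_full}))
    spans.append(pd.DataFrame({"patient_id": pids[split_span], "start": july, "end": cov_end}))
    spans.append(pd.DataFrame({"patient_id": pids[has_gap], "start": cov_start, "end": june_pre}))
    spans.append(pd.DataFrame({"patient_id": pids[has_gap], "start": july, "end": cov_end}))
    enrollment = (
        pd.concat(spans, ignore_index=True)
        .sort_values(["patient_id", "start"], kind="stable")
        .reset_index(drop=True)
    )
    enrollment["start"] = enrollment["start"].astype("datetime64[s]")
    enrollment["end"] = enrollment["end"].astype("datetime64[s]")

    demographics = pd.DataFrame(
        {
            "patient_id": pids,
            "age": age,
            "female": np.where(sex_missing, np.nan, female),
            "sisben_level": sisben,
            "urban": urban,
            **comorb,
        }
    )
    true_labels = pd.DataFrame(
        {
            "patient_id": pids,
            "severity": sev,
            "saba_fills": saba,
            "ocs_fills": ocs,
            "exacerbations": exac,
            "eligible": eligible,
            "cost_multiplier": g,
        }
    )

    pop = SyntheticPopulation(
        demographics=demographics,
        enrollment=enrollment,
        events=events,
        fills=fills,
        true_labels=true_labels,
        config=config,
        calibration=calib,
    )
    pop.validate()
    return pop


_TABLE_FILES = {
    "demographics": "demographics.csv",
    "enrollment": "enrollment.csv",
    "events": "events.csv",
    "fills": "fills.csv",
    "true_labels": "true_labels.csv",
}


def write_claims_tables(population: SyntheticPopulation, destination: str | Path) -> dict:
    """Write the five delimited-text tables; returns {table name: path}."""
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, fname in _TABLE_FILES.items():
        df = getattr(population, name).copy()
        for col in df.columns:
            if np.issubdtype(df[col].dtype, np.datetime64):
                df[col] = df[col].dt.strftime("%Y-%m-%d")
        path = dest / fname
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


def read_claims_tables(source: str | Path) -> dict[str, pd.DataFrame]:
    """Read back the claims tables written by :func:`write_claims_tables`."""
    src = Path(source)
    out = {}
    date_cols = {"enrollment": ["start", "end"], "events": ["date"], "fills": ["date"]}
    for name, fname in _TABLE_FILES.items():
        path = src / fname
        if not path.exists():
            continue
        df = pd.read_csv(path, parse_dates=date_cols.get(name, False))
        out[name] = df
    return out
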