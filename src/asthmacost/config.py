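"""Configuration objects for the generator and the end-to-end pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import yaml

from . import calibration as cal


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class StudyWindows:
    """Identification window (cohort entry) and cost-analysis window.

    Defaults: patients identified 2004-01-01..2014-12-31 by an asthma-coded
    medical event, costs analysed over calendar year 2015.  Both interval
    ends are inclusive.
    """

    identification_start: date = date(2004, 1, 1)
    identification_end: date = date(2014, 12, 31)
    analysis_start: date = date(2015, 1, 1)
    analysis_end: date = date(2015, 12, 31)

    def __post_init__(self) -> None:
        if not (self.identification_start <= self.identification_end):
            raise ConfigurationError("identification window is empty")
        if not (self.analysis_start <= self.analysis_end):
            raise ConfigurationError("analysis window is empty")
        if not (self.identification_end < self.analysis_start):
            raise ConfigurationError(
                "identification window must precede the analysis window"
            )


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic claims generator.

    The defaults are the study conditions the package is calibrated to: a
    20,410-patient 2015 subsidized-regime cohort (severity mixture,
    demographic margins, per-cell cost moments, effect ratios).  ``n_patients``
    and ``seed`` are the knobs a caller normally touches.
    """

    n_patients: int = 20410
    seed: int = 0
    analysis_year: int = 2015
    identification_years: tuple[int, int] = (2004, 2014)
    ppp_rate: float = cal.PPP_RATE_COP_PER_IUSD

    severity_mixture: tuple[float, float, float, float] = cal.SEVERITY_MIXTURE

    age_band_probs: dict = field(default_factory=lambda: dict(cal.AGE_BAND_PROBS))
    female_prob: tuple = cal.FEMALE_PROB
    urban_prob: tuple = cal.URBAN_PROB
    sisben_probs: dict = field(default_factory=lambda: dict(cal.SISBEN_PROBS))
    comorbidity_prevalence: dict = field(
        default_factory=lambda: dict(cal.COMORBIDITY_PREVALENCE)
    )
    missing_sex_fraction: float = cal.MISSING_SEX_FRACTION

    utilization_probs: dict = field(default_factory=lambda: dict(cal.UTILIZATION_PROBS))
    extra_events_poisson_mean: float = cal.EXTRA_EVENTS_POISSON_MEAN
    ed_fraction_of_exacerbations: tuple = cal.ED_FRACTION_OF_EXACERBATIONS

    cost_cells: dict = field(default_factory=lambda: dict(cal.COST_CELLS))
    effect_ratios: dict = field(default_factory=lambda: dict(cal.EFFECT_RATIOS))
    severity_ratios: tuple = cal.SEVERITY_RATIOS

    #: enumeration caps for rule-region sampling (fills/year, exacerbations/year)
    saba_cap: int = 12
    ocs_cap: int = 6
    exac_cap: int = 6

    #: "patient_year" (default): cost cells are annual per-patient moments and
    #: per-event gamma parameters are solved from the count process;
    #: "per_event": cells parameterise each event draw directly.
    cost_cell_basis: str = "patient_year"
    #: embed the multiplicative effect structure with stratum anchoring; when
    #: False, costs are the raw cell draws times the patient's covariate ratio
    calibrate_effects: bool = True

    #: fraction of patients made ineligible (coverage gap or no
    #: identification-window asthma event), so cohort selection filters something
    ineligible_fraction: float = 0.05
    #: fraction of *eligible* patients whose coverage is split into two
    #: adjacent spans (exercises span merging downstream)
    split_span_fraction: float = 0.10

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.ppp_rate <= 0:
            raise ConfigurationError("ppp_rate must be > 0")
        mix = self.severity_mixture
        if len(mix) != 4 or any(p < 0 or p > 1 for p in mix):
            raise ConfigurationError("severity_mixture must be four probabilities")
        if abs(sum(mix) - 1.0) > 1e-9:
            raise ConfigurationError("severity_mixture must sum to 1 within 1e-9")
        for comp, cells in self.cost_cells.items():
            for mean, sd in cells:
                if mean < 0 or sd < 0:
                    raise ConfigurationError(
                        f"negative cost mean/SD for component {comp!r}"
                    )
                if mean == 0 and sd > 0:
                    raise ConfigurationError(
                        f"component {comp!r}: SD > 0 with mean 0 leaves the "
                        "gamma undefined"
                    )
        if not (0 <= self.ineligible_fraction < 1):
            raise ConfigurationError("ineligible_fraction must be in [0, 1)")

    @property
    def windows(self) -> StudyWindows:
        y0, y1 = self.identification_years
        return StudyWindows(
            identification_start=date(y0, 1, 1),
            identification_end=date(y1, 12, 31),
            analysis_start=date(self.analysis_year, 1, 1),
            analysis_end=date(self.analysis_year, 12, 31),
        )


#: GLM covariates fitted by default (severity is always added separately).
DEFAULT_GLM_COVARIATES = (
    "age",
    "female",
    "sisben_level1",
    "rhinitis",
    "acute_bronchitis",
    "atopic_eczema",
    "copd",
    "emphysema",
    "urban",
)


@dataclass
class PipelineConfig:
    """End-to-end pipeline run configuration."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    output_dir: Path = Path("asthmacost_run")
    seed: int = 0
    ppp_rate: float = cal.PPP_RATE_COP_PER_IUSD
    glm_covariates: tuple = DEFAULT_GLM_COVARIATES
    screen_alpha: float = 0.1
    excluded_comorbidities: tuple = (
        "rhinitis",
        "atopic_eczema",
        "acute_bronchitis",
        "emphysema",
        "copd",
    )
    report_decimals: int = 1
    make_plots: bool = True

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        # one seed drives the whole run
        self.generator.seed = self.seed

    @property
    def windows(self) -> StudyWindows:
        return self.generator.windows


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, date):
        return obj.isoformat()
    return obj


def save_config(config: PipelineConfig | GeneratorConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def _tuplify_cells(cells: dict) -> dict:
    return {k: tuple(tuple(c) for c in v) for k, v in cells.items()}


def load_generator_config(path: str | Path) -> GeneratorConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return generator_config_from_dict(raw)


def generator_config_from_dict(raw: dict) -> GeneratorConfig:
    kwargs = dict(raw)
    for key in ("severity_mixture", "female_prob", "urban_prob", "severity_ratios",
                "ed_fraction_of_exacerbations", "identification_years"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "cost_cells" in kwargs:
        kwargs["cost_cells"] = _tuplify_cells(kwargs["cost_cells"])
    if "age_band_probs" in kwargs:
        kwargs["age_band_probs"] = {
            tuple(int(x) for x in str(k).strip("()").split(",")) if isinstance(k, str)
            else tuple(k): tuple(v)
            for k, v in kwargs["age_band_probs"].items()
        }
    cfg = GeneratorConfig(**kwargs)
    cfg.validate()
    return cfg


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    gen = generator_config_from_dict(raw.pop("generator", {}))
    for key in ("glm_covariates", "excluded_comorbidities"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "output_dir" in raw:
        raw["output_dir"] = Path(raw["output_dir"])
    return PipelineConfig(generator=gen, **raw)
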