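"""Gamma log-link GLM for annual direct asthma costs.

The model of the conditional mean is

    E[cost_i | x_i] = exp(b0 + x_i' b),

with a gamma variance function and sandwich (robust) standard errors, the
standard one-part specification for right-skewed expenditure data.
Exponentiated coefficients are *cost ratios*: the multiplicative change in
the mean annual cost for a one-unit change in the covariate (or versus the
reference category).  Records with non-positive cost are outside the gamma
support and are excluded from the fit with logged reasons, as are records
missing any covariate.

Usage follows the statsmodels convention::

    model = AsthmaCostModel.from_profiles(profiles, demographics)
    res = model.fit()
    res.cost_ratios        # term, ratio, robust SE, 95% CI, p
    res.summary()
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import DEFAULT_GLM_COVARIATES

__all__ = ["AsthmaCostModel", "AsthmaCostResults", "univariate_screen", "ScreenResult"]

logger = logging.getLogger(__name__)

_Z95 = 1.96  # normal multiplier for Wald ratio CIs on the log scale


def _design(
    data: pd.DataFrame,
    covariates: Sequence[str],
    severity_col: str | None,
    severity_reference: int = 1,
) -> pd.DataFrame:
    """Build the design matrix: intercept, covariates, severity dummies."""
    X = pd.DataFrame(index=data.index)
    X["Intercept"] = 1.0
    for cov in covariates:
        X[cov] = pd.to_numeric(data[cov], errors="coerce")
    if severity_col is not None:
        sev = data[severity_col].astype("Int64")
        levels = [lv for lv in sorted(sev.dropna().unique()) if lv != severity_reference]
        for lv in levels:
            X[f"severity[{int(lv)}]"] = (sev == lv).astype(float)
        X.loc[sev.isna(), [f"severity[{int(lv)}]" for lv in levels]] = np.nan
    return X


@dataclass
class AsthmaCostModel:
    """One-part gamma GLM of annual total cost with a log link.

    Parameters
    ----------
    data
        Model frame: one row per patient, holding the outcome column,
        numeric/binary covariates, and an integer severity column.
    covariates
        Covariate columns entering linearly (binary flags or continuous).
    outcome
        Cost column, in I$; non-positive values are excluded.
    severity_col
        Ordered severity codes; dummy-coded against ``severity_reference``
        (mild intermittent by default).  ``None`` omits severity.
    """

    data: pd.DataFrame
    covariates: Sequence[str] = DEFAULT_GLM_COVARIATES
    outcome: str = "total_cost"
    severity_col: str | None = "severity"
    severity_reference: int = 1
    exclusions: dict = field(init=False, default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        y = pd.to_numeric(df[self.outcome], errors="coerce")
        X = _design(df, self.covariates, self.severity_col, self.severity_reference)
        missing = X.isna().any(axis=1) | y.isna()
        nonpos = ~missing & (y <= 0)
        keep = ~missing & ~nonpos
        self.exclusions = {
            "missing_covariate_or_outcome": int(missing.sum()),
            "nonpositive_outcome": int(nonpos.sum()),
        }
        if self.exclusions["missing_covariate_or_outcome"] or self.exclusions["nonpositive_outcome"]:
            logger.info("GLM exclusions: %s", self.exclusions)
        self._y = y[keep].astype(float)
        self._X = X[keep].astype(float)
        self.n_used = int(keep.sum())
        # degenerate terms (constant in the included rows) cannot be
        # estimated; drop them with a flagged report rather than failing
        degenerate = [
            c
            for c in self._X.columns
            if c != "Intercept" and self._X[c].nunique() <= 1
        ]
        if degenerate:
            logger.warning("dropping degenerate model terms: %s", degenerate)
            self._X = self._X.drop(columns=degenerate)
        self.dropped_terms = tuple(degenerate)
        rank = np.linalg.matrix_rank(self._X.to_numpy()) if self.n_used else 0
        self.collinear = rank < self._X.shape[1]

    @classmethod
    def from_profiles(
        cls,
        profiles: pd.DataFrame,
        demographics: pd.DataFrame,
        covariates: Sequence[str] = DEFAULT_GLM_COVARIATES,
        **kwargs,
    ) -> "AsthmaCostModel":
        """Assemble the model frame from patient profiles plus demographics.

        Adds the ``sisben_level1`` indicator (most-deprived proxy-means level
        versus levels 2-3/other) expected by the default covariate list.
        """
        demo = demographics.set_index("patient_id").reindex(profiles.index)
        frame = profiles[["severity", "total_cost"]].join(demo)
        if "sisben_level" in frame.columns:
            frame["sisben_level1"] = (frame["sisben_level"].astype(str) == "1").astype(float)
        return cls(frame, covariates=covariates, **kwargs)

    def fit(self, cov_type: str = "HC1", maxiter: int = 100) -> "AsthmaCostResults":
        """Fit by IRLS; ``cov_type`` selects the sandwich covariance flavour."""
        if self.n_used == 0:
            raise ValueError("no records remain after exclusions")
        if self.collinear:
            raise ValueError(
                "design matrix is rank-deficient after dropping degenerate "
                f"terms {self.dropped_terms}: remaining terms are collinear"
            )
        glm = sm.GLM(
            self._y,
            self._X,
            family=sm.families.Gamma(link=sm.families.links.Log()),
        )
        res = glm.fit(cov_type=cov_type, maxiter=maxiter)
        if not res.converged:
            raise RuntimeError(
                f"IRLS did not converge in {maxiter} iterations "
                f"(last deviance {res.deviance:.6g})"
            )
        return AsthmaCostResults(self, res, cov_type)


class AsthmaCostResults:
    """Fitted gamma-GLM results: coefficients, robust SEs, cost ratios."""

    def __init__(self, model: AsthmaCostModel, results, cov_type: str) -> None:
        self.model = model
        self._res = results
        self.cov_type = cov_type
        self.n_used = model.n_used
        self.exclusions = dict(model.exclusions)

    @property
    def params(self) -> pd.Series:
        """Coefficients on the log scale."""
        return self._res.params

    @property
    def bse(self) -> pd.Series:
        """Robust (sandwich) standard errors."""
        return self._res.bse

    @property
    def pvalues(self) -> pd.Series:
        return self._res.pvalues

    @property
    def cost_ratios(self) -> pd.DataFrame:
        """Exponentiated coefficients with Wald 95% CIs and robust SEs.

        The ratio-scale SE is the delta-method value ratio * SE(log ratio).
        The intercept row is the adjusted reference-cell mean cost in I$.
        """
        b, se = self.params, self.bse
        ratio = np.exp(b)
        return pd.DataFrame(
            {
                "coefficient": b,
                "robust_se": se,
                "cost_ratio": ratio,
                "ratio_se": ratio * se,
                "ci_low": np.exp(b - _Z95 * se),
                "ci_high": np.exp(b + _Z95 * se),
                "pvalue": self.pvalues,
            }
        )

    def predict(self, data: pd.DataFrame | None = None) -> pd.Series:
        """Predicted mean cost (I$, original scale) per record."""
        if data is None:
            return pd.Series(self._res.predict(self.model._X), index=self.model._X.index)
        X = _design(
            data, self.model.covariates, self.model.severity_col,
            self.model.severity_reference,
        )[self.model._X.columns]
        return pd.Series(self._res.predict(X.astype(float)), index=data.index)

    def predicted_adjusted_costs(
        self, strata: pd.Series | str | None = None
    ) -> pd.DataFrame:
        """Mean (SD) of model predictions per stratum, on the dollar scale.

        ``strata`` is a column name of the included rows' source frame or an
        aligned Series; ``None`` gives the single overall row.  Strata with
        no included records are absent (undefined) rather than zero.
        """
        pred = self.predict()
        if strata is None:
            groups = pd.Series("all", index=pred.index)
        elif isinstance(strata, str):
            groups = self.model.data.loc[pred.index, strata]
        else:
            groups = strata.loc[pred.index]
        out = pred.groupby(groups).agg(["mean", "std", "count"])
        out.columns = ["adjusted_mean", "adjusted_sd", "n"]
        return out

    def wald_term_pvalue(self, columns: Sequence[str]) -> float:
        """Joint robust Wald test that the listed design columns are all zero."""
        names = list(self.params.index)
        R = np.zeros((len(columns), len(names)))
        for i, c in enumerate(columns):
            R[i, names.index(c)] = 1.0
        return float(np.squeeze(self._res.wald_test(R, scalar=True).pvalue))

    def summary(self) -> str:
        """Text summary: the GLM fit plus the cost-ratio table."""
        ratios = self.cost_ratios.round(4)
        lines = [
            str(self._res.summary()),
            "",
            f"Cost ratios (exp(coef), {self.cov_type} robust 95% CI); "
            f"n_used={self.n_used}, excluded={self.exclusions}",
            ratios.to_string(),
        ]
        return "\n".join(lines)


@dataclass
class ScreenResult:
    """Univariate screen outcome: forced + significant covariates."""

    selected: tuple
    forced: tuple
    table: pd.DataFrame


def univariate_screen(
    data: pd.DataFrame,
    candidates: Sequence[str],
    forced: Sequence[str] = ("age", "female", "sisben_level1"),
    alpha: float = 0.1,
    outcome: str = "total_cost",
    severity_col: str = "severity",
) -> ScreenResult:
    """Single-covariate gamma-GLM screen at the given p threshold.

    Each candidate is fitted alone (severity as its dummy block, tested
    jointly); candidates with p < ``alpha`` join the forced confounders in
    the selected set.
    """
    rows = []
    selected = list(forced)
    for cand in candidates:
        is_sev = cand == severity_col
        m = AsthmaCostModel(
            data,
            covariates=() if is_sev else (cand,),
            outcome=outcome,
            severity_col=severity_col if is_sev else None,
        )
        res = m.fit()
        cols = [c for c in res.params.index if c != "Intercept"]
        if not cols:  # candidate constant in the included rows: untestable
            rows.append({"candidate": cand, "pvalue": np.nan, "selected": cand in forced})
            continue
        p = res.wald_term_pvalue(cols)
        keep = p < alpha
        if keep and cand not in selected:
            selected.append(cand)
        rows.append({"candidate": cand, "pvalue": p, "selected": keep or cand in forced})
    return ScreenResult(
        selected=tuple(selected), forced=tuple(forced), table=pd.DataFrame(rows)
    )
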