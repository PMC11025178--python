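"""Incidence-weighted effect estimation and heterogeneity statistics.

The central estimator is the weighted Cox proportional-hazards model
(WCoxPH): cases carry weight 1 and non-cases weight ``1/inc_t``, where
``inc_t`` is the age-specific population incidence (a proportion, i.e.
rate per 100,000 divided by 100,000) at the subject's exit age. The
weighting undoes the case-enrichment of a follow-up sample relative to
population incidence; because it turns the partial likelihood into a
pseudo-likelihood, the sandwich (robust) variance is reported.

``WeightedCoxPH`` / ``WeightedCoxPHResults`` follow the model/results
convention of statsmodels: build the model from a cohort, call ``fit()``,
read estimates off the results object or print ``summary()``.

EO-vs-LO heterogeneity uses fixed-effect Cochran's Q over (beta, se) pairs,
with I² = max(0, (Q - df)/Q) * 100 and a chi-square upper-tail p-value;
printed hazard ratios with 95% CIs enter through :func:`ci_to_se`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SurvivalCohort
from .coxph import fit_cox
from .exceptions import (NoEventsError, SeparationError, ValidationError,
                         ZeroIncidenceError)

Z95 = stats.norm.ppf(0.975)

__all__ = ["IncidenceSchedule", "interpolate_incidence", "make_weights",
           "WeightedCoxPH", "WeightedCoxPHResults", "EffectEstimate",
           "weighted_cox_fit", "logistic_fit", "ci_to_se", "cochran_q",
           "HeterogeneityResult"]


@dataclass
class IncidenceSchedule:
    """Banded incidence rates and their per-year interpolation.

    ``bands`` has columns ``age_start, age_end, rate_per_100k`` (band ends
    inclusive, e.g. 50–54); ``per_year`` maps integer age to the linearly
    interpolated rate per 100,000 person-years.
    """

    bands: pd.DataFrame
    per_year: pd.Series
    anchor: str = "midpoint"

    def rate_at(self, age: float) -> float:
        """Rate per 100k at the integer part of ``age``, clamped to range."""
        a = int(np.clip(np.floor(age), self.per_year.index.min(),
                        self.per_year.index.max()))
        return float(self.per_year.loc[a])


def interpolate_incidence(bands: pd.DataFrame,
                          age_min: int = 32,
                          age_max: int = 87,
                          anchor: str = "midpoint") -> IncidenceSchedule:
    """Per-year rates from banded rates by linear interpolation.

    Each band's rate is anchored at its midpoint age (``anchor='midpoint'``,
    default) or at its start (``anchor='start'``); integer-age rates are
    linear between adjacent anchors and flat beyond the outermost anchors.
    """
    need = {"age_start", "age_end", "rate_per_100k"}
    if not need.issubset(bands.columns):
        raise ValidationError(f"incidence table needs columns {sorted(need)}")
    if (bands["rate_per_100k"] < 0).any():
        raise ValidationError("negative incidence rate")
    if len(bands) < 2:
        raise ValidationError("need at least two bands to interpolate")
    b = bands.sort_values("age_start").reset_index(drop=True)
    if (b["age_end"] < b["age_start"]).any():
        raise ValidationError("band with age_end < age_start")
    if (b["age_start"].to_numpy()[1:] <= b["age_end"].to_numpy()[:-1]).any():
        raise ValidationError("overlapping or unordered bands")
    if anchor == "midpoint":
        anchors = (b["age_start"] + b["age_end"]) / 2.0
    elif anchor == "start":
        anchors = b["age_start"].astype(float)
    else:
        raise ValidationError(f"unknown anchor {anchor!r}")
    ages = np.arange(age_min, age_max + 1)
    rates = np.interp(ages, anchors, b["rate_per_100k"])
    return IncidenceSchedule(b, pd.Series(rates, index=ages), anchor)


def make_weights(c: SurvivalCohort,
                 sched: IncidenceSchedule,
                 renormalize: bool = False) -> np.ndarray:
    """Sampling weights: 1 for cases, ``1/inc_t`` for non-cases.

    ``inc_t`` is the per-year incidence at the integer part of the exit
    age, expressed as a proportion (rate per 100,000 / 100,000). With
    ``renormalize=True`` non-case weights are rescaled to mean 1, which
    leaves the weighted Cox estimate unchanged and keeps effective sample
    sizes interpretable.
    """
    exit_age = c.table["exit_age"].to_numpy(dtype=float)
    event = c.table["event"].to_numpy(dtype=int)
    w = np.ones(len(c))
    for i in np.flatnonzero(event == 0):
        rate = sched.rate_at(exit_age[i])
        if rate <= 0:
            raise ZeroIncidenceError(
                f"zero incidence at age {int(exit_age[i])} for a non-case")
        w[i] = 1.0 / (rate / 100_000.0)
    if renormalize and (event == 0).any():
        nc = event == 0
        w[nc] = w[nc] / w[nc].mean()
    return w


@dataclass
class EffectEstimate:
    """One exposure effect: log ratio, Wald CI on the ratio scale, p."""
    beta: float
    se: float
    p: float
    n: int
    n_events: int
    model_tag: str
    population_tag: str = "General"
    term: str = "exposure"

    @property
    def hr_or(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + Z95 * self.se))

    def as_row(self) -> dict:
        return {
            "population": self.population_tag, "term": self.term,
            "beta": self.beta, "se": self.se, "hr": self.hr_or,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.p,
            "n": self.n, "n_events": self.n_events,
            "model_tag": self.model_tag,
        }


class WeightedCoxPH:
    """Weighted Cox proportional-hazards model for a scored cohort.

    Parameters
    ----------
    cohort : SurvivalCohort
        Follow-up data on the age timescale.
    exposure : array-like
        Per-sample exposure (typically a PRS standardised against the
        General population, so the estimate reads 'per SD').
    covariates : list of str, optional
        Adjustment covariate columns of the cohort table (rows with a
        missing covariate are dropped and counted).
    weights : array-like, optional
        Sampling weights; when supplied the sandwich variance is used.
    """

    def __init__(self, cohort: SurvivalCohort, exposure,
                 covariates: list[str] | None = None,
                 weights=None, exposure_name: str = "exposure"):
        self.cohort = cohort
        self.exposure = np.asarray(exposure, dtype=float)
        self.covariates = list(covariates or [])
        self.weights = None if weights is None else np.asarray(weights, float)
        self.exposure_name = exposure_name
        if len(self.exposure) != len(cohort):
            raise ValidationError("exposure length does not match cohort")
        unknown = [x for x in self.covariates if x not in cohort.table]
        if unknown:
            raise ValidationError(f"unknown covariates {unknown}")
        if cohort.n_events == 0:
            raise NoEventsError("cohort has zero events")

    def _design(self):
        cov = self.cohort.table[self.covariates].to_numpy(dtype=float) \
            if self.covariates else np.empty((len(self.cohort), 0))
        ok = ~np.isnan(cov).any(axis=1) & ~np.isnan(self.exposure)
        X = np.column_stack([self.exposure[ok], cov[ok]])
        t = self.cohort.table
        w = None if self.weights is None else self.weights[ok]
        return (X, t["exit_age"].to_numpy(float)[ok],
                t["event"].to_numpy(int)[ok],
                t["entry_age"].to_numpy(float)[ok], w, ok)

    def fit(self, max_iter: int = 25, tol: float = 1e-8) -> "WeightedCoxPHResults":
        X, exit_age, event, entry, w, ok = self._design()
        if np.nanstd(X[:, 0]) == 0:
            raise SeparationError("constant exposure carries no information")
        fit = fit_cox(X, exit_age, event, entry_age=entry, weights=w,
                      robust=self.weights is not None,
                      max_iter=max_iter, tol=tol,
                      raise_on_nonconvergence=True)
        se = fit.robust_se if fit.robust_se is not None else fit.se
        names = [self.exposure_name] + self.covariates
        return WeightedCoxPHResults(self, fit, names, se)


class WeightedCoxPHResults:
    """Estimates from a :class:`WeightedCoxPH` fit."""

    def __init__(self, model, fit, names, se):
        self.model = model
        self._fit = fit
        self.names = names
        self.params = pd.Series(fit.beta, index=names)
        self.bse = pd.Series(se, index=names)
        self.hazard_ratios = np.exp(self.params)
        z = self.params / self.bse
        self.pvalues = pd.Series(
            np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0), index=names)
        self.n = fit.n
        self.n_events = fit.n_events
        self.converged = fit.converged
        self.loglik = fit.loglik

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        zq = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame({
            "ci_low": np.exp(self.params - zq * self.bse),
            "ci_high": np.exp(self.params + zq * self.bse),
        }, index=self.names)

    def effect(self) -> EffectEstimate:
        """The exposure term as an :class:`EffectEstimate`."""
        name = self.names[0]
        return EffectEstimate(
            beta=float(self.params[name]), se=float(self.bse[name]),
            p=float(self.pvalues[name]), n=self.n, n_events=self.n_events,
            model_tag="wcox", population_tag=self.model.cohort.label,
            term=name)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Weighted Cox proportional hazards"
            if self.model.weights is not None else
            "Cox proportional hazards",
            f"population: {self.model.cohort.label}   "
            f"n={self.n}  events={self.n_events}  "
            f"log-PL={self.loglik:.3f}",
            f"{'term':<16}{'HR':>8}{'ci_low':>9}{'ci_high':>9}{'p':>11}",
        ]
        for name in self.names:
            lines.append(
                f"{name:<16}{self.hazard_ratios[name]:>8.3f}"
                f"{ci.loc[name, 'ci_low']:>9.3f}{ci.loc[name, 'ci_high']:>9.3f}"
                f"{self.pvalues[name]:>11.3g}")
        return "\n".join(lines)


def weighted_cox_fit(c: SurvivalCohort, exposure,
                     covariate_names: list[str] | None = None,
                     weights=None,
                     exposure_name: str = "exposure") -> EffectEstimate:
    """Convenience wrapper: fit and return the exposure effect."""
    model = WeightedCoxPH(c, exposure, covariate_names, weights,
                          exposure_name)
    return model.fit().effect()


def logistic_fit(table: pd.DataFrame, exposure,
                 covariate_names: list[str] | None = None,
                 outcome_col: str = "case") -> EffectEstimate:
    """Logistic regression OR for a case–control re-analysis (IRLS MLE)."""
    import statsmodels.api as sm

    covariate_names = list(covariate_names or [])
    y = table[outcome_col].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("outcome must be binary 0/1")
    x = np.asarray(exposure, dtype=float)
    if np.nanstd(x) == 0:
        raise SeparationError("constant exposure carries no information")
    cov = table[covariate_names].to_numpy(dtype=float) if covariate_names \
        else np.empty((len(table), 0))
    ok = ~np.isnan(x) & ~np.isnan(cov).any(axis=1)
    X = sm.add_constant(np.column_stack([x[ok], cov[ok]]))
    import warnings

    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation is detected from the fitted SE below
            warnings.simplefilter("ignore")
            res = sm.GLM(y[ok], X, family=sm.families.Binomial()).fit()
    except Exception as exc:  # pragma: no cover - defensive
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    beta = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(se) or se > 1e3:
        raise SeparationError("quasi-separation: unbounded estimate")
    zval = beta / se
    return EffectEstimate(
        beta=beta, se=se,
        p=float(np.clip(2 * stats.norm.sf(abs(zval)), 1e-300, 1.0)),
        n=int(ok.sum()), n_events=int(y[ok].sum()),
        model_tag="logistic")


def ci_to_se(point: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Invert a printed ratio with 95% Wald CI to (log-ratio, SE)."""
    if not (0 < ci_low <= point <= ci_high):
        raise ValidationError(
            f"CI ordering violated: {ci_low} <= {point} <= {ci_high}")
    beta = float(np.log(point))
    se = float((np.log(ci_high) - np.log(ci_low)) / (2 * Z95))
    return beta, se


@dataclass
class HeterogeneityResult:
    """Fixed-effect heterogeneity across effect estimates."""
    Q: float
    df: int
    I2: float          # percent in [0, 100]
    p_het: float
    inputs: list[tuple[float, float]] = field(default_factory=list)

    def summary(self) -> str:
        return (f"Cochran Q = {self.Q:.3f} on {self.df} df, "
                f"I2 = {self.I2:.0f}%, P_het = {self.p_het:.3g}")


def cochran_q(estimates: list[tuple[float, float]]) -> HeterogeneityResult:
    """Cochran's Q and I² over (beta, se) pairs with 1/se² weights."""
    if len(estimates) < 2:
        raise ValidationError("heterogeneity needs at least two estimates")
    beta = np.array([b for b, _ in estimates], dtype=float)
    se = np.array([s for _, s in estimates], dtype=float)
    if (se < 0).any():
        raise ValidationError("negative SE")
    df = len(estimates) - 1
    if (se == 0).any():
        # infinite weight: only coherent when every estimate coincides
        if np.unique(beta).size > 1:
            raise ValidationError("zero SE with distinct betas: infinite weight")
        return HeterogeneityResult(Q=0.0, df=df, I2=0.0, p_het=1.0,
                                   inputs=list(estimates))
    w = 1.0 / se ** 2
    pooled = float((w * beta).sum() / w.sum())
    Q = float((w * (beta - pooled) ** 2).sum())
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    p = float(stats.chi2.sf(Q, df)) if Q > 0 else 1.0
    return HeterogeneityResult(Q=Q, df=df, I2=I2, p_het=p,
                               inputs=list(estimates))
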