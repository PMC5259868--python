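"""Cox proportional-hazards fits, nested-model comparison and Kaplan-Meier
median-split curves.

Fits use the Efron-corrected partial likelihood (lifelines).  Model fit is
summarized by -2 log partial likelihood; adding one covariate to a nested
model is called a significant improvement when -2LL drops by more than 3.84,
the 0.95 critical value of a chi-square with one degree of freedom.  The
IMDC prognostic score enters as a single ordinal covariate (good=0,
intermediate=1, poor=2) so that the combined models spend one degree of
freedom, consistent with that criterion.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning

from .types import IMDC_LEVELS

logger = logging.getLogger(__name__)

# chi-square(1 df) 0.95 critical value, at the precision used for reporting
MINUS2LL_IMPROVEMENT_THRESHOLD = 3.84


@dataclass
class CoxFitResult:
    """One fitted proportional-hazards model."""

    names: list[str]
    coefficients: np.ndarray
    hr: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    p_wald: np.ndarray
    minus2ll: float
    n: int
    n_events: int
    converged: bool
    n_dropped_missing: int = 0

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])

    def p_value(self, name: str) -> float:
        return float(self.p_wald[self.names.index(name)])

    def ci(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return float(self.ci95_low[i]), float(self.ci95_high[i])


@dataclass
class ModelComparison:
    """Nested-model verdict by the -2LL chi-square criterion."""

    base_minus2ll: float
    extended_minus2ll: float
    delta: float
    threshold: float = MINUS2LL_IMPROVEMENT_THRESHOLD
    significant_improvement: bool = False


@dataclass
class KMCurve:
    """Product-limit survival curve for one median-split group."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    label: str
    split_value: float


def _failed_fit(names, n, n_events, n_dropped) -> CoxFitResult:
    nan = np.full(len(names), np.nan)
    return CoxFitResult(
        names=list(names), coefficients=nan.copy(), hr=nan.copy(),
        ci95_low=nan.copy(), ci95_high=nan.copy(), p_wald=nan.copy(),
        minus2ll=float("nan"), n=n, n_events=n_events,
        converged=False, n_dropped_missing=n_dropped,
    )


def fit_cox(covariates, time, event) -> CoxFitResult:
    """Fit a Cox model; covariates is a DataFrame, Series or 1D/2D array.

    Patients with any missing covariate are dropped listwise (count logged
    and recorded).  Constant covariates and event-free data are rejected
    outright; monotone-likelihood / collinear fits come back flagged
    ``converged=False`` rather than silently reported.
    """
    X = pd.DataFrame(covariates)
    X.columns = [str(c) for c in X.columns]
    names = list(X.columns)
    df = X.copy()
    df["_T"] = np.asarray(time, dtype=float)
    df["_E"] = np.asarray(event, dtype=int)

    n_before = len(df)
    df = df.dropna()
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("fit_cox: dropped %d patient(s) with missing covariates", n_dropped)
    if len(df) < 2:
        raise ValueError("need at least 2 complete-case patients")
    n_events = int(df["_E"].sum())
    if n_events < 1:
        raise ValueError("no events observed; Cox model is unidentifiable")
    for name in names:
        if df[name].nunique() <= 1:
            raise ValueError(f"covariate {name!r} is constant")

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            cph.fit(df, duration_col="_T", event_col="_E")
    except (ConvergenceError, ConvergenceWarning, np.linalg.LinAlgError) as exc:
        logger.warning("fit_cox: non-converged fit (%s)", exc)
        return _failed_fit(names, len(df), n_events, n_dropped)

    summary = cph.summary.loc[names]
    return CoxFitResult(
        names=names,
        coefficients=summary["coef"].to_numpy(),
        hr=summary["exp(coef)"].to_numpy(),
        ci95_low=summary["exp(coef) lower 95%"].to_numpy(),
        ci95_high=summary["exp(coef) upper 95%"].to_numpy(),
        p_wald=summary["p"].to_numpy(),
        minus2ll=float(-2.0 * cph.log_likelihood_),
        n=len(df),
        n_events=n_events,
        converged=True,
        n_dropped_missing=n_dropped,
    )


def fit_cox_with_imdc(biomarker, imdc, time, event, name: str = "biomarker") -> CoxFitResult:
    """Two-covariate fit: a biomarker plus the ordinal IMDC level."""
    levels = [IMDC_LEVELS[v] if isinstance(v, str) else int(v) for v in np.asarray(imdc, dtype=object)]
    X = pd.DataFrame({name: np.asarray(biomarker, dtype=float), "imdc": levels})
    return fit_cox(X, time, event)


def compare_nested(base, extended) -> ModelComparison:
    """Compare nested Cox fits by the drop in -2 log likelihood.

    ``base`` and ``extended`` are CoxFitResult objects (the extended model
    must add exactly one covariate and keep the same risk set) or plain -2LL
    numbers.  Improvement is significant when the drop exceeds 3.84.
    """
    if isinstance(base, CoxFitResult) and isinstance(extended, CoxFitResult):
        if len(extended.names) != len(base.names) + 1:
            raise ValueError("extended model must add exactly one covariate")
        if base.n != extended.n:
            raise ValueError(
                f"risk sets differ after missing-data deletion "
                f"(base n={base.n}, extended n={extended.n}); refusing to compare"
            )
        base_ll, ext_ll = base.minus2ll, extended.minus2ll
    else:
        base_ll, ext_ll = float(base), float(extended)
    delta = base_ll - ext_ll
    return ModelComparison(
        base_minus2ll=base_ll,
        extended_minus2ll=ext_ll,
        delta=delta,
        significant_improvement=bool(delta > MINUS2LL_IMPROVEMENT_THRESHOLD),
    )


def km_median_split(values, time, event, label: str = "biomarker") -> tuple[KMCurve, KMCurve]:
    """Kaplan-Meier curves for the cohort split at the biomarker median.

    The median is the midpoint of the central order statistics for even n;
    ties at the median go to the low group (low: value <= median).
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    keep = ~np.isnan(v)
    v, t, e = v[keep], t[keep], e[keep]
    if v.size < 2:
        raise ValueError("need at least 2 patients with a non-missing biomarker")
    median = float(np.median(v))
    low = v <= median
    if low.all():
        raise ValueError("all biomarker values identical; cannot median-split")

    curves = []
    for mask, name in ((low, f"{label} <= median"), (~low, f"{label} > median")):
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask])
        sf = kmf.survival_function_
        times = sf.index.to_numpy(dtype=float)
        surv = sf.iloc[:, 0].to_numpy(dtype=float)
        at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
        curves.append(
            KMCurve(times=times, survival=surv, at_risk=at_risk,
                    label=name, split_value=median)
        )
    return curves[0], curves[1]
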