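"""Time-to-event machinery: Kaplan-Meier curves and Cox regression.

Estimation is delegated to lifelines. ``KaplanMeierFitter`` provides the
product-limit estimator with confidence intervals on the log(-log S) scale
(the "exponential Greenwood" formula), and ``CoxPHFitter`` maximises the
partial likelihood with Efron's correction for tied event times. This module
adapts those fits to the cohort containers, adds Greenwood variances and
stratified risk summaries, and screens for non-identifiable designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning

from .cohort import CohortRecord, ConsensusProfile, ValidationError, cohort_to_frame, profiles_to_frame

EVENTS = ("transformation", "recurrence")


class FitError(ValidationError):
    """Model fit failed (non-convergence or non-identifiable design)."""


def _event_columns(event: str) -> tuple[str, str]:
    if event not in EVENTS:
        raise ValidationError(f"unknown event {event!r}; expected one of {EVENTS}")
    return f"{event}_time", f"{event}_event"


def _as_frame(cohort: Iterable[CohortRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(cohort, pd.DataFrame):
        return cohort
    return cohort_to_frame(list(cohort))


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve for one stratum of one event."""

    event: str
    stratum: str
    times: np.ndarray  # event times t_j (strictly increasing)
    at_risk: np.ndarray  # n_j
    events: np.ndarray  # d_j >= 1
    survival: np.ndarray  # S(t_j)
    variance: np.ndarray  # Greenwood Var[S(t_j)]
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_subjects: int
    n_events: int
    flagged_no_events: bool = False

    def survival_at(self, t: float) -> float:
        """Step-function S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def risk_at(self, t: float) -> float:
        """Cumulative event risk 1 - S(t) at t months."""
        return 1.0 - self.survival_at(t)


def km_fit(
    cohort: Iterable[CohortRecord] | pd.DataFrame,
    event: str,
    strata: Mapping[str, str] | None = None,
) -> list[KMCurve]:
    """Kaplan-Meier curves per stratum for transformation or recurrence.

    ``strata`` maps case_id -> stratum label; omitted means one pooled
    stratum "all". Every case must be covered. A stratum with zero events
    yields a constant S = 1 curve flagged as degenerate.
    """
    frame = _as_frame(cohort)
    time_col, event_col = _event_columns(event)
    if strata is None:
        labels = pd.Series("all", index=frame.index)
    else:
        labels = pd.Series({cid: strata.get(cid) for cid in frame.index})
        if labels.isna().any():
            raise ValidationError(
                f"strata must cover all cases; missing {labels.index[labels.isna()].tolist()}"
            )
    if (frame[time_col] <= 0).any():
        raise ValidationError("event/censoring times must be > 0")

    curves = []
    for label in sorted(labels.unique()):
        sub = frame.loc[labels == label]
        durations = sub[time_col].to_numpy(float)
        observed = sub[event_col].to_numpy(int)
        kmf = KaplanMeierFitter()
        kmf.fit(durations, observed, label="S")
        table = kmf.event_table
        mask = table["observed"].to_numpy() > 0
        t = table.index.to_numpy(float)[mask]
        d = table["observed"].to_numpy(float)[mask]
        n = table["at_risk"].to_numpy(float)[mask]
        s = kmf.survival_function_["S"].reindex(t).to_numpy(float)
        # Greenwood: Var[S] = S^2 * cumsum(d / (n (n - d)))
        with np.errstate(divide="ignore"):
            var = s**2 * np.cumsum(np.where(n > d, d / (n * (n - d)), np.inf))
        ci = kmf.confidence_interval_.reindex(t)
        curves.append(
            KMCurve(
                event=event,
                stratum=str(label),
                times=t,
                at_risk=n,
                events=d,
                survival=s,
                variance=var,
                ci_lower=ci.iloc[:, 0].to_numpy(float),
                ci_upper=ci.iloc[:, 1].to_numpy(float),
                n_subjects=len(sub),
                n_events=int(observed.sum()),
                flagged_no_events=bool(observed.sum() == 0),
            )
        )
    return curves


@dataclass(frozen=True)
class CoxFit:
    """Cox proportional-hazards fit (Efron tie correction)."""

    event: str
    covariates: tuple[str, ...]
    coef: np.ndarray
    hazard_ratio: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray  # on the HR scale
    ci_upper: np.ndarray
    p_value: np.ndarray
    log_likelihood: float
    n_subjects: int
    n_events: int
    warnings: tuple[str, ...] = field(default_factory=tuple)

    @property
    def possibly_separated(self) -> bool:
        return any("separat" in w or "convergence" in w.lower() for w in self.warnings)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "hazard_ratio": self.hazard_ratio,
                "se": self.se,
                "hr_ci_lower": self.ci_lower,
                "hr_ci_upper": self.ci_upper,
                "p": self.p_value,
            },
            index=pd.Index(self.covariates, name="covariate"),
        )


def cox_fit(
    cohort: Iterable[CohortRecord] | pd.DataFrame,
    event: str,
    covariates: pd.DataFrame | Mapping[str, Sequence[float]],
) -> CoxFit:
    """Single- or multi-covariate Cox PH fit with Efron tie handling.

    ``covariates`` is a numeric design matrix indexed (or indexable) by
    case_id. Constant columns are rejected up front as non-identifiable;
    lifelines convergence complaints (e.g. monotone likelihood under
    complete separation) are captured on the returned fit.
    """
    frame = _as_frame(cohort)
    design = pd.DataFrame(covariates)
    if not design.index.equals(frame.index):
        design = design.reindex(frame.index)
        if design.isna().any().any():
            raise ValidationError("covariate matrix does not cover all cases")
    if design.shape[1] == 0:
        raise ValidationError("no covariates supplied")
    for col in design.columns:
        if design[col].nunique() <= 1:
            raise FitError(f"covariate {col!r} is constant: non-identifiable")
    time_col, event_col = _event_columns(event)
    if int(frame[event_col].sum()) == 0:
        raise FitError(f"no {event} events observed: Cox model non-identifiable")

    df = design.copy()
    df["_time"] = frame[time_col].to_numpy(float)
    df["_event"] = frame[event_col].to_numpy(int)

    cph = CoxPHFitter()
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always", ConvergenceWarning)
        try:
            cph.fit(df, duration_col="_time", event_col="_event")
        except ConvergenceError as exc:
            raise FitError(f"Cox fit did not converge: {exc}") from exc
        caught = [str(w.message) for w in wlist if issubclass(w.category, ConvergenceWarning)]

    summ = cph.summary
    return CoxFit(
        event=event,
        covariates=tuple(str(c) for c in design.columns),
        coef=summ["coef"].to_numpy(float),
        hazard_ratio=summ["exp(coef)"].to_numpy(float),
        se=summ["se(coef)"].to_numpy(float),
        ci_lower=summ["exp(coef) lower 95%"].to_numpy(float),
        ci_upper=summ["exp(coef) upper 95%"].to_numpy(float),
        p_value=summ["p"].to_numpy(float),
        log_likelihood=float(cph.log_likelihood_),
        n_subjects=len(df),
        n_events=int(df["_event"].sum()),
        warnings=tuple(caught),
    )


def univariate_feature_cox(
    cohort: Iterable[CohortRecord] | pd.DataFrame,
    profiles: Sequence[ConsensusProfile],
    events: Sequence[str] = EVENTS,
) -> pd.DataFrame:
    """One single-covariate Cox fit per feature per event.

    Mirrors the univariate hazard-ratio table: rows are features, with HR,
    95% Wald CI, p and a significance flag at p < 0.05 per event. Features
    constant across the cohort are flagged non-identifiable and skipped
    without disturbing the remaining fits.
    """
    frame = _as_frame(cohort)
    presence = profiles_to_frame(profiles).reindex(frame.index)
    if presence.isna().any().any():
        raise ValidationError("profiles do not cover all cohort cases")
    rows = []
    for event in events:
        for feature in presence.columns:
            base = {"event": event, "feature": feature}
            try:
                fit = cox_fit(frame, event, presence[[feature]])
            except FitError as exc:
                rows.append({**base, "identifiable": False, "note": str(exc)})
                continue
            rows.append(
                {
                    **base,
                    "identifiable": True,
                    "hazard_ratio": fit.hazard_ratio[0],
                    "hr_ci_lower": fit.ci_lower[0],
                    "hr_ci_upper": fit.ci_upper[0],
                    "p": fit.p_value[0],
                    "significant": bool(fit.p_value[0] < 0.05),
                    "n_events": fit.n_events,
                    "note": "; ".join(fit.warnings),
                }
            )
    return pd.DataFrame(rows)
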