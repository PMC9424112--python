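"""Synthetic OED study generator.

Emulates the structure of the 109-case multi-rater cohort: latent binary
feature profiles, three noisy raters, clinical covariates, and two
time-to-event outcomes (malignant transformation and recurrence) whose
hazards depend on the latent features.

Generative model
----------------
* latent feature ``L_j ~ Bernoulli(p_j)`` per case, independent across
  features by default (optional shared-severity Gaussian copula for the six
  scoring features);
* each rater observes ``L_j`` through a misclassification channel:
  ``P(score 1 | present) = sensitivity``, ``P(score 1 | absent) =
  1 - specificity``, independent across raters;
* event time is exponential with rate ``h0 * exp(sum_j L_j * log HR_j)``,
  administratively censored at the follow-up horizon, with an optional
  fraction of cases censored early, uniformly between the 60-month minimum
  follow-up and the horizon;
* WHO / binary grade are sampled from ordinal-logistic models driven by the
  latent six-feature count, so grade carries (noisy) signal about severity.

The default configuration targets the published cohort: pooled assessment
prevalences are hit by back-solving the latent prevalence through the rater
error model, and baseline hazards are calibrated by root-finding so the
expected observed event fraction matches ~18% (transformation) and ~25%
(recurrence).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .agreement import agreement_table
from .cohort import (
    MIN_FOLLOWUP_MONTHS,
    CohortRecord,
    RatingPanel,
    SITES,
    TREATMENTS,
    ValidationError,
    cohort_to_frame,
)
from .consensus import consensus_profiles
from .features import FEATURES, SIX_POINT_FEATURES
from .survival import EVENTS, FitError, cox_fit

# Pooled assessment prevalences (positives out of 327 assessments) in the
# published cohort; generator targets.
DEFAULT_ASSESSMENT_PREVALENCE: dict[str, float] = {
    "basal_cell_hyperplasia": 236 / 327,
    "bulbous_rete_pegs": 187 / 327,
    "dyskeratosis": 110 / 327,
    "hyperchromatism": 176 / 327,
    "irregular_surface_keratin": 196 / 327,
    "loss_of_epithelial_cohesion": 98 / 327,
    "loss_of_stratification": 138 / 327,
    "suprabasal_mitoses": 148 / 327,
    "nuclear_pleomorphism": 118 / 327,
    "abrupt_orthokeratosis": 174 / 327,
    "lymphocytic_band": 112 / 327,
    "verrucous_surface": 85 / 327,
}

# Published univariate hazard-ratio point estimates for the six features
# significant for both outcomes; all other features are null (HR 1).
DEFAULT_HAZARD_RATIOS: dict[str, dict[str, float]] = {
    "transformation": {
        "bulbous_rete_pegs": 8.27,
        "hyperchromatism": 2.96,
        "loss_of_epithelial_cohesion": 3.78,
        "loss_of_stratification": 5.35,
        "suprabasal_mitoses": 3.06,
        "nuclear_pleomorphism": 3.74,
    },
    "recurrence": {
        "bulbous_rete_pegs": 2.52,
        "hyperchromatism": 2.90,
        "loss_of_epithelial_cohesion": 3.50,
        "loss_of_stratification": 4.50,
        "suprabasal_mitoses": 3.17,
        "nuclear_pleomorphism": 3.45,
    },
}

DEFAULT_EVENT_RATE = {"transformation": 0.18, "recurrence": 0.25}

DEFAULT_SITE_WEIGHTS = {
    "tongue": 44,
    "floor_of_mouth": 23,
    "buccal_mucosa": 17,
    "gingivae": 7,
    "hard_palate": 6,
    "lower_lip": 6,
    "soft_palate": 6,
}
DEFAULT_TREATMENT_WEIGHTS = {"monitored": 34, "excised": 70, "laser": 5}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic study; defaults emulate the published cohort."""

    seed: int
    n_cases: int = 109
    n_raters: int = 3
    features: tuple[str, ...] = FEATURES
    assessment_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ASSESSMENT_PREVALENCE)
    )
    sensitivity: float = 0.85
    specificity: float = 0.90
    hazard_ratios: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {e: dict(v) for e, v in DEFAULT_HAZARD_RATIOS.items()}
    )
    baseline_hazard: Mapping[str, float] | None = None  # per month; calibrated if None
    target_event_rate: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_RATE)
    )
    horizon_months: float = 120.0
    early_censor_fraction: float = 0.2
    female_fraction: float = 42 / 109
    age_mean: float = 66.0
    age_sd: float = 13.0
    site_weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SITE_WEIGHTS))
    treatment_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_WEIGHTS)
    )
    grade_slope: float = 0.8  # ordinal-logistic pull of grade toward feature count
    feature_correlation: float = 0.0  # shared-severity copula loading, scoring features
    time_decimals: int = 3

    def validate(self) -> None:
        if self.n_cases < 1 or self.n_raters < 1:
            raise ValidationError("n_cases and n_raters must be >= 1")
        for name, value in (
            ("sensitivity", self.sensitivity),
            ("specificity", self.specificity),
            ("early_censor_fraction", self.early_censor_fraction),
            ("female_fraction", self.female_fraction),
            ("feature_correlation", self.feature_correlation),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {value}")
        for f in self.features:
            if f not in self.assessment_prevalence:
                raise ValidationError(f"assessment_prevalence missing feature {f!r}")
            if not 0.0 < self.assessment_prevalence[f] < 1.0:
                raise ValidationError(f"assessment_prevalence[{f!r}] must be in (0,1)")
        for event in EVENTS:
            for f, hr in self.hazard_ratios.get(event, {}).items():
                if f not in self.features:
                    raise ValidationError(f"hazard_ratios[{event!r}] names unknown feature {f!r}")
                if hr <= 0:
                    raise ValidationError(f"hazard_ratios[{event!r}][{f!r}] must be > 0")
        if self.baseline_hazard is not None:
            for event, h0 in self.baseline_hazard.items():
                if h0 < 0:
                    raise ValidationError(f"baseline_hazard[{event!r}] must be >= 0")
        if self.horizon_months < MIN_FOLLOWUP_MONTHS:
            raise ValidationError("horizon_months must allow the 60-month minimum follow-up")
        if self.sensitivity + self.specificity <= 1.0:
            raise ValidationError("rater channel must be informative: sensitivity+specificity > 1")


def latent_prevalence(config: GeneratorConfig) -> dict[str, float]:
    """Back-solve the latent prevalence so the expected pooled assessment
    prevalence hits the configured target through the rater error model."""
    denom = config.sensitivity + config.specificity - 1.0
    out = {}
    for f in config.features:
        target = config.assessment_prevalence[f]
        p = (target - (1.0 - config.specificity)) / denom
        out[f] = float(np.clip(p, 0.01, 0.99))
    return out


def _expected_event_fraction(h0: float, multipliers: np.ndarray, weights: np.ndarray, config: GeneratorConfig) -> float:
    """E[P(event observed before censoring)] under the censoring mixture."""
    lam = h0 * multipliers
    H, L, f = config.horizon_months, MIN_FOLLOWUP_MONTHS, config.early_censor_fraction
    with np.errstate(divide="ignore", invalid="ignore"):
        surv_admin = np.exp(-lam * H)
        surv_early = np.where(
            lam > 0, (np.exp(-lam * L) - np.exp(-lam * H)) / (lam * (H - L)), 1.0
        )
    p_event = 1.0 - ((1 - f) * surv_admin + f * surv_early)
    return float(np.sum(weights * p_event))


def _risk_multipliers(config: GeneratorConfig, event: str) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of exp(sum L_j log HR_j) over latent profiles.

    Enumerates combinations of the features with non-null hazard ratios
    (independence case); falls back to a deterministic Monte Carlo draw when
    the shared-severity copula is on.
    """
    prev = latent_prevalence(config)
    hrs = {f: hr for f, hr in config.hazard_ratios.get(event, {}).items() if hr != 1.0}
    active = sorted(hrs)
    if not active:
        return np.array([1.0]), np.array([1.0])
    if config.feature_correlation == 0.0 and len(active) <= 16:
        mult, wts = np.array([1.0]), np.array([1.0])
        for f in active:
            p = prev[f]
            mult = np.concatenate([mult, mult * hrs[f]])
            wts = np.concatenate([wts * (1 - p), wts * p])
        return mult, wts
    rng = np.random.default_rng(987654321)  # internal, calibration-only
    n = 40000
    lat = _draw_latent(rng, n, config, prev)
    logm = np.zeros(n)
    for f in active:
        logm += lat[f].to_numpy() * np.log(hrs[f])
    return np.exp(logm), np.full(n, 1.0 / n)


def calibrate_baseline_hazard(config: GeneratorConfig) -> dict[str, float]:
    """Per-event exponential baseline hazard (per month) hitting the target
    expected observed event fraction, by root-finding."""
    out = {}
    for event in EVENTS:
        target = config.target_event_rate[event]
        mult, wts = _risk_multipliers(config, event)
        fn = lambda h0: _expected_event_fraction(h0, mult, wts, config) - target
        out[event] = float(brentq(fn, 1e-9, 10.0, xtol=1e-12))
    return out


def _draw_latent(
    rng: np.random.Generator, n: int, config: GeneratorConfig, prev: Mapping[str, float]
) -> pd.DataFrame:
    """Latent feature matrix; optional shared-severity copula couples the
    six scoring features."""
    rho = config.feature_correlation
    cols = {}
    z = rng.standard_normal(n)
    for f in config.features:
        if rho > 0 and f in SIX_POINT_FEATURES:
            u = norm.cdf(rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(n))
        else:
            u = rng.uniform(size=n)
        cols[f] = (u < prev[f]).astype(int)
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class SyntheticStudy:
    panel: RatingPanel
    records: list[CohortRecord]
    truth: pd.DataFrame  # latent features + per-event hazards per case
    config: GeneratorConfig
    baseline_hazard: dict[str, float]


def default_config(seed: int, **overrides) -> GeneratorConfig:
    cfg = GeneratorConfig(seed=seed)
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


def generate(config: GeneratorConfig) -> SyntheticStudy:
    """Draw a full synthetic study: rating panel, cohort table, latent truth.

    Fully reproducible: identical config (including seed) gives
    byte-identical outputs. The returned truth frame carries the latent
    feature vector and the per-event hazard of every case, so parameter-
    recovery loops can close against the generating values.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    width = max(4, len(str(n)))
    case_ids = [f"case_{i + 1:0{width}d}" for i in range(n)]
    raters = [f"R{j + 1}" for j in range(config.n_raters)]
    prev = latent_prevalence(config)

    latent = _draw_latent(rng, n, config, prev)
    latent.index = pd.Index(case_ids, name="case_id")

    # rater channel: flip latent through sensitivity/specificity
    blocks = []
    for rater in raters:
        u = rng.uniform(size=latent.shape)
        prob1 = np.where(latent.to_numpy() == 1, config.sensitivity, 1 - config.specificity)
        obs = (u < prob1).astype(float)
        frame = pd.DataFrame(obs, columns=latent.columns)
        frame.index = pd.MultiIndex.from_arrays(
            [case_ids, [rater] * n], names=["case_id", "rater_id"]
        )
        blocks.append(frame)
    panel_data = pd.concat(blocks).sort_index(
        level="case_id", sort_remaining=False, kind="stable"
    )
    # preserve generation order: cases in id order, raters in panel order
    panel_data = panel_data.reindex(
        pd.MultiIndex.from_product([case_ids, raters], names=["case_id", "rater_id"])
    )
    panel = RatingPanel(panel_data, tuple(config.features))

    # covariates
    age = np.clip(np.round(rng.normal(config.age_mean, config.age_sd, n)), 25, 95)
    gender = np.where(rng.uniform(size=n) < config.female_fraction, "female", "male")
    site_names = list(config.site_weights)
    site_p = np.array([config.site_weights[s] for s in site_names], float)
    site = rng.choice(site_names, size=n, p=site_p / site_p.sum())
    trt_names = list(config.treatment_weights)
    trt_p = np.array([config.treatment_weights[t] for t in trt_names], float)
    treatment = rng.choice(trt_names, size=n, p=trt_p / trt_p.sum())

    # grade: ordinal logistic on the latent six-feature count, cutpoints set
    # so the marginal matches the cohort's grade mix at the mean count
    count6 = latent[[f for f in SIX_POINT_FEATURES if f in latent.columns]].sum(axis=1).to_numpy()
    mean_count = float(np.sum([prev[f] for f in SIX_POINT_FEATURES if f in prev]))
    b = config.grade_slope
    c_mild = float(np.log(0.31 / 0.69)) + b * mean_count
    c_mod = float(np.log(0.75 / 0.25)) + b * mean_count
    u = rng.uniform(size=n)
    p_mild = expit(c_mild - b * count6)
    p_mild_mod = expit(c_mod - b * count6)
    who = np.where(u < p_mild, "mild", np.where(u < p_mild_mod, "moderate", "severe"))
    c_low = float(np.log(0.67 / 0.33)) + b * mean_count
    binary = np.where(rng.uniform(size=n) < expit(c_low - b * count6), "low", "high")

    # outcomes
    h0 = dict(config.baseline_hazard) if config.baseline_hazard is not None else calibrate_baseline_hazard(config)
    early = rng.uniform(size=n) < config.early_censor_fraction
    censor = np.where(
        early,
        rng.uniform(MIN_FOLLOWUP_MONTHS, config.horizon_months, n),
        config.horizon_months,
    )
    censor = np.round(censor, config.time_decimals)

    truth = latent.copy()
    truth["six_point_count"] = count6
    event_data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for event in EVENTS:
        loghr = np.zeros(n)
        for f, hr in config.hazard_ratios.get(event, {}).items():
            loghr += latent[f].to_numpy() * np.log(hr)
        lam = h0[event] * np.exp(loghr)
        with np.errstate(divide="ignore"):
            scale = np.where(lam > 0, 1.0 / np.maximum(lam, 1e-300), np.inf)
        t = np.where(lam > 0, rng.exponential(1.0, n) * scale, np.inf)
        t = np.round(t, config.time_decimals)
        occurred = t <= censor
        time = np.where(occurred, np.maximum(t, 10.0**-config.time_decimals), censor)
        event_data[event] = (occurred.astype(int), time)
        truth[f"{event}_hazard"] = lam

    records = []
    for i, cid in enumerate(case_ids):
        records.append(
            CohortRecord(
                case_id=cid,
                age=float(age[i]),
                gender=str(gender[i]),
                site=str(site[i]),
                who_grade=str(who[i]),
                binary_grade=str(binary[i]),
                treatment=str(treatment[i]),
                transformation_event=int(event_data["transformation"][0][i]),
                transformation_time=float(event_data["transformation"][1][i]),
                recurrence_event=int(event_data["recurrence"][0][i]),
                recurrence_time=float(event_data["recurrence"][1][i]),
                followup_time=float(censor[i]),
            )
        )
        records[-1].validate()
    return SyntheticStudy(panel, records, truth, config, h0)


def calibration_report(study: SyntheticStudy) -> dict:
    """Compare the realised study against the generator's targets.

    Reports pooled prevalences vs targets, observed event fractions vs
    targets, the agreement-statistic range the rater noise produced, and —
    where identifiable — hazard ratios refitted from the latent truth.
    JSON-serialisable.
    """
    config = study.config
    frame = cohort_to_frame(study.records)
    long = study.panel.data
    report: dict = {"n_cases": config.n_cases, "degenerate": False, "flags": []}

    prev = {}
    for f in study.panel.features:
        col = long[f]
        prev[f] = {
            "target": float(config.assessment_prevalence[f]),
            "realised": float(col.mean()),
        }
    report["assessment_prevalence"] = prev

    summaries = agreement_table(study.panel) if config.n_raters >= 2 else []
    if summaries:
        report["agreement"] = {
            s.feature: {"kappa": s.kappa, "ac1": s.ac1, "pa": s.pa} for s in summaries
        }

    report["events"] = {}
    for event in EVENTS:
        observed = int(frame[f"{event}_event"].sum())
        rate = observed / config.n_cases
        report["events"][event] = {
            "target_rate": float(config.target_event_rate[event]),
            "observed": observed,
            "observed_rate": rate,
            "baseline_hazard": study.baseline_hazard[event],
        }
        if observed == 0:
            report["degenerate"] = True
            report["flags"].append(f"no {event} events: calibration degenerate")

    fitted: dict = {}
    for event in EVENTS:
        fitted[event] = {}
        for f, hr in config.hazard_ratios.get(event, {}).items():
            if hr == 1.0:
                continue
            try:
                fit = cox_fit(frame, event, study.truth[[f]].astype(float))
                fitted[event][f] = {"true": float(hr), "fitted": float(fit.hazard_ratio[0])}
            except (FitError, ValidationError):
                fitted[event][f] = {"true": float(hr), "fitted": None}
    report["fitted_hazard_ratios"] = fitted
    return report


def single_feature_cohort(
    n: int,
    prevalence: float,
    hazard_ratio: float,
    baseline_hazard: float,
    seed: int,
    horizon_months: float = 120.0,
    event: str = "transformation",
) -> pd.DataFrame:
    """Minimal one-covariate survival cohort for parameter-recovery studies.

    Binary feature ~ Bernoulli(prevalence); event time exponential with rate
    ``baseline_hazard * hazard_ratio**feature``; administrative censoring at
    the horizon. Returns a frame (index case_id) with the feature column and
    the ``{event}_time`` / ``{event}_event`` columns :func:`oedprog.cox_fit`
    expects.
    """
    if event not in EVENTS:
        raise ValidationError(f"unknown event {event!r}")
    rng = np.random.default_rng(seed)
    x = (rng.uniform(size=n) < prevalence).astype(float)
    lam = baseline_hazard * hazard_ratio**x
    t = rng.exponential(1.0, n) / lam
    observed = t <= horizon_months
    frame = pd.DataFrame(
        {
            "feature": x,
            f"{event}_time": np.where(observed, t, horizon_months),
            f"{event}_event": observed.astype(int),
        },
        index=pd.Index([f"case_{i + 1}" for i in range(n)], name="case_id"),
    )
    return frame


def panel_from_marginals(
    n_positive: int,
    n_unanimous: int,
    n_cases: int = 109,
    feature: str = "verrucous_surface",
    n_raters: int = 3,
) -> RatingPanel:
    """Build a three-rater panel realising printed agreement-table marginals.

    For three binary raters the pair (positive assessments, complete-
    agreement cases) pins down every agreement statistic: non-unanimous
    cases are necessarily 2-1 splits. This constructs one panel consistent
    with those marginals (unanimous-positive, 2-1, 1-2 and unanimous-
    negative blocks), raising if the pair is infeasible.
    """
    if n_raters != 3:
        raise ValidationError("marginal reconstruction is specific to 3 raters")
    if not 0 <= n_unanimous <= n_cases:
        raise ValidationError("n_unanimous must be in [0, n_cases]")
    splits = n_cases - n_unanimous
    solution = None
    for two_votes in range(splits + 1):
        rem = n_positive - splits - two_votes
        if rem % 3 == 0 and 0 <= rem // 3 <= n_unanimous:
            solution = (rem // 3, two_votes)
            break
    if solution is None:
        raise ValidationError(
            f"marginals infeasible: {n_positive} positives with {n_unanimous} unanimous of {n_cases}"
        )
    unan_pos, two_votes = solution
    rows = (
        [(1, 1, 1)] * unan_pos
        + [(1, 1, 0)] * two_votes
        + [(1, 0, 0)] * (splits - two_votes)
        + [(0, 0, 0)] * (n_unanimous - unan_pos)
    )
    case_ids = [f"case_{i + 1:04d}" for i in range(n_cases)]
    raters = ["R1", "R2", "R3"]
    index = pd.MultiIndex.from_product([case_ids, raters], names=["case_id", "rater_id"])
    values = np.array(rows, dtype=float).reshape(-1, 1)
    data = pd.DataFrame(values, index=index, columns=[feature])
    vocab = FEATURES if feature in FEATURES else FEATURES + (feature,)
    return RatingPanel(data, vocab)
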