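"""Discrimination analysis for the prognostic models.

The outcome here is binary — did the event (transformation or recurrence)
occur at any time during follow-up — not the time to it. AUROC is the
Mann-Whitney probability that a random event case outscores a random
non-event case (ties count one half); correlated AUCs on the same cases are
compared with DeLong's test. Covariate-augmented models combine the score
with age, gender and/or histological grade through an in-sample logistic
model, mirroring how point scores are typically extended with clinical
covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

from .cohort import (
    CohortRecord,
    ConsensusProfile,
    RatingPanel,
    ValidationError,
    cohort_to_frame,
    profiles_to_frame,
)
from .consensus import consensus_profiles, rater_profiles
from .scoring import MODELS, score_cohort
from .survival import EVENTS, _as_frame

AUGMENT_COVARIATES = ("age", "gender", "who_grade", "binary_grade")

WHO_ORDINAL = {"mild": 1, "moderate": 2, "severe": 3}


@dataclass(frozen=True)
class ROCResult:
    """ROC curve and AUROC for one predictor against one binary outcome."""

    predictor: str
    event: str
    case_ids: tuple[str, ...]
    scores: np.ndarray
    events: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    notes: tuple[str, ...] = field(default_factory=tuple)


def _placements(scores: np.ndarray, events: np.ndarray):
    """Midrank placement values (V10, V01) and the AUC they average to."""
    pos = scores[events == 1]
    neg = scores[events == 0]
    m, n = len(pos), len(neg)
    r_all = rankdata(np.concatenate([pos, neg]))
    v10 = (r_all[:m] - rankdata(pos)) / n
    v01 = 1.0 - (r_all[m:] - rankdata(neg)) / m
    return float(v10.mean()), v10, v01


def auroc(
    scores: Sequence[float],
    events: Sequence[int],
    predictor: str = "score",
    event: str = "event",
    case_ids: Sequence[str] | None = None,
) -> ROCResult:
    """Rank-based AUROC with midrank tie handling plus the full ROC point set."""
    s = np.asarray(scores, dtype=float)
    e = np.asarray(events, dtype=int)
    if s.shape != e.shape or s.ndim != 1:
        raise ValidationError("scores and events must be 1-d and aligned")
    n_pos, n_neg = int(e.sum()), int((1 - e).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            f"degenerate outcome for {predictor!r}: needs at least one event and one non-event"
        )
    auc, _, _ = _placements(s, e)
    fpr, tpr, thr = roc_curve(e, s)
    ids = tuple(case_ids) if case_ids is not None else tuple(str(i) for i in range(len(s)))
    return ROCResult(predictor, event, ids, s, e, fpr, tpr, thr, auc, n_pos, n_neg)


def compare_auroc(a: ROCResult, b: ROCResult) -> dict:
    """DeLong test for two correlated AUCs computed on the same cases.

    Returns the AUC difference (a - b), its variance, z and the two-sided p.
    Antisymmetric in (a, b); identical predictors give difference 0, p = 1.
    """
    if a.case_ids != b.case_ids:
        raise ValidationError("compare_auroc requires identical case sets (same order)")
    if not np.array_equal(a.events, b.events):
        raise ValidationError("compare_auroc requires identical outcomes")
    auc_a, v10_a, v01_a = _placements(a.scores, a.events)
    auc_b, v10_b, v01_b = _placements(b.scores, b.events)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
        z = 0.0 if diff == 0 else np.sign(diff) * np.inf
    else:
        z = diff / np.sqrt(var)
        p = float(2 * norm.sf(abs(z)))
    return {"auc_a": auc_a, "auc_b": auc_b, "difference": diff, "variance": var, "z": float(z), "p": p}


def event_indicator(frame: pd.DataFrame, event: str) -> pd.Series:
    if event not in EVENTS:
        raise ValidationError(f"unknown event {event!r}")
    return frame[f"{event}_event"].astype(int)


def incidence_table(
    cohort: Iterable[CohortRecord] | pd.DataFrame,
    profiles: Sequence[ConsensusProfile],
) -> pd.DataFrame:
    """Event counts and percentages among feature-positive and -negative cases.

    One row per feature; columns per event give positive/negative-arm counts
    and percentages. A zero denominator yields a NaN percentage (rendered as
    an em dash in text exports, never as 0%).
    """
    frame = _as_frame(cohort)
    presence = profiles_to_frame(profiles).reindex(frame.index)
    if presence.isna().any().any():
        raise ValidationError("profiles do not cover all cohort cases")
    rows = []
    for feature in presence.columns:
        pos_mask = presence[feature] == 1
        row: dict = {"feature": feature, "n_positive": int(pos_mask.sum()), "n_negative": int((~pos_mask).sum())}
        for event in EVENTS:
            ev = event_indicator(frame, event)
            for arm, mask in (("positive", pos_mask), ("negative", ~pos_mask)):
                k, d = int(ev[mask].sum()), int(mask.sum())
                row[f"{event}_{arm}_events"] = k
                row[f"{event}_{arm}_pct"] = 100.0 * k / d if d else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _encode_covariates(frame: pd.DataFrame, names: Sequence[str]) -> pd.DataFrame:
    """Numeric design columns: age as-is, gender 0/1, WHO grade ordinal 1-3,
    binary grade 0/1."""
    cols = {}
    for name in names:
        if name == "age":
            cols["age"] = frame["age"].astype(float)
        elif name == "gender":
            cols["gender_male"] = (frame["gender"] == "male").astype(float)
        elif name == "who_grade":
            cols["who_grade_ord"] = frame["who_grade"].map(WHO_ORDINAL).astype(float)
        elif name == "binary_grade":
            cols["binary_grade_high"] = (frame["binary_grade"] == "high").astype(float)
        else:
            raise ValidationError(
                f"unsupported covariate {name!r}; expected subset of {AUGMENT_COVARIATES}"
            )
    return pd.DataFrame(cols, index=frame.index)


def augmented_model_auroc(
    score: Mapping[str, float] | pd.Series,
    cohort: Iterable[CohortRecord] | pd.DataFrame,
    covariates: Sequence[str],
    event: str,
    predictor: str | None = None,
) -> ROCResult:
    """AUROC of a logistic model combining the score with clinical covariates.

    The model is fit and evaluated in-sample (no held-out split). Complete
    separation falls back to a ridge-penalised logistic fit and is flagged
    in the result's notes. With no covariates this reduces exactly to the
    score-only AUROC, since the logistic transform is monotone.
    """
    import statsmodels.api as sm

    frame = _as_frame(cohort)
    s = pd.Series(score).reindex(frame.index)
    if s.isna().any():
        raise ValidationError("score does not cover all cohort cases")
    y = event_indicator(frame, event)
    design = _encode_covariates(frame, covariates)
    design.insert(0, "score", s.astype(float))
    label = predictor or ("score" + "".join(f"+{c}" for c in covariates))

    if design.shape[1] == 1:
        return auroc(design["score"], y, label, event, frame.index)

    notes: list[str] = []
    X = sm.add_constant(design.to_numpy(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y.to_numpy(int), X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True) or not np.all(np.isfinite(fit.bse)):
            raise np.linalg.LinAlgError("logistic fit ill-conditioned")
        prob = fit.predict(X)
    except Exception:  # separation / singular design -> penalised fallback
        clf = LogisticRegression(C=1.0, max_iter=1000)
        clf.fit(design.to_numpy(float), y.to_numpy(int))
        prob = clf.predict_proba(design.to_numpy(float))[:, 1]
        notes.append("separation: ridge-penalised logistic fallback used")

    result = auroc(prob, y, label, event, frame.index)
    return ROCResult(**{**result.__dict__, "notes": tuple(notes)})


def per_rater_evaluation(
    panel: RatingPanel,
    cohort: Iterable[CohortRecord] | pd.DataFrame,
    models: Sequence[str] = MODELS,
) -> pd.DataFrame:
    """AUROC of each model for each event, per rater and for consensus.

    Rows are (model, event); columns one per rater plus ``consensus``.
    Scores are recomputed from each rater's own profile, reflecting
    single-assessor use of the models in practice.
    """
    frame = _as_frame(cohort)
    sources: dict[str, list[ConsensusProfile]] = {
        f"rater:{r}": rater_profiles(panel, r) for r in panel.raters
    }
    sources["consensus"] = consensus_profiles(panel)
    rows = []
    for model in models:
        for event in EVENTS:
            y = event_indicator(frame, event)
            row: dict = {"model": model, "event": event}
            for name, profiles in sources.items():
                results, _ = score_cohort(profiles, model)
                s = pd.Series({r.case_id: r.score for r in results}).reindex(frame.index)
                row[name] = auroc(s, y, f"{model}[{name}]", event, frame.index).auc
            rows.append(row)
    return pd.DataFrame(rows)
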