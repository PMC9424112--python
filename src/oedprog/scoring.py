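"""Feature-count prognostic scores.

Two equal-weight point models over the consensus (or single-rater) feature
profile:

* six-point model — one point per present feature among bulbous/drop-shaped
  rete pegs, hyperchromatism, loss of epithelial cohesion, loss of
  stratification, suprabasal mitoses and nuclear pleomorphism; reported in
  risk strata 0-1 / 2-3 / 4-6;
* two-point model — loss of epithelial cohesion and bulbous rete pegs only,
  reported as the four presence categories (neither / cohesion_only /
  bulbous_only / both).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .cohort import ConsensusProfile, DuplicateKeyError, ValidationError
from .features import SIX_POINT_FEATURES, TWO_POINT_FEATURES

SIX_POINT_STRATA = ((0, 1, "0-1"), (2, 3, "2-3"), (4, 6, "4-6"))

MODELS = ("six_point", "two_point")


@dataclass(frozen=True)
class ScoreResult:
    case_id: str
    model: str
    score: int
    stratum: str
    source: str


def _require(profile: ConsensusProfile, features: Sequence[str]) -> list[int]:
    vals = []
    for f in features:
        if f not in profile.presence:
            raise ValidationError(
                f"case {profile.case_id}: scoring feature {f!r} missing from profile"
            )
        vals.append(int(profile.presence[f]))
    return vals


def six_point_stratum(score: int, strata=SIX_POINT_STRATA) -> str:
    for lo, hi, label in strata:
        if lo <= score <= hi:
            return label
    raise ValidationError(f"score {score} outside configured strata")


def six_point_score(
    profile: ConsensusProfile, strata=SIX_POINT_STRATA
) -> ScoreResult:
    """Count of the six scoring features present (0-6), with its risk stratum.

    The stratum cut-points default to 0-1 / 2-3 / 4-6 but are configurable;
    threshold exploration belongs to the evaluation module, not here.
    """
    score = sum(_require(profile, SIX_POINT_FEATURES))
    return ScoreResult(
        profile.case_id, "six_point", score, six_point_stratum(score, strata), profile.source
    )


def two_point_score(profile: ConsensusProfile) -> ScoreResult:
    """Count of the two high-agreement features (0-2) with presence category."""
    cohesion, bulbous = _require(profile, TWO_POINT_FEATURES)
    category = {
        (0, 0): "neither",
        (1, 0): "cohesion_only",
        (0, 1): "bulbous_only",
        (1, 1): "both",
    }[(cohesion, bulbous)]
    return ScoreResult(
        profile.case_id, "two_point", cohesion + bulbous, category, profile.source
    )


def score_cohort(
    profiles: Sequence[ConsensusProfile], model: str
) -> tuple[list[ScoreResult], dict[str, int]]:
    """Score every profile; returns results sorted by case_id plus the
    per-stratum count summary (for logging/reporting)."""
    if not profiles:
        raise ValidationError("empty profile list")
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}; expected one of {MODELS}")
    ids = [p.case_id for p in profiles]
    dupes = [i for i, c in Counter(ids).items() if c > 1]
    if dupes:
        raise DuplicateKeyError(f"duplicate case_id in profiles: {sorted(dupes)}")
    scorer = six_point_score if model == "six_point" else two_point_score
    results = sorted((scorer(p) for p in profiles), key=lambda r: r.case_id)
    counts = dict(Counter(r.stratum for r in results))
    return results, counts
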