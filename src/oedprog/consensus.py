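"""Majority-rule consensus calling and single-rater profile extraction.

A feature is called present for a case when at least ``min_agree`` raters
scored it 1 (default: strict majority, i.e. 2 of 3). Missing assessments
reduce a case's effective panel size but never the threshold, which keeps
the rule conservative when votes are absent; this situation is logged.
"""

from __future__ import annotations

import logging
import math

from .cohort import ConsensusProfile, RatingPanel, ValidationError

logger = logging.getLogger(__name__)


def default_min_agree(n_raters: int) -> int:
    """Strict majority threshold: smallest integer exceeding r/2."""
    return math.floor(n_raters / 2) + 1


def consensus_profiles(
    panel: RatingPanel, min_agree: int | None = None
) -> list[ConsensusProfile]:
    """Call each feature present iff >= ``min_agree`` raters scored it 1.

    Parameters
    ----------
    panel
        Multi-rater assessment panel.
    min_agree
        Vote threshold; defaults to a strict majority of the panel's raters
        (2 of 3 for the three-rater design).
    """
    r = panel.n_raters
    if r == 0:
        return []
    if min_agree is None:
        min_agree = default_min_agree(r)
    if not 1 <= min_agree <= r:
        raise ValidationError(
            f"min_agree must be between 1 and the number of raters ({r}), got {min_agree}"
        )
    n_missing = int(panel.data.isna().to_numpy().sum())
    if n_missing:
        logger.warning(
            "consensus over %d missing assessments: absolute threshold %d kept, "
            "missing votes count as non-endorsements",
            n_missing,
            min_agree,
        )
    votes = panel.data.groupby(level="case_id", sort=False).sum(min_count=1)
    calls = (votes >= min_agree).astype(int)
    return [
        ConsensusProfile(case_id, row.to_dict(), source="consensus")
        for case_id, row in calls.iterrows()
    ]


def rater_profiles(panel: RatingPanel, rater_id: str) -> list[ConsensusProfile]:
    """Extract one rater's assessments as profiles (source=``rater:<id>``).

    Output shape is identical to :func:`consensus_profiles`, so scoring and
    evaluation accept either. Missing assessments are treated as absent
    (logged), mirroring the consensus rule.
    """
    if rater_id not in panel.raters:
        raise ValidationError(f"unknown rater {rater_id!r} (panel has {panel.raters})")
    sub = panel.data.xs(rater_id, level="rater_id")
    n_missing = int(sub.isna().to_numpy().sum())
    if n_missing:
        logger.warning(
            "rater %s has %d missing assessments; treated as absent", rater_id, n_missing
        )
    calls = sub.fillna(0).astype(int)
    return [
        ConsensusProfile(case_id, row.to_dict(), source=f"rater:{rater_id}")
        for case_id, row in calls.iterrows()
    ]
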