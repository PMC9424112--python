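"""Inter-rater agreement statistics for binary feature panels.

For each feature the panel yields, per case, the votes of r raters. Let

* ``Pa`` — observed agreement: the fraction of agreeing rater pairs, pooled
  over cases (each case weighted by its own number of available pairs, so
  missing assessments are handled by pairwise deletion);
* ``pi`` — pooled prevalence: positive assessments / all assessments.

Two chance corrections are reported:

* Fleiss-type kappa, with chance agreement ``Pe = pi^2 + (1-pi)^2`` from the
  pooled category marginals. With complete data this coincides with Fleiss'
  multi-rater kappa.
* Gwet's AC1, with chance agreement ``Pe = 2*pi*(1-pi)``, which stays
  well-behaved at prevalence extremes where kappa collapses.

Both equal ``(Pa - Pe) / (1 - Pe)``. For binary ratings the two chance terms
sum to 1, hence AC1 >= kappa whenever pi != 0.5.

An average-pairwise Cohen's kappa (rater-specific marginals, averaged over
rater pairs) is available as a non-default variant.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd

from .cohort import RatingPanel, ValidationError


@dataclass(frozen=True)
class AgreementSummary:
    """Per-feature prevalence and agreement statistics."""

    feature: str
    n_cases: int
    n_raters: int
    positive_assessments: int
    prevalence: float
    complete_agreement_count: int
    complete_agreement_fraction: float
    pa: float
    pe_kappa: float
    pe_ac1: float
    kappa: float
    ac1: float

    def as_dict(self) -> dict:
        return asdict(self)


def report_round(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, as agreement tables are conventionally printed."""
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _pair_counts(mat: np.ndarray) -> tuple[float, float, int, int]:
    """(agreeing pairs, total pairs, complete-agreement cases, included cases).

    ``mat`` is cases x raters with NaN for missing. Cases with fewer than two
    non-missing votes contribute no pairs and are excluded from the
    complete-agreement denominator.
    """
    k = np.nansum(mat, axis=1)  # positive votes per case
    m = np.sum(~np.isnan(mat), axis=1).astype(float)  # votes per case
    incl = m >= 2
    if not incl.any():
        raise ValidationError("no case has >= 2 non-missing assessments")
    k, m = k[incl], m[incl]
    # agreeing pairs: both positive or both negative
    agree = k * (k - 1) / 2 + (m - k) * (m - k - 1) / 2
    pairs = m * (m - 1) / 2
    complete = int(np.sum((k == 0) | (k == m)))
    return float(agree.sum()), float(pairs.sum()), complete, int(incl.sum())


def observed_agreement(panel: RatingPanel, feature: str) -> tuple[float, float]:
    """Return (Pa, complete-agreement fraction) for one feature.

    Pa pools agreeing rater pairs over all pairs; with three raters a
    non-unanimous case contributes exactly one agreeing pair in three.
    """
    mat = panel.feature_matrix(feature).to_numpy(dtype=float)
    agree, pairs, complete, n_incl = _pair_counts(mat)
    return agree / pairs, complete / n_incl


def _summary(panel: RatingPanel, feature: str) -> AgreementSummary:
    mat = panel.feature_matrix(feature).to_numpy(dtype=float)
    agree, pairs, complete, n_incl = _pair_counts(mat)
    pa = agree / pairs
    n_pos = int(np.nansum(mat))
    n_total = int(np.sum(~np.isnan(mat)))
    pi = n_pos / n_total
    pe_ac1 = 2 * pi * (1 - pi)
    pe_kappa = pi**2 + (1 - pi) ** 2
    ac1 = (pa - pe_ac1) / (1 - pe_ac1)
    if pe_kappa >= 1.0:
        warnings.warn(
            f"feature {feature!r}: all assessments in one category (pi={pi}); "
            "kappa undefined",
            RuntimeWarning,
            stacklevel=3,
        )
        kappa = float("nan")
    else:
        kappa = (pa - pe_kappa) / (1 - pe_kappa)
    return AgreementSummary(
        feature=feature,
        n_cases=n_incl,
        n_raters=panel.n_raters,
        positive_assessments=n_pos,
        prevalence=pi,
        complete_agreement_count=complete,
        complete_agreement_fraction=complete / n_incl,
        pa=pa,
        pe_kappa=pe_kappa,
        pe_ac1=pe_ac1,
        kappa=kappa,
        ac1=ac1,
    )


def gwet_ac1(panel: RatingPanel, feature: str) -> AgreementSummary:
    """Full agreement summary; the AC1 statistic is the headline field."""
    return _summary(panel, feature)


def multirater_kappa(
    panel: RatingPanel, feature: str, variant: str = "pooled"
) -> AgreementSummary:
    """Chance-corrected kappa for r raters.

    ``variant="pooled"`` (default) is the Fleiss-type kappa on pooled
    marginals. ``variant="pairwise_cohen"`` averages two-rater Cohen's kappa
    (rater-specific marginals) over all rater pairs; reported in the kappa
    field with the pooled Pe left in place for reference.
    """
    summ = _summary(panel, feature)
    if variant == "pooled":
        return summ
    if variant != "pairwise_cohen":
        raise ValueError(f"unknown kappa variant {variant!r}")
    mat = panel.feature_matrix(feature).to_numpy(dtype=float)
    kappas = []
    for i, j in combinations(range(mat.shape[1]), 2):
        ok = ~np.isnan(mat[:, i]) & ~np.isnan(mat[:, j])
        if ok.sum() < 2:
            continue
        a, b = mat[ok, i], mat[ok, j]
        po = float(np.mean(a == b))
        pa_i, pa_j = float(a.mean()), float(b.mean())
        pe = pa_i * pa_j + (1 - pa_i) * (1 - pa_j)
        if pe < 1.0:
            kappas.append((po - pe) / (1 - pe))
    if not kappas:
        raise ValidationError(f"feature {feature!r}: no rater pair with shared data")
    return AgreementSummary(**{**summ.as_dict(), "kappa": float(np.mean(kappas))})


def agreement_table(panel: RatingPanel) -> list[AgreementSummary]:
    """One summary per feature, in canonical vocabulary order."""
    if panel.n_cases == 0:
        raise ValidationError("empty panel")
    if panel.n_raters < 2:
        raise ValidationError("agreement needs at least 2 raters")
    return [_summary(panel, f) for f in panel.features]


def agreement_frame(summaries: list[AgreementSummary]) -> pd.DataFrame:
    """Tabular export mirroring the printed agreement-table layout."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "feature": s.feature,
                "n_positive": s.positive_assessments,
                "prevalence": report_round(s.prevalence),
                "complete_agreement": report_round(s.complete_agreement_fraction),
                "kappa": report_round(s.kappa),
                "ac1": report_round(s.ac1),
            }
        )
    return pd.DataFrame(rows)
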