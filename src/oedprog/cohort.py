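"""Domain types, CSV readers/writers and validation.

Three containers travel through the pipeline:

* :class:`RatingPanel` — per-case, per-rater, per-feature binary assessments
  (the raw unit of the multi-observer review; missing assessments allowed).
* :class:`CohortRecord` — clinical covariates plus the two time-to-event
  outcomes (malignant transformation and recurrence) for one case.
* :class:`ConsensusProfile` — one binary feature vector per case, either
  from majority-rule consensus or from a single rater.

Times are months from the baseline biopsy; the minimum follow-up rule for
censored cases is five years (60 months).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .features import FEATURES, canonical_feature

MIN_FOLLOWUP_MONTHS = 60.0

GENDERS = ("female", "male")
SITES = (
    "tongue",
    "floor_of_mouth",
    "buccal_mucosa",
    "gingivae",
    "hard_palate",
    "lower_lip",
    "soft_palate",
)
WHO_GRADES = ("mild", "moderate", "severe")
BINARY_GRADES = ("low", "high")
TREATMENTS = ("monitored", "excised", "laser")

RATINGS_COLUMNS = ("case_id", "rater_id", "feature", "present")
COHORT_COLUMNS = (
    "case_id",
    "age",
    "gender",
    "site",
    "who_grade",
    "binary_grade",
    "treatment",
    "transformation_event",
    "transformation_time",
    "recurrence_event",
    "recurrence_time",
    "followup_time",
)


class ValidationError(ValueError):
    """Input data violates a pipeline contract."""


class SchemaError(ValidationError):
    """A required column is missing or mistyped."""


class ParseError(ValidationError):
    """A row holds an unparseable value; message names the line number."""


class DuplicateKeyError(ValidationError):
    """The same logical key appears more than once."""


@dataclass(frozen=True)
class RatingPanel:
    """Ternary-coded assessments for every (case, rater, feature) cell.

    ``data`` is a wide frame indexed by (case_id, rater_id) with one float
    column per feature: 1.0 present, 0.0 absent, NaN missing.
    """

    data: pd.DataFrame
    vocabulary: tuple[str, ...] = FEATURES

    def __post_init__(self) -> None:
        extra = [c for c in self.data.columns if c not in self.vocabulary]
        if extra:
            raise ValidationError(f"features outside vocabulary: {extra}")

    @property
    def cases(self) -> tuple[str, ...]:
        return tuple(self.data.index.get_level_values("case_id").unique())

    @property
    def raters(self) -> tuple[str, ...]:
        return tuple(self.data.index.get_level_values("rater_id").unique())

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def n_raters(self) -> int:
        return len(self.raters)

    @property
    def n_assessments(self) -> int:
        """Number of non-missing assessments across all features."""
        return int(self.data.notna().to_numpy().sum())

    def feature_matrix(self, feature: str) -> pd.DataFrame:
        """Case x rater matrix (float; NaN = missing) for one feature."""
        if feature not in self.data.columns:
            raise ValidationError(f"feature {feature!r} not in panel")
        return self.data[feature].unstack("rater_id").reindex(
            index=list(self.cases), columns=list(self.raters)
        )

    def to_long(self) -> pd.DataFrame:
        """Long frame (case_id, rater_id, feature, present); missing dropped."""
        long = (
            self.data.stack(future_stack=True)
            .rename_axis(["case_id", "rater_id", "feature"])
            .rename("present")
            .dropna()
            .astype(int)
            .reset_index()
        )
        return long


@dataclass(frozen=True)
class CohortRecord:
    """Clinical covariates and outcomes for one case.

    Event times and ``followup_time`` are months from baseline biopsy.
    ``followup_time`` is the planned observation time; censored cases
    (neither event) must reach the 60-month minimum follow-up unless the
    strict inclusion rule is relaxed at read time.
    """

    case_id: str
    age: float
    gender: str
    site: str
    who_grade: str
    binary_grade: str
    treatment: str
    transformation_event: int
    transformation_time: float
    recurrence_event: int
    recurrence_time: float
    followup_time: float

    def validate(self, strict_followup: bool = True) -> None:
        def _cat(value: str, levels: tuple[str, ...], name: str) -> None:
            if value not in levels:
                raise ValidationError(
                    f"case {self.case_id}: unknown {name} level {value!r} "
                    f"(expected one of {levels})"
                )

        if not self.age > 0:
            raise ValidationError(f"case {self.case_id}: age must be > 0")
        _cat(self.gender, GENDERS, "gender")
        _cat(self.site, SITES, "site")
        _cat(self.who_grade, WHO_GRADES, "who_grade")
        _cat(self.binary_grade, BINARY_GRADES, "binary_grade")
        _cat(self.treatment, TREATMENTS, "treatment")
        for ev, t, label in (
            (self.transformation_event, self.transformation_time, "transformation"),
            (self.recurrence_event, self.recurrence_time, "recurrence"),
        ):
            if ev not in (0, 1):
                raise ValidationError(
                    f"case {self.case_id}: {label}_event must be 0 or 1"
                )
            if not np.isfinite(t) or t <= 0:
                raise ValidationError(
                    f"case {self.case_id}: {label}_time must be a positive number"
                )
            if t > self.followup_time + 1e-9:
                raise ValidationError(
                    f"case {self.case_id}: {label}_time exceeds followup_time"
                )
        if (
            strict_followup
            and self.transformation_event == 0
            and self.recurrence_event == 0
            and self.followup_time < MIN_FOLLOWUP_MONTHS
        ):
            raise ValidationError(
                f"case {self.case_id}: censored with followup_time "
                f"{self.followup_time} < {MIN_FOLLOWUP_MONTHS} months "
                "(minimum five-year follow-up rule)"
            )


@dataclass(frozen=True)
class ConsensusProfile:
    """Per-case binary feature vector with its provenance.

    ``source`` is ``"consensus"`` for majority-rule profiles or
    ``"rater:<id>"`` when extracted from a single rater, so per-rater and
    consensus profiles are interchangeable downstream.
    """

    case_id: str
    presence: dict[str, int] = field(default_factory=dict)
    source: str = "consensus"

    def __post_init__(self) -> None:
        for feat, val in self.presence.items():
            if val not in (0, 1):
                raise ValidationError(
                    f"case {self.case_id}: feature {feat!r} presence must be 0/1"
                )


def profiles_to_frame(profiles: Sequence[ConsensusProfile]) -> pd.DataFrame:
    """Stack profiles into a case x feature 0/1 frame (index case_id)."""
    if not profiles:
        raise ValidationError("empty profile list")
    ids = [p.case_id for p in profiles]
    dupes = pd.Index(ids)[pd.Index(ids).duplicated()].tolist()
    if dupes:
        raise DuplicateKeyError(f"duplicate case_id in profiles: {dupes}")
    frame = pd.DataFrame([p.presence for p in profiles], index=pd.Index(ids, name="case_id"))
    return frame.astype(int)


# ---------------------------------------------------------------------------
# ratings CSV


def read_ratings(
    path: str | Path,
    vocabulary: Sequence[str] | None = None,
    allow_extra: bool = False,
) -> RatingPanel:
    """Read a long-format ratings CSV into a validated :class:`RatingPanel`.

    Expected columns: ``case_id, rater_id, feature, present`` with present
    in {0, 1} (an empty cell marks a missing assessment). Duplicate
    (case, rater, feature) rows are an error; feature names outside the
    vocabulary are an error unless ``allow_extra`` is set.
    """
    vocab = tuple(vocabulary) if vocabulary is not None else FEATURES
    try:
        raw = pd.read_csv(path, dtype={"case_id": str, "rater_id": str, "feature": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, expected header") from exc
    missing_cols = [c for c in RATINGS_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing required columns {missing_cols}")
    if raw.empty:
        empty = pd.DataFrame(
            columns=list(vocab),
            index=pd.MultiIndex.from_arrays([[], []], names=["case_id", "rater_id"]),
            dtype=float,
        )
        return RatingPanel(empty, vocab)

    canon = []
    extra_vocab = list(vocab)
    for i, name in enumerate(raw["feature"]):
        try:
            canon.append(canonical_feature(name, tuple(extra_vocab)))
        except KeyError:
            if allow_extra:
                from .features import _slug

                slug = _slug(str(name))
                extra_vocab.append(slug)
                canon.append(slug)
            else:
                raise ParseError(
                    f"{path}, line {i + 2}: feature {name!r} not in vocabulary"
                ) from None
    raw = raw.assign(feature=canon)

    present = pd.to_numeric(raw["present"], errors="coerce")
    bad = present.notna() & ~present.isin([0, 1])
    unparsed = raw["present"].notna() & present.isna()
    for mask, what in ((bad, "present value outside {0,1}"), (unparsed, "unparseable present value")):
        if mask.any():
            line = int(np.flatnonzero(mask.to_numpy())[0]) + 2
            raise ParseError(f"{path}, line {line}: {what} ({raw['present'][mask].iloc[0]!r})")
    raw = raw.assign(present=present)

    dup = raw.duplicated(subset=["case_id", "rater_id", "feature"], keep=False)
    if dup.any():
        keys = (
            raw.loc[dup, ["case_id", "rater_id", "feature"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        raise DuplicateKeyError(f"{path}: duplicate (case,rater,feature) rows: {sorted(keys)}")

    wide = raw.pivot(
        index=["case_id", "rater_id"], columns="feature", values="present"
    ).astype(float)
    wide = wide.reindex(columns=[f for f in extra_vocab if f in wide.columns])
    wide.columns.name = None
    return RatingPanel(wide, tuple(extra_vocab))


def write_ratings(panel: RatingPanel, path: str | Path) -> None:
    panel.to_long().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cohort CSV


def read_cohort(path: str | Path, strict_followup: bool = True) -> list[CohortRecord]:
    """Read and validate the clinical covariate + outcome table."""
    raw = pd.read_csv(path, dtype={"case_id": str})
    missing_cols = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing required columns {missing_cols}")
    dup = raw["case_id"].duplicated(keep=False)
    if dup.any():
        raise DuplicateKeyError(
            f"{path}: duplicate case_id: {sorted(raw.loc[dup, 'case_id'].unique())}"
        )
    records = []
    for i, row in enumerate(raw.itertuples(index=False)):
        try:
            rec = CohortRecord(
                case_id=str(row.case_id),
                age=float(row.age),
                gender=str(row.gender),
                site=str(row.site),
                who_grade=str(row.who_grade),
                binary_grade=str(row.binary_grade),
                treatment=str(row.treatment),
                transformation_event=int(row.transformation_event),
                transformation_time=float(row.transformation_time),
                recurrence_event=int(row.recurrence_event),
                recurrence_time=float(row.recurrence_time),
                followup_time=float(row.followup_time),
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}, line {i + 2}: {exc}") from exc
        rec.validate(strict_followup=strict_followup)
        records.append(rec)
    return records


def cohort_to_frame(records: Iterable[CohortRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return frame.set_index("case_id")


def write_cohort(records: Iterable[CohortRecord], path: str | Path) -> None:
    cohort_to_frame(records).reset_index().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# consensus CSV


def write_consensus(profiles: Sequence[ConsensusProfile], path: str | Path) -> None:
    frame = profiles_to_frame(profiles)
    frame.insert(0, "source", [p.source for p in profiles])
    frame.reset_index().to_csv(path, index=False)


def read_consensus(path: str | Path) -> list[ConsensusProfile]:
    raw = pd.read_csv(path, dtype={"case_id": str})
    if "case_id" not in raw.columns:
        raise SchemaError(f"{path}: missing case_id column")
    features = [c for c in raw.columns if c not in ("case_id", "source")]
    profiles = []
    for row in raw.itertuples(index=False):
        presence = {f: int(getattr(row, f)) for f in features}
        source = getattr(row, "source", "consensus")
        profiles.append(ConsensusProfile(str(row.case_id), presence, str(source)))
    return profiles
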