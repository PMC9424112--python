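"""AUROC, DeLong comparison, incidence tables and per-rater evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oedprog.cohort import ValidationError
from oedprog.consensus import consensus_profiles
from oedprog.evaluation import (
    augmented_model_auroc,
    auroc,
    compare_auroc,
    incidence_table,
    per_rater_evaluation,
)


def brute_force_auc(scores, events):
    """Oracle: all (positive, negative) pairs, ties worth one half."""
    pos = scores[events == 1]
    neg = scores[events == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestAuroc:
    @pytest.mark.parametrize(
        "scores,events,expected",
        [
            ([0, 1, 2, 3], [0, 0, 1, 1], 1.0),
            ([0, 1, 1, 2], [0, 1, 0, 1], 0.875),
            ([3, 2, 1, 0], [0, 0, 1, 1], 0.0),
            ([1, 1, 1, 1], [0, 1, 0, 1], 0.5),
        ],
    )
    def test_known_values(self, scores, events, expected):
        assert auroc(scores, events).auc == pytest.approx(expected)

    def test_degenerate_outcome_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            auroc([1, 2, 3], [1, 1, 1])

    @given(st.integers(0, 2**31 - 1), st.integers(4, 60))
    @settings(max_examples=100, deadline=None)
    def test_rank_formula_matches_pairwise_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 7, n).astype(float)  # heavy ties on purpose
        events = rng.integers(0, 2, n)
        if events.sum() in (0, n):
            return
        result = auroc(scores, events)
        assert result.auc == pytest.approx(brute_force_auc(scores, events), abs=1e-12)
        assert np.all(np.diff(result.fpr) >= 0) and np.all(np.diff(result.tpr) >= 0)


class TestCompareAuroc:
    def test_self_comparison_is_exactly_null(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=80)
        e = (rng.uniform(size=80) < 0.4).astype(int)
        a = auroc(s, e)
        out = compare_auroc(a, a)
        assert out["difference"] == 0.0 and out["p"] == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        e = (rng.uniform(size=100) < 0.3).astype(int)
        a = auroc(rng.normal(size=100) + e, e)
        b = auroc(rng.normal(size=100), e)
        ab, ba = compare_auroc(a, b), compare_auroc(b, a)
        assert ab["difference"] == pytest.approx(-ba["difference"])
        assert ab["p"] == pytest.approx(ba["p"])

    def test_monotone_transform_leaves_p_unchanged(self):
        rng = np.random.default_rng(2)
        e = (rng.uniform(size=120) < 0.35).astype(int)
        s1 = rng.normal(size=120) + 0.8 * e
        s2 = rng.normal(size=120) + 0.3 * e
        base = compare_auroc(auroc(s1, e), auroc(s2, e))
        warped = compare_auroc(auroc(np.exp(s1), e), auroc(s2**3 + 5 * s2, e))
        assert warped["p"] == pytest.approx(base["p"], abs=1e-12)

    def test_case_order_invariance(self):
        rng = np.random.default_rng(3)
        e = (rng.uniform(size=60) < 0.4).astype(int)
        s1, s2 = rng.normal(size=60), rng.normal(size=60)
        ids = [f"c{i}" for i in range(60)]
        base = compare_auroc(auroc(s1, e, case_ids=ids), auroc(s2, e, case_ids=ids))
        perm = rng.permutation(60)
        shuf = compare_auroc(
            auroc(s1[perm], e[perm], case_ids=[ids[i] for i in perm]),
            auroc(s2[perm], e[perm], case_ids=[ids[i] for i in perm]),
        )
        assert shuf["p"] == pytest.approx(base["p"], abs=1e-12)

    def test_mismatched_cases_rejected(self):
        e = np.array([0, 1, 0, 1])
        a = auroc([1, 2, 3, 4], e, case_ids=list("abcd"))
        b = auroc([1, 2, 3, 4], e, case_ids=list("abce"))
        with pytest.raises(ValidationError, match="identical case sets"):
            compare_auroc(a, b)


class TestIncidence:
    def test_percentages_consistent_with_counts(self, study, study_frame):
        table = incidence_table(study_frame, consensus_profiles(study.panel))
        assert len(table) == 12
        for _, row in table.iterrows():
            assert row["n_positive"] + row["n_negative"] == len(study_frame)
            for event in ("transformation", "recurrence"):
                for arm in ("positive", "negative"):
                    n = row[f"n_{arm}"]
                    k = row[f"{event}_{arm}_events"]
                    pct = row[f"{event}_{arm}_pct"]
                    if n:
                        assert pct == pytest.approx(100 * k / n)
                    else:
                        assert np.isnan(pct)

    def test_all_positive_feature_leaves_negative_arm_undefined(self, study_frame):
        from oedprog.cohort import ConsensusProfile

        profiles = [
            ConsensusProfile(cid, {"bulbous_rete_pegs": 1}) for cid in study_frame.index
        ]
        table = incidence_table(study_frame, profiles).iloc[0]
        assert table["n_negative"] == 0
        assert np.isnan(table["transformation_negative_pct"])

    def test_zero_event_cohort_gives_zero_incidence(self, study_frame):
        from oedprog.cohort import ConsensusProfile

        frame = study_frame.copy()
        frame[["transformation_event", "recurrence_event"]] = 0
        profiles = [
            ConsensusProfile(cid, {"dyskeratosis": i % 2})
            for i, cid in enumerate(frame.index)
        ]
        table = incidence_table(frame, profiles).iloc[0]
        assert table["transformation_positive_pct"] == 0.0
        assert table["recurrence_negative_pct"] == 0.0


class TestAugmentedModels:
    def test_score_only_model_equals_raw_auroc(self, study_frame):
        rng = np.random.default_rng(4)
        score = pd.Series(rng.integers(0, 7, len(study_frame)), index=study_frame.index)
        raw = auroc(score, study_frame["transformation_event"].astype(int))
        fitted = augmented_model_auroc(score, study_frame, (), "transformation")
        assert fitted.auc == pytest.approx(raw.auc, abs=1e-12)

    def test_uninformative_covariates_do_not_change_auroc_much(self):
        rng = np.random.default_rng(6)
        n = 3000
        score = rng.integers(0, 7, n).astype(float)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(2.2 - 0.5 * score))).astype(int)
        frame = pd.DataFrame(
            {
                "transformation_event": y,
                "age": rng.normal(65, 10, n),
                "gender": rng.choice(["male", "female"], n),
                "who_grade": rng.choice(["mild", "moderate", "severe"], n),
                "binary_grade": rng.choice(["low", "high"], n),
            },
            index=pd.Index([f"c{i}" for i in range(n)], name="case_id"),
        )
        base = auroc(score, y).auc
        aug = augmented_model_auroc(
            pd.Series(score, index=frame.index), frame, ("age", "gender"), "transformation"
        )
        assert aug.auc == pytest.approx(base, abs=0.02)

    def test_informative_grade_raises_auroc(self, study, study_frame):
        from oedprog.scoring import score_cohort

        results, _ = score_cohort(consensus_profiles(study.panel), "six_point")
        score = pd.Series({r.case_id: r.score for r in results}).reindex(study_frame.index)
        base = auroc(score, study_frame["transformation_event"].astype(int)).auc
        aug = augmented_model_auroc(score, study_frame, ("who_grade",), "transformation")
        assert aug.auc >= base - 0.02  # in-sample logistic never loses much

    def test_separation_falls_back_to_penalised_fit(self):
        n = 40
        y = np.array([0] * 20 + [1] * 20)
        frame = pd.DataFrame(
            {
                "transformation_event": y,
                "age": np.where(y == 1, 80.0, 40.0),  # perfectly separates
                "gender": ["male"] * 40,
                "who_grade": ["mild"] * 40,
                "binary_grade": ["low"] * 40,
            },
            index=pd.Index([f"c{i}" for i in range(n)], name="case_id"),
        )
        score = pd.Series(np.r_[np.zeros(20), np.ones(20)], index=frame.index)
        result = augmented_model_auroc(score, frame, ("age",), "transformation")
        assert result.auc == 1.0
        assert any("penalised" in note for note in result.notes)


class TestPerRater:
    def test_perfect_raters_match_consensus(self, perfect_study):
        from oedprog.cohort import cohort_to_frame

        frame = cohort_to_frame(perfect_study.records)
        table = per_rater_evaluation(perfect_study.panel, frame)
        assert len(table) == 4  # 2 models x 2 events
        for _, row in table.iterrows():
            for rater in ("rater:R1", "rater:R2", "rater:R3"):
                assert row[rater] == pytest.approx(row["consensus"], abs=1e-12)

    def test_noisy_raters_tend_not_to_beat_consensus(self, study, study_frame):
        table = per_rater_evaluation(study.panel, study_frame)
        rater_cols = [c for c in table.columns if c.startswith("rater:")]
        mean_rater = table[rater_cols].mean(axis=1)
        # expected ordering in aggregate: consensus discriminates at least
        # as well as the average single rater, with slack for one draw
        assert (mean_rater <= table["consensus"] + 0.05).all()
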