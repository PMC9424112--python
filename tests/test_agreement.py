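"""Agreement statistics: closed forms, oracles and invariances.

The printed agreement table for the 109-case, three-rater panel is exactly
determined by two marginals per feature — positive assessments (of 327) and
complete-agreement cases (of 109) — because every non-unanimous case is a
2-1 split. Panels rebuilt from those marginals must reproduce the printed
kappa and AC1 at two decimal places.
"""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.inter_rater import fleiss_kappa

from oedprog.agreement import (
    agreement_frame,
    agreement_table,
    gwet_ac1,
    multirater_kappa,
    observed_agreement,
    report_round,
)
from oedprog.cohort import RatingPanel, ValidationError
from oedprog.simulate import panel_from_marginals

from conftest import build_panel, random_panel

# feature, positive assessments (of 327), unanimous cases (of 109),
# published kappa / AC1 (None where the printed cell is not reproducible
# from the pooled-marginal formulas)
PUBLISHED_AGREEMENT = [
    ("verrucous_surface", 85, 92, 0.73, 0.83),
    ("loss_of_epithelial_cohesion", 98, 80, 0.58, 0.69),
    ("bulbous_rete_pegs", 187, 72, 0.54, 0.56),
    ("abrupt_orthokeratosis", 174, 81, None, 0.66),
    ("lymphocytic_band", 112, 79, None, 0.67),
    ("dyskeratosis", 110, 68, None, 0.55),
]


def brute_force_pa(panel, feature):
    """Oracle: enumerate every rater pair in every case."""
    mat = panel.feature_matrix(feature).to_numpy()
    agree = total = 0
    for row in mat:
        votes = row[~np.isnan(row)]
        for a, b in combinations(votes, 2):
            agree += a == b
            total += 1
    return agree / total


class TestPublishedMarginals:
    @pytest.mark.parametrize("feature,x,u,kappa,ac1", PUBLISHED_AGREEMENT)
    def test_marginals_reproduce_published_statistics(self, feature, x, u, kappa, ac1):
        panel = panel_from_marginals(x, u, feature=feature)
        summ = gwet_ac1(panel, feature)
        assert summ.positive_assessments == x
        assert summ.complete_agreement_count == u
        assert report_round(summ.ac1) == ac1
        if kappa is not None:
            assert report_round(summ.kappa) == kappa

    def test_verrucous_surface_observed_agreement(self):
        # 92 unanimous cases, 17 two-one splits contributing 1/3 each
        panel = panel_from_marginals(85, 92, feature="verrucous_surface")
        pa, complete = observed_agreement(panel, "verrucous_surface")
        assert pa == pytest.approx((92 + 17 / 3) / 109, abs=1e-12)
        assert complete == pytest.approx(92 / 109, abs=1e-12)


class TestObservedAgreement:
    def test_all_unanimous_gives_perfect_agreement(self):
        panel = build_panel([(1, 1, 1), (0, 0, 0)])
        pa, complete = observed_agreement(panel, "verrucous_surface")
        assert pa == 1.0 and complete == 1.0

    def test_four_raters_split_two_two_contributes_one_third(self):
        panel = build_panel([(1, 1, 0, 0)])
        pa, _ = observed_agreement(panel, "verrucous_surface")
        assert pa == pytest.approx(2 / 6)
        assert pa == pytest.approx(brute_force_pa(panel, "verrucous_surface"))

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValidationError, match="not in panel"):
            observed_agreement(build_panel([(1, 0, 1)]), "dyskeratosis")

    @given(st.integers(0, 2**31 - 1), st.integers(2, 50), st.integers(2, 5),
           st.sampled_from([0.0, 0.15]))
    @settings(max_examples=80, deadline=None)
    def test_closed_form_matches_pair_enumeration(self, seed, n, r, missing):
        rng = np.random.default_rng(seed)
        panel = random_panel(rng, n, r, missing_rate=missing)
        mat = panel.feature_matrix("verrucous_surface").to_numpy()
        if (np.sum(~np.isnan(mat), axis=1) < 2).all():
            return
        pa, _ = observed_agreement(panel, "verrucous_surface")
        assert pa == pytest.approx(brute_force_pa(panel, "verrucous_surface"), abs=1e-12)


class TestChanceCorrection:
    def test_perfect_agreement_regardless_of_prevalence(self):
        panel = build_panel([(1, 1, 1)] * 3 + [(0, 0, 0)] * 17)
        summ = gwet_ac1(panel, "verrucous_surface")
        assert summ.ac1 == 1.0 and summ.kappa == 1.0

    def test_degenerate_single_category_flags_kappa_nan(self):
        panel = build_panel([(1, 1, 1)] * 5)
        with pytest.warns(RuntimeWarning, match="kappa undefined"):
            summ = multirater_kappa(panel, "verrucous_surface")
        assert np.isnan(summ.kappa)
        assert summ.ac1 == 1.0  # AC1 chance term maxes at 0.5, stays defined

    def test_random_ratings_at_half_prevalence_give_near_zero_kappa(self):
        rng = np.random.default_rng(2024)
        panel = random_panel(rng, 10_000, 3)
        summ = multirater_kappa(panel, "verrucous_surface")
        assert abs(summ.kappa) < 0.02
        assert abs(summ.ac1) < 0.02  # chance terms coincide at pi = 0.5

    def test_pooled_kappa_matches_statsmodels_fleiss(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            panel = random_panel(rng, int(rng.integers(5, 60)), int(rng.integers(2, 6)))
            mat = panel.feature_matrix("verrucous_surface").to_numpy()
            counts = np.column_stack([(mat == 0).sum(axis=1), (mat == 1).sum(axis=1)])
            if counts[:, 1].sum() in (0, counts.sum()):
                continue
            summ = multirater_kappa(panel, "verrucous_surface")
            assert summ.kappa == pytest.approx(fleiss_kappa(counts, method="fleiss"), abs=1e-10)

    @given(st.integers(0, 2**31 - 1), st.integers(3, 40), st.integers(2, 5))
    @settings(max_examples=60, deadline=None)
    def test_ac1_dominates_kappa_off_half_prevalence(self, seed, n, r):
        import warnings

        rng = np.random.default_rng(seed)
        panel = random_panel(rng, n, r)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # degenerate pi draws
            summ = gwet_ac1(panel, "verrucous_surface")
        if np.isnan(summ.kappa) or summ.prevalence == 0.5:
            return
        assert summ.ac1 >= summ.kappa - 1e-12
        if summ.pa < 1.0:
            assert summ.ac1 > summ.kappa

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_invariance_under_label_swap_and_permutations(self, seed):
        rng = np.random.default_rng(seed)
        panel = random_panel(rng, 25, 3)
        summ = gwet_ac1(panel, "verrucous_surface")
        # swap present/absent on every assessment
        swapped = RatingPanel(1.0 - panel.data, panel.vocabulary)
        summ_sw = gwet_ac1(swapped, "verrucous_surface")
        assert summ_sw.kappa == pytest.approx(summ.kappa, abs=1e-12)
        assert summ_sw.ac1 == pytest.approx(summ.ac1, abs=1e-12)
        # shuffle cases
        perm = rng.permutation(25)
        cases = panel.feature_matrix("verrucous_surface").to_numpy()[perm]
        shuffled = build_panel([tuple(row) for row in cases.astype(int)])
        summ_sh = gwet_ac1(shuffled, "verrucous_surface")
        assert summ_sh.kappa == pytest.approx(summ.kappa, abs=1e-12)
        assert summ_sh.ac1 == pytest.approx(summ.ac1, abs=1e-12)

    def test_pairwise_cohen_variant_is_an_alternative_kappa(self):
        rng = np.random.default_rng(5)
        panel = random_panel(rng, 60, 3)
        pooled = multirater_kappa(panel, "verrucous_surface")
        pairwise = multirater_kappa(panel, "verrucous_surface", variant="pairwise_cohen")
        assert pairwise.kappa <= 1.0
        assert pairwise.pa == pooled.pa  # only the chance model differs
        with pytest.raises(ValueError, match="variant"):
            multirater_kappa(panel, "verrucous_surface", variant="weighted")


class TestAgreementTable:
    def test_full_panel_table_is_ordered_and_bounded(self, study):
        summaries = agreement_table(study.panel)
        assert [s.feature for s in summaries] == list(study.panel.features)
        for s in summaries:
            assert 0.0 <= s.pa <= 1.0 and 0.0 <= s.pe_ac1 <= 0.5
            assert s.pa >= s.complete_agreement_fraction
            assert s.kappa <= 1.0 and s.ac1 <= 1.0

    def test_frame_export_has_report_columns(self, study):
        frame = agreement_frame(agreement_table(study.panel))
        assert list(frame.columns) == [
            "feature", "n_positive", "prevalence", "complete_agreement", "kappa", "ac1",
        ]
        assert len(frame) == 12

    def test_rounding_is_half_away_from_zero(self):
        assert report_round(0.625) == 0.63
        assert report_round(0.615) == 0.62
        assert report_round(-0.625) == -0.63

    def test_single_feature_panel_gives_single_row(self):
        panel = build_panel([(1, 0, 1), (0, 0, 0)])
        assert len(agreement_table(panel)) == 1

    def test_fewer_than_two_raters_rejected(self):
        with pytest.raises(ValidationError, match="2 raters"):
            agreement_table(build_panel([(1,), (0,)]))
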