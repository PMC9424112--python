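import numpy as np
import pandas as pd
import pytest

from oedprog.cohort import RatingPanel, cohort_to_frame
from oedprog.features import FEATURES
from oedprog.simulate import default_config, generate


def build_panel(votes, feature="verrucous_surface", vocabulary=None):
    """Panel for one feature from per-case vote tuples.

    ``votes`` is a list of tuples, one per case; tuple length sets the
    number of raters; None marks a missing assessment.
    """
    n_raters = len(votes[0])
    case_ids = [f"case_{i + 1:04d}" for i in range(len(votes))]
    raters = [f"R{j + 1}" for j in range(n_raters)]
    index = pd.MultiIndex.from_product([case_ids, raters], names=["case_id", "rater_id"])
    values = [np.nan if v is None else float(v) for row in votes for v in row]
    data = pd.DataFrame({feature: values}, index=index)
    vocab = vocabulary or (FEATURES if feature in FEATURES else FEATURES + (feature,))
    return RatingPanel(data, tuple(vocab))


def build_multifeature_panel(case_feature_votes, raters=("R1", "R2", "R3")):
    """Panel from {case_id: {feature: (votes...)}} nested dicts."""
    features = sorted({f for d in case_feature_votes.values() for f in d})
    rows = {}
    for cid, per_feature in case_feature_votes.items():
        for j, rater in enumerate(raters):
            rows[(cid, rater)] = {
                f: float(per_feature[f][j]) if per_feature[f][j] is not None else np.nan
                for f in features
            }
    data = pd.DataFrame.from_dict(rows, orient="index")
    data.index = pd.MultiIndex.from_tuples(data.index, names=["case_id", "rater_id"])
    vocab = tuple(FEATURES) + tuple(f for f in features if f not in FEATURES)
    return RatingPanel(data[features], vocab)


def random_panel(rng, n_cases, n_raters, missing_rate=0.0, feature="verrucous_surface"):
    votes = []
    for _ in range(n_cases):
        row = [int(v) for v in rng.integers(0, 2, n_raters)]
        if missing_rate:
            row = [None if rng.uniform() < missing_rate else v for v in row]
        votes.append(tuple(row))
    return build_panel(votes, feature=feature)


@pytest.fixture(scope="session")
def study():
    """Default-size synthetic study (109 cases, 3 raters), fixed seed."""
    return generate(default_config(20240117))


@pytest.fixture(scope="session")
def study_frame(study):
    return cohort_to_frame(study.records)


@pytest.fixture(scope="session")
def perfect_study():
    """Noise-free raters: the panel equals the latent truth."""
    return generate(default_config(55, sensitivity=1.0, specificity=1.0))
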