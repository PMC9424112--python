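"""Canonical vocabulary of OED histological features.

The twelve most prominent architectural and cytological features assessed by
the rating panel. CSV files may use either the canonical snake_case
identifier or the printed display name (case-insensitive); both map to the
canonical identifier.
"""

from __future__ import annotations

import re

# canonical identifier -> printed display name
FEATURE_LABELS: dict[str, str] = {
    "basal_cell_hyperplasia": "Basal cell hyperplasia",
    "bulbous_rete_pegs": "Bulbous/drop shaped rete pegs",
    "dyskeratosis": "Dyskeratosis",
    "hyperchromatism": "Hyperchromatism",
    "irregular_surface_keratin": "Irregular surface keratin",
    "loss_of_epithelial_cohesion": "Loss of epithelial cohesion",
    "loss_of_stratification": "Loss of stratification",
    "suprabasal_mitoses": "Suprabasal mitoses",
    "nuclear_pleomorphism": "Nuclear pleomorphism",
    "abrupt_orthokeratosis": "Abrupt orthokeratosis",
    "lymphocytic_band": "Lymphocytic band",
    "verrucous_surface": "Verrucous surface",
}

FEATURES: tuple[str, ...] = tuple(FEATURE_LABELS)

# The six features entering the six-point prognostic score: those associated
# with both transformation and recurrence in univariate survival analysis.
SIX_POINT_FEATURES: tuple[str, ...] = (
    "bulbous_rete_pegs",
    "hyperchromatism",
    "loss_of_epithelial_cohesion",
    "loss_of_stratification",
    "suprabasal_mitoses",
    "nuclear_pleomorphism",
)

# The two features with the best inter-rater agreement among the six above.
TWO_POINT_FEATURES: tuple[str, ...] = (
    "loss_of_epithelial_cohesion",
    "bulbous_rete_pegs",
)


def _slug(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", name.strip().lower()).strip("_")


_ALIAS: dict[str, str] = {}
for _key, _label in FEATURE_LABELS.items():
    _ALIAS[_key] = _key
    _ALIAS[_slug(_label)] = _key
# common shorthand seen in hand-edited files
_ALIAS["bulbous_drop_shaped_rete_pegs"] = "bulbous_rete_pegs"


def canonical_feature(name: str, vocabulary: tuple[str, ...] | None = None) -> str:
    """Map a feature name (display name or identifier) to its canonical form.

    Names outside the built-in vocabulary are canonicalised to snake_case and
    accepted only when ``vocabulary`` explicitly lists them.

    Raises
    ------
    KeyError
        If the name is not in the (possibly extended) vocabulary.
    """
    slug = _slug(name)
    if slug in _ALIAS:
        return _ALIAS[slug]
    if vocabulary is not None and slug in vocabulary:
        return slug
    raise KeyError(f"unknown feature name: {name!r}")
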