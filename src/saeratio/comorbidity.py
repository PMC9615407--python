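"""Medication-derived multimorbidity counts.

Concomitant-medication categories act as a surrogate for prevalent chronic
conditions: each medication-class token maps to at most one of 21 broad
comorbidity categories (e.g. inhaled bronchodilators indicate obstructive
airways disease), and the multimorbidity count for a person is the number
of *distinct* categories with at least one qualifying medication.
Ambiguous drug classes used for diverse indications (e.g. tricyclic
antidepressants, also used for chronic pain) are carried on an exclusion
list and never counted.

The mapping is a user-supplied three-column TSV (``token``, ``category``,
``action`` with action in {include, exclude}).  The bundled default map
(``data/comorbidity_map.tsv``) is *synthetic*: it covers the 21 categories
with plausible medication-class tokens for testing and simulation, and is
not a clinically validated code list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: The 21 comorbidity categories, in canonical order.
DEFAULT_CATEGORIES: tuple[str, ...] = (
    "cardiovascular_disease",
    "chronic_pain",
    "arthritis",
    "affective_disorders",
    "acid_related_disorders",
    "asthma_copd",
    "diabetes_mellitus",
    "osteoporosis",
    "thyroid_disease",
    "thromboembolic_disease",
    "inflammatory_conditions",
    "benign_prostatic_hyperplasia",
    "gout",
    "glaucoma",
    "urinary_incontinence",
    "erectile_dysfunction",
    "psychotic_disorders",
    "epilepsy",
    "migraine",
    "parkinsonism",
    "dementia",
)


class ComorbidityMapError(ValueError):
    """Raised for invalid or internally inconsistent mapping files."""


@dataclass(frozen=True)
class ComorbidityMap:
    """Mapping from medication-class tokens to comorbidity categories.

    Parameters
    ----------
    categories
        Ordered category names; every mapped category must appear here.
    mapping
        token -> category.  Many-to-one; a token may map to one category only.
    exclusions
        Tokens never counted, regardless of any include row elsewhere.
    """

    categories: tuple[str, ...]
    mapping: dict[str, str] = field(default_factory=dict)
    exclusions: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        unknown = {c for c in self.mapping.values() if c not in self.categories}
        if unknown:
            raise ComorbidityMapError(
                f"mapped categories not in category list: {sorted(unknown)}"
            )
        clash = set(self.mapping) & set(self.exclusions)
        if clash:
            raise ComorbidityMapError(
                f"tokens both included and excluded: {sorted(clash)}"
            )

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def category_of(self, token: str) -> str | None:
        """Category for ``token``, or None if excluded/unknown."""
        if token in self.exclusions:
            return None
        return self.mapping.get(token)


def load_comorbidity_map(
    path: str | Path, categories: tuple[str, ...] | None = None
) -> ComorbidityMap:
    """Load and validate a mapping TSV with columns token/category/action.

    A token listed with ``action=exclude`` must not also carry an include
    row, and no token may map to two categories; either case raises
    :class:`ComorbidityMapError` listing the offending tokens.  An empty
    file (header only) yields an empty map: all downstream counts are zero.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"token", "category", "action"}
    missing = required - set(df.columns)
    if missing:
        raise ComorbidityMapError(f"mapping file missing columns: {sorted(missing)}")
    bad_action = df.loc[~df["action"].isin(["include", "exclude"]), "action"]
    if len(bad_action):
        raise ComorbidityMapError(
            f"invalid action values: {sorted(bad_action.unique())}"
        )

    inc = df[df["action"] == "include"]
    exc = df[df["action"] == "exclude"]

    conflicted = sorted(set(inc["token"]) & set(exc["token"]))
    if conflicted:
        raise ComorbidityMapError(
            f"tokens appear with both include and exclude actions: {conflicted}"
        )
    multi = inc.groupby("token")["category"].nunique()
    offenders = sorted(multi[multi > 1].index)
    if offenders:
        raise ComorbidityMapError(f"tokens mapped to two categories: {offenders}")

    mapping = dict(zip(inc["token"], inc["category"]))
    if categories is None:
        if mapping:
            # preserve canonical order where possible, append extras
            mapped = set(mapping.values())
            cats = [c for c in DEFAULT_CATEGORIES if c in mapped]
            cats += sorted(mapped - set(DEFAULT_CATEGORIES))
            categories = tuple(cats)
        else:
            categories = ()
    return ComorbidityMap(
        categories=categories,
        mapping=mapping,
        exclusions=frozenset(exc["token"]),
    )


def default_comorbidity_map() -> ComorbidityMap:
    """The bundled synthetic 21-category map (for tests and simulation)."""
    with resources.as_file(
        resources.files("saeratio").joinpath("data/comorbidity_map.tsv")
    ) as p:
        return load_comorbidity_map(p, categories=DEFAULT_CATEGORIES)


@dataclass(frozen=True)
class MMCount:
    """Multimorbidity count for one person/participant."""

    person_id: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("multimorbidity count must be nonnegative")


_warned_tokens: set[str] = set()


def count_comorbidities(
    medications: set[str],
    cmap: ComorbidityMap,
    index_condition_category: str | None = None,
    person_id: str = "",
) -> MMCount:
    """Distinct-category comorbidity count from a person's medication tokens.

    Duplicated tokens and multiple tokens within one category count once;
    excluded and unknown tokens contribute nothing (unknown tokens are
    logged once per token).  When ``index_condition_category`` is given,
    that category is removed from the count — comorbidities are conditions
    *other than* the trial's index condition.
    """
    cats: set[str] = set()
    for tok in medications:
        if tok in cmap.exclusions:
            continue
        cat = cmap.mapping.get(tok)
        if cat is None:
            if tok not in _warned_tokens:
                _warned_tokens.add(tok)
                logger.warning("unknown medication token ignored: %r", tok)
            continue
        cats.add(cat)
    cats.discard(index_condition_category)
    return MMCount(person_id=person_id, count=len(cats))


def counts_frame(
    meds_by_person: dict[str, set[str]],
    cmap: ComorbidityMap,
    index_condition_category: str | None = None,
) -> pd.DataFrame:
    """Per-person counts as a two-column DataFrame (person_id, mm_count)."""
    rows = [
        (pid, count_comorbidities(meds, cmap, index_condition_category, pid).count)
        for pid, meds in meds_by_person.items()
    ]
    return pd.DataFrame(rows, columns=["person_id", "mm_count"])
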