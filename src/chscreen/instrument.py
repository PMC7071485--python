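"""The 12-item cluster-headache screening instrument.

The questionnaire mixes six pain images, a 0-10 visual-analogue pain scale,
verbal pain descriptors, and key yes/no questions distinguishing cluster
headache (CH) from migraine.  Each raw categorical answer maps to an integer
test score; higher scores mark features characteristic of CH.  The total
score (sum of the 12 coded items) ranges from 3 to 32; a "no-images" variant
omits the image-preference item and ranges from 2 to 26.

Raw answers use a strict lowercase vocabulary (e.g. image ``a``..``f``,
durations ``le3h``/``>3h``); anything outside the vocabulary is rejected
rather than silently miscoded.  Missing answers propagate: an item score is
missing when its answer is, and a total is present only when every
contributing answer is.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "ItemId",
    "Diagnosis",
    "ItemDefinition",
    "ResponseRecord",
    "ScoredRecord",
    "UnknownCategoryError",
    "InstrumentConfigError",
    "canonical_items",
    "code_item",
    "score_record",
    "score_bounds",
    "score_frame",
    "read_cohort_csv",
    "write_cohort_csv",
    "cohort_to_frame",
    "ITEM_COLUMNS",
    "META_COLUMNS",
]


class ItemId(str, Enum):
    """The twelve questionnaire variables."""

    IMAGE_PREFERENCE = "image_preference"
    PAIN_SCALE = "pain_scale"
    INTENSITY = "intensity"
    NATURE_OF_PAIN = "nature_of_pain"
    DESCRIPTION_OF_PAIN = "description_of_pain"
    RESTLESSNESS = "restlessness"
    EXCRUCIATING_AGONY = "excruciating_agony"
    HEADACHE_SPECIFIC_TIMES = "headache_specific_times"
    STRICTLY_UNILATERAL = "strictly_unilateral"
    IPSILATERAL_AUTONOMIC = "ipsilateral_autonomic"
    TREATED_DURATION = "treated_duration"
    UNTREATED_DURATION = "untreated_duration"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Diagnosis(str, Enum):
    CH = "CH"
    MIGRAINE = "migraine"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The five strictly dichotomous yes/no questions.
BINARY_ITEMS: tuple[ItemId, ...] = (
    ItemId.RESTLESSNESS,
    ItemId.EXCRUCIATING_AGONY,
    ItemId.HEADACHE_SPECIFIC_TIMES,
    ItemId.STRICTLY_UNILATERAL,
    ItemId.IPSILATERAL_AUTONOMIC,
)

#: Items evaluated as dichotomous tests (coded 0/1): the five yes/no
#: questions plus pain description and the two attack durations.
DICHOTOMOUS_TEST_ITEMS: tuple[ItemId, ...] = BINARY_ITEMS + (
    ItemId.DESCRIPTION_OF_PAIN,
    ItemId.TREATED_DURATION,
    ItemId.UNTREATED_DURATION,
)

META_COLUMNS: tuple[str, ...] = ("patient_id", "diagnosis", "subtype", "sex", "age")
ITEM_COLUMNS: tuple[str, ...] = tuple(i.value for i in ItemId)


class UnknownCategoryError(ValueError):
    """Raised when a raw answer is outside an item's category vocabulary."""


class InstrumentConfigError(ValueError):
    """Raised for duplicate/missing item definitions."""


@dataclass(frozen=True)
class ItemDefinition:
    """One questionnaire item: admissible raw categories and their codes."""

    item_id: ItemId
    categories: tuple[str, ...]
    code_map: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = set(self.categories) - set(self.code_map)
        extra = set(self.code_map) - set(self.categories)
        if missing or extra:
            raise InstrumentConfigError(
                f"{self.item_id}: code_map must be total over categories "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )

    @property
    def min_score(self) -> int:
        return min(self.code_map.values())

    @property
    def max_score(self) -> int:
        return max(self.code_map.values())


@dataclass
class ResponseRecord:
    """One patient's raw answers plus diagnosis, subtype, sex and age."""

    patient_id: str
    diagnosis: Diagnosis
    subtype: str
    sex: str
    age: Optional[int]
    answers: dict[ItemId, Optional[str]] = field(default_factory=dict)


@dataclass
class ScoredRecord:
    """Coded item scores and totals for one patient.

    ``total_score`` is present only when all 12 answers are; ``total_no_images``
    only when the 11 non-image answers are.
    """

    patient_id: str
    diagnosis: Diagnosis
    sex: str
    item_scores: dict[ItemId, Optional[int]]
    total_score: Optional[int]
    total_no_images: Optional[int]


def canonical_items() -> tuple[ItemDefinition, ...]:
    """Load the canonical instrument definition shipped with the package."""
    text = resources.files("chscreen.data").joinpath("instrument.json").read_text()
    raw = json.loads(text)
    return tuple(
        ItemDefinition(
            item_id=ItemId(entry["item_id"]),
            categories=tuple(entry["categories"]),
            code_map={k: int(v) for k, v in entry["code_map"].items()},
        )
        for entry in raw["items"]
    )


def code_item(item: ItemDefinition, raw: Optional[str]) -> Optional[int]:
    """Map a raw answer to its coded test score; missing propagates."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    if raw not in item.code_map:
        raise UnknownCategoryError(
            f"item {item.item_id!s}: unknown category {raw!r} "
            f"(expected one of {list(item.categories)})"
        )
    return item.code_map[raw]


def _check_item_set(items: Sequence[ItemDefinition]) -> dict[ItemId, ItemDefinition]:
    by_id: dict[ItemId, ItemDefinition] = {}
    for it in items:
        if it.item_id in by_id:
            raise InstrumentConfigError(f"duplicate item definition: {it.item_id!s}")
        by_id[it.item_id] = it
    absent = set(ItemId) - set(by_id)
    if absent:
        raise InstrumentConfigError(
            f"missing item definitions: {sorted(i.value for i in absent)}"
        )
    return by_id


def score_record(
    rec: ResponseRecord, items: Optional[Sequence[ItemDefinition]] = None
) -> ScoredRecord:
    """Code one record and form totals where the contributing answers exist."""
    by_id = _check_item_set(items if items is not None else canonical_items())
    scores = {iid: code_item(by_id[iid], rec.answers.get(iid)) for iid in ItemId}
    total = (
        sum(scores[i] for i in ItemId)  # type: ignore[misc]
        if all(scores[i] is not None for i in ItemId)
        else None
    )
    non_image = [i for i in ItemId if i is not ItemId.IMAGE_PREFERENCE]
    total_ni = (
        sum(scores[i] for i in non_image)  # type: ignore[misc]
        if all(scores[i] is not None for i in non_image)
        else None
    )
    return ScoredRecord(
        patient_id=rec.patient_id,
        diagnosis=rec.diagnosis,
        sex=rec.sex,
        item_scores=scores,
        total_score=total,
        total_no_images=total_ni,
    )


def score_bounds(
    items: Optional[Sequence[ItemDefinition]] = None,
) -> tuple[int, int, int, int]:
    """(min_total, max_total, min_no_images, max_no_images) for an item set.

    For the canonical instrument this is (3, 32, 2, 26).  Partial instruments
    are allowed here (the image-free bounds then cover whatever non-image
    items are present).
    """
    items = tuple(items) if items is not None else canonical_items()
    lo = sum(it.min_score for it in items)
    hi = sum(it.max_score for it in items)
    non_img = [it for it in items if it.item_id is not ItemId.IMAGE_PREFERENCE]
    lo_ni = sum(it.min_score for it in non_img)
    hi_ni = sum(it.max_score for it in non_img)
    return lo, hi, lo_ni, hi_ni


# --- cohort table (CSV schema) -------------------------------------------

def cohort_to_frame(records: Iterable[ResponseRecord]) -> pd.DataFrame:
    """Flatten ResponseRecords into the cohort CSV schema."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "patient_id": r.patient_id,
            "diagnosis": r.diagnosis.value,
            "subtype": r.subtype,
            "sex": r.sex,
            "age": r.age,
        }
        for iid in ItemId:
            row[iid.value] = r.answers.get(iid)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + list(ITEM_COLUMNS))


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV (one row per patient; empty cell = missing)."""
    df = pd.read_csv(path, dtype={c: "string" for c in ITEM_COLUMNS} | {"patient_id": "string"})
    missing_cols = (set(META_COLUMNS) | set(ITEM_COLUMNS)) - set(df.columns)
    if missing_cols:
        raise ValueError(f"cohort CSV lacks columns: {sorted(missing_cols)}")
    bad = set(df["diagnosis"].dropna().unique()) - {d.value for d in Diagnosis}
    if bad:
        raise ValueError(f"unknown diagnosis labels: {sorted(bad)}")
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def score_frame(
    df: pd.DataFrame, items: Optional[Sequence[ItemDefinition]] = None
) -> pd.DataFrame:
    """Code every item column of a cohort table and append totals.

    Returns a copy of ``df`` with one ``score_<item>`` column per item (float,
    NaN = missing), plus ``total_score`` and ``total_no_images`` computed under
    the complete-case rule of :func:`score_record`.
    """
    by_id = _check_item_set(items if items is not None else canonical_items())
    out = df.copy()
    for iid, item in by_id.items():
        col = df[iid.value]
        known = col.dropna().unique()
        bad = set(known) - set(item.categories)
        if bad:
            raise UnknownCategoryError(
                f"item {iid!s}: unknown categories {sorted(bad)}"
            )
        out[f"score_{iid.value}"] = col.map(item.code_map).astype("float")
    score_cols = [f"score_{i.value}" for i in ItemId]
    ni_cols = [c for c in score_cols if c != f"score_{ItemId.IMAGE_PREFERENCE.value}"]
    out["total_score"] = out[score_cols].sum(axis=1, skipna=False)
    out["total_no_images"] = out[ni_cols].sum(axis=1, skipna=False)
    return out
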