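"""Coding of raw questionnaire answers and total-score formation."""

import hypothesis.strategies as st
import pandas as pd
import pytest
from hypothesis import given

from chscreen.instrument import (
    BINARY_ITEMS,
    Diagnosis,
    InstrumentConfigError,
    ItemId,
    ResponseRecord,
    UnknownCategoryError,
    canonical_items,
    code_item,
    cohort_to_frame,
    read_cohort_csv,
    score_bounds,
    score_frame,
    score_record,
    write_cohort_csv,
)
from conftest import all_max_answers, all_min_answers


def _by_id(items):
    return {it.item_id: it for it in items}


def _record(answers, pid="p1", diagnosis=Diagnosis.CH):
    return ResponseRecord(
        patient_id=pid, diagnosis=diagnosis, subtype="chronic", sex="male",
        age=40, answers={ItemId(k): v for k, v in answers.items()},
    )


@pytest.mark.parametrize(
    "item_id,raw,expected",
    [
        (ItemId.IMAGE_PREFERENCE, "d", 6),
        (ItemId.IMAGE_PREFERENCE, "f", 1),
        (ItemId.IMAGE_PREFERENCE, "a", 2),
        (ItemId.IMAGE_PREFERENCE, "c", 3),
        (ItemId.IMAGE_PREFERENCE, "b", 4),
        (ItemId.IMAGE_PREFERENCE, "e", 5),
        (ItemId.PAIN_SCALE, "0", 0),
        (ItemId.PAIN_SCALE, "7", 7),
        (ItemId.PAIN_SCALE, "10", 10),
        (ItemId.INTENSITY, "mild", 1),
        (ItemId.INTENSITY, "excruciating", 5),
        (ItemId.NATURE_OF_PAIN, "throbbing_other", 1),
        (ItemId.NATURE_OF_PAIN, "pressure", 2),
        (ItemId.NATURE_OF_PAIN, "stabbing_burning", 3),
        (ItemId.DESCRIPTION_OF_PAIN, "red_hot_poker", 1),
        (ItemId.DESCRIPTION_OF_PAIN, "pounding_heart_other", 0),
        (ItemId.RESTLESSNESS, "yes", 1),
        (ItemId.TREATED_DURATION, "le3h", 1),
        (ItemId.UNTREATED_DURATION, ">3h", 0),
    ],
)
def test_code_item_canonical_codes(items, item_id, raw, expected):
    assert code_item(_by_id(items)[item_id], raw) == expected


def test_code_item_missing_propagates(items):
    assert code_item(_by_id(items)[ItemId.RESTLESSNESS], None) is None


def test_code_item_rejects_unknown_category_naming_it(items):
    with pytest.raises(UnknownCategoryError, match="restlessness.*maybe"):
        code_item(_by_id(items)[ItemId.RESTLESSNESS], "maybe")


def test_binary_items_code_as_yes_indicator(items):
    by_id = _by_id(items)
    for iid in BINARY_ITEMS:
        assert code_item(by_id[iid], "yes") == 1
        assert code_item(by_id[iid], "no") == 0


def test_score_record_extremes(items):
    assert score_record(_record(all_min_answers()), items).total_score == 3
    hi = score_record(_record(all_max_answers()), items)
    assert hi.total_score == 32
    assert hi.total_no_images == 26


def test_score_record_missing_binary_blocks_total(items):
    ans = all_max_answers()
    ans["restlessness"] = None
    s = score_record(_record(ans), items)
    assert s.total_score is None
    assert s.total_no_images is None  # missing item is not the image item

    ans = all_max_answers()
    ans["image_preference"] = None
    s = score_record(_record(ans), items)
    assert s.total_score is None
    assert s.total_no_images == 26  # images are the only gap


def test_score_record_rejects_bad_item_sets(items):
    with pytest.raises(InstrumentConfigError, match="duplicate"):
        score_record(_record(all_min_answers()), list(items) + [items[0]])
    with pytest.raises(InstrumentConfigError, match="missing item"):
        score_record(_record(all_min_answers()), items[:-1])


def test_score_bounds_canonical_and_partial(items):
    assert score_bounds(items) == (3, 32, 2, 26)
    restl = [it for it in items if it.item_id is ItemId.RESTLESSNESS]
    lo, hi, lo_ni, hi_ni = score_bounds(restl)
    assert (lo, hi, lo_ni, hi_ni) == (0, 1, 0, 1)
    no_scale = [it for it in items if it.item_id is not ItemId.PAIN_SCALE]
    assert score_bounds(no_scale)[1] == 22


@given(
    st.fixed_dictionaries(
        {it.item_id: st.sampled_from(it.categories) for it in canonical_items()}
    )
)
def test_total_is_sum_of_coded_items_and_in_range(answers):
    """Any fully answered record: total = sum of the 12 codes, within [3, 32]."""
    items = canonical_items()
    s = score_record(_record({k.value: v for k, v in answers.items()}), items)
    assert s.total_score == sum(s.item_scores.values())
    assert 3 <= s.total_score <= 32
    img = s.item_scores[ItemId.IMAGE_PREFERENCE]
    assert s.total_no_images == s.total_score - img
    assert 2 <= s.total_no_images <= 26


def test_score_frame_matches_score_record(items, cohort):
    scored = score_frame(cohort, items)
    for idx in [0, 40, 100, 295]:
        row = cohort.iloc[idx]
        rec = _record(
            {c: row[c] for c in (i.value for i in ItemId)},
            pid=row["patient_id"],
            diagnosis=Diagnosis(row["diagnosis"]),
        )
        expect = score_record(rec, items)
        assert scored.iloc[idx]["total_score"] == expect.total_score
        for iid in ItemId:
            assert scored.iloc[idx][f"score_{iid.value}"] == expect.item_scores[iid]


def test_cohort_csv_round_trip(tmp_path, cohort):
    path = tmp_path / "cohort.csv"
    write_cohort_csv(cohort, path)
    back = read_cohort_csv(path)
    assert list(back.columns) == list(cohort.columns)
    assert back["diagnosis"].tolist() == cohort["diagnosis"].tolist()
    pd.testing.assert_frame_equal(
        score_frame(back)[["total_score"]], score_frame(cohort)[["total_score"]]
    )


def test_read_cohort_csv_rejects_missing_columns(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("patient_id,diagnosis\nx,CH\n")
    with pytest.raises(ValueError, match="lacks columns"):
        read_cohort_csv(p)


def test_cohort_to_frame_preserves_missing_answers():
    ans = all_min_answers()
    ans["pain_scale"] = None
    df = cohort_to_frame([_record(ans)])
    assert pd.isna(df.loc[0, "pain_scale"])
    assert df.loc[0, "image_preference"] == "f"
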