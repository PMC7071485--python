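"""Synthetic cohort generator: canonical spec, determinism, marginal fidelity."""

import dataclasses
import io

import numpy as np
import pytest

from chscreen.instrument import Diagnosis, ItemId, score_frame
from chscreen.synth import (
    default_spec,
    expected_total_score,
    generate,
    generate_frame,
)


def test_default_spec_matches_published_cohort(spec):
    assert spec.n_ch == 81 and spec.n_migraine == 215
    assert spec.subtype_split["CH"] == {"chronic": 45, "episodic": 36}
    assert spec.subtype_split["migraine"] == {"chronic": 123, "episodic": 92}
    assert spec.sex_split["CH"] == {"male": 51, "female": 30}
    assert spec.sex_split["migraine"] == {"male": 35, "female": 180}
    assert spec.age_range == (18, 79)
    # raw printed percentage retained pre-normalisation
    assert spec.marginals.raw_percent["CH"][ItemId.IMAGE_PREFERENCE]["d"] == 61.9


def test_default_spec_probabilities_normalised(spec):
    for group in ("CH", "migraine"):
        for item in ItemId:
            p = spec.marginals.probs(group, item)
            assert sum(p.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(v >= 0 for v in p.values())


def test_invalid_split_rejected(spec):
    with pytest.raises(ValueError, match="sex split"):
        dataclasses.replace(
            spec, sex_split={**spec.sex_split, "CH": {"male": 50, "female": 30}}
        )


def test_generated_counts_exact(spec, cohort):
    assert (cohort["diagnosis"] == "CH").sum() == 81
    assert (cohort["diagnosis"] == "migraine").sum() == 215
    ch = cohort[cohort["diagnosis"] == "CH"]
    assert ch["sex"].value_counts().to_dict() == {"male": 51, "female": 30}
    assert ch["subtype"].value_counts().to_dict() == {"chronic": 45, "episodic": 36}
    assert cohort["age"].between(18, 79).all()


def test_degenerate_marginal_forces_answer(spec):
    raw = {g: dict(d) for g, d in spec.marginals.raw_percent.items()}
    raw["CH"] = dict(raw["CH"])
    raw["CH"][ItemId.RESTLESSNESS] = {"no": 0.0, "yes": 100.0}
    spec2 = dataclasses.replace(
        spec, marginals=dataclasses.replace(spec.marginals, raw_percent=raw)
    )
    df = generate_frame(spec2, seed=4)
    assert (df.loc[df["diagnosis"] == "CH", "restlessness"] == "yes").all()


@pytest.mark.parametrize("seed", [0, 7])
def test_untreated_duration_separates_groups_exactly(spec, seed):
    """The published distribution is degenerate: every CH attack lasts <= 3 h
    untreated, every migraine > 3 h."""
    df = generate_frame(spec, seed=seed)
    assert (df.loc[df["diagnosis"] == "CH", "untreated_duration"] == "le3h").all()
    assert (df.loc[df["diagnosis"] == "migraine", "untreated_duration"] == ">3h").all()


def test_large_cohort_frequencies_match_marginals(spec):
    big = generate_frame(spec.with_scale(100), seed=2)
    for group in ("CH", "migraine"):
        sub = big[big["diagnosis"] == group]
        for item in (ItemId.IMAGE_PREFERENCE, ItemId.INTENSITY, ItemId.RESTLESSNESS):
            obs = sub[item.value].value_counts(normalize=True)
            for cat, p in spec.marginals.probs(group, item).items():
                assert obs.get(cat, 0.0) == pytest.approx(p, abs=0.02)


def test_seed_reproducibility_bitwise(spec):
    bufs = []
    for _ in range(2):
        buf = io.StringIO()
        generate_frame(spec, seed=42).to_csv(buf, index=False)
        bufs.append(buf.getvalue())
    assert bufs[0] == bufs[1]
    buf = io.StringIO()
    generate_frame(spec, seed=43).to_csv(buf, index=False)
    assert buf.getvalue() != bufs[0]


def test_missingness_hook(spec):
    marg = dataclasses.replace(
        spec.marginals, missingness={"CH": {ItemId.PAIN_SCALE: 1.0}}
    )
    df = generate_frame(dataclasses.replace(spec, marginals=marg), seed=0)
    assert df.loc[df["diagnosis"] == "CH", "pain_scale"].isna().all()
    assert df.loc[df["diagnosis"] == "migraine", "pain_scale"].notna().all()


def test_joint_sampler_hook(spec):
    def degenerate(group, n, rng):
        fixed = dict.fromkeys(ItemId, None)
        fixed.update({i: "yes" for i in ItemId if "yes" in spec.marginals.probs(group, i)})
        return [dict(fixed) for _ in range(n)]

    recs = generate(spec, seed=0, joint_sampler=degenerate)
    assert all(r.answers[ItemId.RESTLESSNESS] == "yes" for r in recs)


def test_simulated_means_converge_to_expectation(spec):
    """Group mean total scores concentrate on the linearity-of-expectation
    value computed from the canonical marginals."""
    e_ch = expected_total_score(spec, "CH")
    e_mig = expected_total_score(spec, "migraine")
    means_ch, means_mig = [], []
    for seed in range(30):
        scored = score_frame(generate_frame(spec, seed=seed))
        g = scored.groupby("diagnosis")["total_score"].mean()
        means_ch.append(g["CH"])
        means_mig.append(g["migraine"])
    assert np.mean(means_ch) == pytest.approx(e_ch, abs=0.15)
    assert np.mean(means_mig) == pytest.approx(e_mig, abs=0.15)
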