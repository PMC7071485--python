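import pandas as pd
import pytest
from hypothesis import settings

from chscreen import canonical_items, default_spec, generate_frame

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def items():
    return canonical_items()


@pytest.fixture(scope="session")
def spec():
    return default_spec()


@pytest.fixture(scope="session")
def cohort(spec) -> pd.DataFrame:
    """One canonical synthetic cohort (296 patients), fixed seed."""
    return generate_frame(spec, seed=0)


def all_min_answers() -> dict:
    return {
        "image_preference": "f",
        "pain_scale": "0",
        "intensity": "mild",
        "nature_of_pain": "throbbing_other",
        "description_of_pain": "pounding_heart_other",
        "restlessness": "no",
        "excruciating_agony": "no",
        "headache_specific_times": "no",
        "strictly_unilateral": "no",
        "ipsilateral_autonomic": "no",
        "treated_duration": ">3h",
        "untreated_duration": ">3h",
    }


def all_max_answers() -> dict:
    return {
        "image_preference": "d",
        "pain_scale": "10",
        "intensity": "excruciating",
        "nature_of_pain": "stabbing_burning",
        "description_of_pain": "red_hot_poker",
        "restlessness": "yes",
        "excruciating_agony": "yes",
        "headache_specific_times": "yes",
        "strictly_unilateral": "yes",
        "ipsilateral_autonomic": "yes",
        "treated_duration": "le3h",
        "untreated_duration": "le3h",
    }
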