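import numpy as np
import pandas as pd
import pytest

import ykofit as yk


@pytest.fixture(scope="session")
def small_truth():
    return yk.generate_truth(
        120,
        collections=("YKO",),
        dropout_fracs={"YKO": 0.1},
        effect_spec={"condA": (8, [2.0]), "condB": (6, [1.5])},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_library(small_truth):
    return yk.make_random_library(small_truth.strains, seed=7)


@pytest.fixture(scope="session")
def small_design():
    return yk.make_screen_design(conditions=("condA", "condB"))


@pytest.fixture(scope="session")
def noiseless_screen(small_truth, small_design):
    params = yk.ArraySimParams(noise_sd=0.0, artifact_rate=0.0)
    return yk.generate_array_screen(small_truth, params, small_design, seed=5)


@pytest.fixture(scope="session")
def noisy_screen(small_truth, small_design):
    params = yk.ArraySimParams(noise_sd=0.3)
    return yk.generate_array_screen(small_truth, params, small_design, seed=5)


@pytest.fixture()
def tiny_manifest():
    return pd.DataFrame(
        {
            "array_id": ["a1", "a2", "a3"],
            "collection": "YKO",
            "media": "SC",
            "condition": ["control", "control", "condA"],
            "batch": "b1",
            "replicate": [1, 2, 1],
            "role": ["control", "control", "treatment"],
        }
    )
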