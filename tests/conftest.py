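import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from fairadmit.cohort import generate_cohort
from fairadmit.groups import build_collection, prevalence_filter
from fairadmit.presets import biased_cohort_config


@pytest.fixture(scope="session")
def preset_cohort():
    """Medium preset cohort with planted intersectional bias."""
    return generate_cohort(biased_cohort_config(20_000, seed=3))


@pytest.fixture(scope="session")
def intersectional(preset_cohort):
    coll = build_collection(preset_cohort, ["ethnoracial", "gender"],
                            "intersectional")
    return prevalence_filter(coll, 0.001)


@pytest.fixture
def toy_frame():
    """Tiny hand-written table: 2 attributes, 8 visits."""
    return pd.DataFrame({
        "race": pd.Categorical(["A", "A", "B", "B", "A", "B", "A", "B"]),
        "gender": pd.Categorical(["W", "M", "W", "M", "W", "W", "M", "M"]),
        "x": np.arange(8, dtype=float),
        "admitted": [1, 0, 1, 0, 1, 0, 1, 0],
    })
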