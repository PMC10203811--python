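import numpy as np
import pandas as pd
import pytest

from restmem import cohort as ch
from restmem import groupglm as gg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_geometry():
    return ch.ImageGeometry(shape=(6, 6, 6), voxel_size=3.0, tr=2.0, n_vols=120)


@pytest.fixture
def tiny_cohort():
    spec = ch.CohortSpec(n_young=12, n_old=14, seed=7)
    subjects, manifest = ch.generate_cohort(spec)
    return subjects, manifest


@pytest.fixture
def tiny_cohort_frame(tiny_cohort):
    return ch.cohort_frame(tiny_cohort[0])


def balanced_frame(n_young: int, n_old: int) -> pd.DataFrame:
    """Minimal cohort table with alternating scanners, for group designs."""
    rows = []
    for i in range(n_young):
        rows.append({"subject_id": f"y{i}", "age_group": "young",
                     "scanner": "Skyra" if i % 2 else "Verio", "age": 22.0 + i % 5})
    for i in range(n_old):
        rows.append({"subject_id": f"o{i}", "age_group": "older",
                     "scanner": "Skyra" if i % 2 else "Verio", "age": 65.0 + i % 5})
    return pd.DataFrame(rows)


@pytest.fixture
def group_contrast_young_gt_old():
    def make(names):
        return gg.contrast_vector(names, {"young_Skyra": 0.5, "young_Verio": 0.5,
                                          "older_Skyra": -0.5, "older_Verio": -0.5})
    return make
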