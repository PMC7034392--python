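import numpy as np
import pytest

from depclust import (
    ResponseMatrix,
    SurveyTable,
    default_bdi13_spec,
    generate_dataset,
)


@pytest.fixture(scope="session")
def well_sep_dataset():
    """n=2,000 cohort with nearly disjoint per-class item profiles."""
    return generate_dataset(default_bdi13_spec("well_separated",
                                               n_respondents=2000, seed=11))


@pytest.fixture(scope="session")
def paper_like_dataset():
    """n=8,000 cohort with overlapping, imbalanced severity classes."""
    return generate_dataset(default_bdi13_spec("paper_like",
                                               n_respondents=8000, seed=7))


@pytest.fixture
def tiny_table():
    """Three respondents, 13 items, with one auxiliary scale column."""
    import pandas as pd

    values = np.array([
        [0] * 13,
        [1, 1, 1] + [0] * 10,
        [3] * 13,
    ])
    return SurveyTable(
        ids=np.array([101, 102, 103]),
        responses=ResponseMatrix(values, np.full(13, 3)),
        correlates=pd.DataFrame({"sas": [30.0, 45.0, 60.0]}),
    )


def make_matrix(values, item_max=None):
    values = np.asarray(values)
    if item_max is None:
        item_max = np.full(values.shape[1], max(3, values.max()))
    return ResponseMatrix(values, np.asarray(item_max))
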