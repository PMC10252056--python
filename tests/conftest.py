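import datetime as dt

import numpy as np
import pandas as pd
import pytest

from deersurvey import CountMatrix, ModelSpec


@pytest.fixture
def toy_counts() -> CountMatrix:
    """3 sites x 2 occasions with known values."""
    return CountMatrix(
        site_ids=["A", "B", "C"],
        occasions=[dt.date(2018, 1, 1), dt.date(2018, 1, 2)],
        counts=np.array([[1, 0], [2, 1], [0, 0]], dtype=float),
    )


@pytest.fixture
def toy_covariates() -> pd.DataFrame:
    return pd.DataFrame({"site_id": ["A", "B", "C"]})


@pytest.fixture
def winter_spec() -> ModelSpec:
    """The covariate structure used as generating truth in recovery tests."""
    return ModelSpec(abundance=("aspect_ns", "elevation"), detection=("slope",))


@pytest.fixture
def photo_csv(tmp_path):
    """Write a small well-formed photo-record file and return its path."""

    def _write(rows, extra_cols=None, name="photos.csv"):
        cols = ["site_id", "timestamp", "n_males", "n_females", "n_fawns",
                "n_unknown", "male_id"]
        if extra_cols:
            cols = cols + list(extra_cols)
        df = pd.DataFrame(rows, columns=cols)
        path = tmp_path / name
        df.to_csv(path, index=False)
        return path

    return _write
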