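"""Shared fixtures: small designs and hand-built count matrices."""

import numpy as np
import pandas as pd
import pytest

from myotime.io_formats import CountMatrix
from myotime.simulate import DesignSpec


@pytest.fixture
def design():
    return DesignSpec()


@pytest.fixture
def meta36(design):
    """The full 36-sample study layout (2 lines x 6 days x 3 reps)."""
    return design.sample_table()


def make_cm(counts, meta, library_sizes=None, feature_ids=None):
    """Build a CountMatrix from an array and a metadata frame."""
    counts = np.asarray(counts)
    if feature_ids is None:
        feature_ids = [f"F{i:04d}" for i in range(counts.shape[0])]
    df = pd.DataFrame(counts, index=feature_ids, columns=meta.index)
    return CountMatrix(df, meta, library_sizes)


@pytest.fixture
def tiny_meta():
    """12 samples: 2 cell lines x 3 days x 2 replicates."""
    rows = []
    for c in ("line1", "line2"):
        for d in (0, 1, 2):
            for r in (1, 2):
                rows.append(
                    {"sample_id": f"{c}_d{d}_r{r}", "cell_line": c, "day": d,
                     "replicate": r}
                )
    return pd.DataFrame(rows).set_index("sample_id")


@pytest.fixture
def tiny_cm(tiny_meta):
    rng = np.random.default_rng(7)
    counts = rng.poisson(100, size=(20, len(tiny_meta)))
    return make_cm(counts, tiny_meta)
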