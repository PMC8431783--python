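import numpy as np
import pandas as pd
import pytest

from sfimpute import IntensityMatrix, SampleGroups


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, scale="log2", proteins=None, samples=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    proteins = proteins or [f"P{i:03d}" for i in range(n)]
    samples = samples or [f"s{j}" for j in range(p)]
    return IntensityMatrix(
        pd.DataFrame(values, index=proteins, columns=samples), scale=scale
    )


@pytest.fixture
def two_group_6():
    """Sample names and grouping for a standard 3 vs 3 design."""
    samples = ["t1", "t2", "t3", "c1", "c2", "c3"]
    groups = SampleGroups({s: ("T" if s.startswith("t") else "C") for s in samples}, ("T", "C"))
    return samples, groups


@pytest.fixture
def random_log2(rng, two_group_6):
    """60 x 6 complete log2 matrix with a handful of planted shifts."""
    samples, groups = two_group_6
    vals = rng.normal(20, 2, (60, 6))
    vals[:10, :3] += 3.0
    m = make_matrix(vals, samples=samples)
    return m, groups


@pytest.fixture
def masked_log2(rng, random_log2):
    """As random_log2 but with ~12% cells masked at random (no empty rows)."""
    m, groups = random_log2
    vals = m.values.to_numpy().copy()
    mask = rng.random(vals.shape) < 0.12
    for i in range(vals.shape[0]):  # keep at least two observed per row
        while mask[i].sum() > vals.shape[1] - 2:
            mask[i, rng.integers(vals.shape[1])] = False
    vals[mask] = np.nan
    return make_matrix(vals, samples=m.sample_ids), groups
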