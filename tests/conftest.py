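import numpy as np
import pandas as pd
import pytest

from ithkit.simulate import SimConfig, SimTruth, simulate_patient


def make_somatic_records(
    n: int, rng: np.random.Generator, with_normal: bool = True
) -> pd.DataFrame:
    """Random tumor-role variant records straddling all filter boundaries."""
    depth = rng.integers(0, 120, n)
    alt = np.minimum(rng.integers(0, 60, n), depth)
    df = pd.DataFrame(
        {
            "depth": depth,
            "alt_count": alt,
            "af": np.where(depth > 0, alt / np.maximum(depth, 1), 0.0),
            "in_1000g": rng.random(n) < 0.15,
            "in_esp": rng.random(n) < 0.15,
        },
        index=[f"r{i}" for i in range(n)],
    )
    if with_normal:
        df["matched_normal_af"] = rng.choice([0.0, 0.005, 0.01, 0.02, 0.2], n)
    return df


def make_germline_records(n: int, rng: np.random.Generator) -> pd.DataFrame:
    depth = rng.integers(0, 200, n)
    alt = np.minimum(rng.integers(0, 160, n), depth)
    return pd.DataFrame(
        {
            "depth": depth,
            "alt_count": alt,
            "af": np.where(depth > 0, alt / np.maximum(depth, 1), 0.0),
            "gq": rng.choice([np.nan, 10, 29, 30, 31, 99], n),
            "vqsr": rng.choice([90.0, 96.99, 97.0, 97.01, 99.9], n),
            "is_multiallelic": rng.random(n) < 0.1,
            "in_segdup": rng.random(n) < 0.1,
        },
        index=[f"g{i}" for i in range(n)],
    )


def p6_like_truth() -> SimTruth:
    """Truncal clone, high shared subclone, one sample-private subclone."""
    ccfs = pd.DataFrame(
        [[1.0, 1.0], [0.75, 0.72], [0.6, 0.0]], index=[0, 1, 2], columns=["T1", "T2"]
    )
    truth = SimTruth(clone_tree={1: 0, 2: 1}, ccf_matrix=ccfs)
    truth.validate()
    return truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_patient(SimConfig(seed=11, n_clusters=3, mutations_per_cluster=20))
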