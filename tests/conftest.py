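"""Shared fixtures and the independent box-count oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


def oracle_box_count(grid: np.ndarray, r: int) -> int:
    """Independent box-count oracle: map every foreground voxel to its box
    index relative to the bounding-box corner and count distinct boxes."""
    coords = np.argwhere(np.asarray(grid) != 0)
    assert coords.size, "oracle needs a nonempty mask"
    boxes = (coords - coords.min(axis=0)) // r
    return len({tuple(b) for b in boxes})


def make_noiseless_table(n: int = 40, seed: int = 0) -> pd.DataFrame:
    """Deterministic covariates with exactly linear FD responses.

    fd_a = 2.4 - 3e-4*age + 4e-3*sex + 2e-8*tbv (no noise); fd_b adds a
    known quadratic age term and fd_c a known age x sex interaction.
    """
    rng = np.random.default_rng(seed)
    age = np.linspace(45, 79, n)
    sex = (np.arange(n) % 2).astype(int)
    tbv = 1.1e6 + 1e5 * rng.standard_normal(n)
    df = pd.DataFrame({"id": [f"s{i}" for i in range(n)], "age": age, "sex": sex, "tbv": tbv})
    df["fd_a"] = 2.4 - 3e-4 * age + 4e-3 * sex + 2e-8 * tbv
    df["fd_b"] = df["fd_a"] + 1e-5 * age**2
    df["fd_c"] = df["fd_a"] - 5e-5 * age * sex
    return df


@pytest.fixture(scope="session")
def noiseless_table() -> pd.DataFrame:
    return make_noiseless_table()


@pytest.fixture(scope="session")
def cohort_2000():
    """One n=2000 cohort from the default generative model (fixed seed)."""
    from ribbonfd import CohortConfig, generate_cohort_table

    table, truth = generate_cohort_table(CohortConfig(n_subjects=2000, outlier_rate=0.0, seed=42))
    return table, truth
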