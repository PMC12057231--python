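"""Shared fixtures: a default synthetic cohort and its network model.

Session-scoped because network construction is the expensive step and many
tests only read from the result.
"""

import numpy as np
import pandas as pd
import pytest

import proteostage as ps


@pytest.fixture(scope="session")
def cohort():
    """Default discovery cohort (seed 1): raw matrix, metadata, truth."""
    return ps.generate_cohort(seed=1)


@pytest.fixture(scope="session")
def normalized(cohort):
    matrix, meta, truth = cohort
    norm = ps.normalize_tmt(matrix).drop_reference_channels()
    return ps.filter_missingness(norm)


@pytest.fixture(scope="session")
def network_model(normalized):
    return ps.build_network(normalized)


@pytest.fixture(scope="session")
def staged(cohort):
    _, meta, _ = cohort
    assign, pooling = ps.pool_sparse_stages(ps.assign_groups(meta, stage_basis="pet"))
    return assign, pooling


def make_matrix(values, sample_prefix="S", protein_prefix="P", **kwargs):
    """Small AbundanceMatrix from a plain array (proteins x samples)."""
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values,
        index=[f"{protein_prefix}{i}" for i in range(values.shape[0])],
        columns=[f"{sample_prefix}{j}" for j in range(values.shape[1])],
    )
    return ps.AbundanceMatrix(values=df, **kwargs)
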