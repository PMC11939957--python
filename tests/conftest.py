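import numpy as np
import pytest

from braindyn.cohort import (
    default_cohort_spec,
    generate_cohort,
    generate_connectome,
    generate_region_table,
)


@pytest.fixture(scope="session")
def region_table_20():
    return generate_region_table(20, seed=1)


@pytest.fixture(scope="session")
def connectome_20(region_table_20):
    return generate_connectome(region_table_20, density=0.6, seed=2)


@pytest.fixture(scope="session")
def small_cohort():
    """8 subjects, 20 regions, 150 volumes from the group-A ground truth."""
    spec, region_table, sc = default_cohort_spec(
        n_group_a=8, n_group_b=0, n_regions=20, n_volumes=150, seed=3
    )
    cohort, meta, gt = generate_cohort(spec)
    return {
        "spec": spec,
        "region_table": region_table,
        "sc": sc,
        "cohort": cohort,
        "meta": meta,
        "ground_truth": gt,
    }


@pytest.fixture(scope="session")
def two_group_cohort():
    """Small two-group cohort for pipeline-level tests."""
    spec, region_table, sc = default_cohort_spec(
        n_group_a=10, n_group_b=10, n_regions=20, n_volumes=120, seed=7
    )
    cohort, meta, gt = generate_cohort(spec)
    return {
        "spec": spec,
        "region_table": region_table,
        "sc": sc,
        "cohort": cohort,
        "meta": meta,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
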