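"""Shared fixtures: small synthetic cohorts and generated CSV inputs."""

import numpy as np
import pytest

import labri


@pytest.fixture(scope="session")
def small_spec():
    """Compact default-recipe cohort: 3 ages, both genders, 600 results/segment."""
    return labri.default_spec(n_per_segment=600, ages=[30, 60, 90])


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    table, truth = labri.generate_cohort(small_spec, seed=11)
    return table, truth


@pytest.fixture()
def cohort_csv(tmp_path, small_cohort):
    table, _ = small_cohort
    path = tmp_path / "cohort.csv"
    labri.write_results(table, path)
    return path


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
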