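"""Shared fixtures: one default synthetic study, preprocessed and profiled.

Session-scoped because generation and QMP rarefaction are reused by many
test modules; tests must not mutate these objects.
"""

import warnings

import pytest

import beeqmp as bq
from beeqmp.pipeline import preprocess_stage


@pytest.fixture(scope="session")
def study():
    return bq.generate_study(seed=1)


@pytest.fixture(scope="session")
def pre(study):
    return preprocess_stage(
        study.counts, study.samples, study.taxonomy, study.copy_numbers
    )


@pytest.fixture(scope="session")
def bees(pre):
    return pre["bee_samples"]


@pytest.fixture(scope="session")
def loads(study):
    return bq.load_from_ct(study.ct)


@pytest.fixture(scope="session")
def profile(pre, loads):
    return bq.qmp_rarefy(pre["corrected"], loads, n_reps=100, seed=2)


@pytest.fixture(scope="session")
def genus_abund(profile, study):
    return bq.pool_by_genus(profile, study.taxonomy)


@pytest.fixture(scope="session")
def micro():
    return bq.generate_worked_micro(seed=3)


@pytest.fixture(autouse=True)
def _quiet_interaction_warning():
    """The study design has an empty condition x location cell by design."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*interaction df reduced.*", category=UserWarning
        )
        yield
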