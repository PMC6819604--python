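from pathlib import Path

import pandas as pd
import pytest

from spdm import feature_table as ft
from spdm.simulate import worked_fixture

FIXTURE_DIR = Path(__file__).parent / "data" / "worked_fixture"


@pytest.fixture(scope="session")
def fixture_dir():
    return FIXTURE_DIR


@pytest.fixture(scope="session")
def fixture_cohort():
    return worked_fixture()


@pytest.fixture(scope="session")
def fixture_profiles(fixture_cohort):
    """Normalized group profiles of the worked fixture (groups 1..5)."""
    rel = ft.to_relative_abundance(fixture_cohort.counts)
    meta = ft.assign_age_groups(fixture_cohort.metadata)
    return ft.normalize_features(ft.group_means(rel, meta))
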