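"""Shared fixtures: the deterministic mini-landscape used across the suite."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from cherry_rga.synthetic import SyntheticDataset, fixture_small

settings.register_profile(
    "suite", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset() -> SyntheticDataset:
    return fixture_small()


@pytest.fixture(scope="session")
def small_files(small_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture_small")
    return small_dataset.write(outdir)
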