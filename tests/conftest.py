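from pathlib import Path

import pytest

from varprio import SimulationParams, generate_cohort, write_fixture_bundle

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_generated():
    """A 1,000-variant cohort with planted truth (fixed seed)."""
    return generate_cohort(SimulationParams(n_variants_total=1_000, seed=11))


@pytest.fixture(scope="session")
def small_bundle(small_generated, tmp_path_factory):
    """The same cohort written as an on-disk fixture bundle."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = write_fixture_bundle(small_generated, outdir)
    return small_generated, paths
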