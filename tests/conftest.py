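import pathlib

import pytest

from glycotarget.fixtures import FixtureConfig, toy_fasta_path


@pytest.fixture(scope="session")
def toy_fasta() -> pathlib.Path:
    return toy_fasta_path()


@pytest.fixture()
def fixture_dir(tmp_path) -> pathlib.Path:
    return tmp_path


@pytest.fixture(scope="session")
def base_config() -> FixtureConfig:
    return FixtureConfig(seed=7)
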