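import pytest

from dunnartdelim import synthetic_data as sd
from dunnartdelim.seqio import read_fasta_alignment, read_group_map


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """The canonical synthetic study, written once per session."""
    out = tmp_path_factory.mktemp("fixture_set")
    return sd.write_fixture_set(out, seed=1)


@pytest.fixture(scope="session")
def fixture_alignment(fixture_paths):
    return read_fasta_alignment(fixture_paths["cytb_like"])


@pytest.fixture(scope="session")
def fixture_groups(fixture_paths):
    return read_group_map(fixture_paths["groups"])
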