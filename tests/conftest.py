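import pytest
from hypothesis import HealthCheck, settings

from u34scan.protfeat import default_scheme

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture
def write_fasta_file(tmp_path):
    """Write raw FASTA text to a temp file and return its path."""

    def _write(text, name="test.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
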