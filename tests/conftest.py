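import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    """The stable default synthetic marker panel."""
    from aspmat.synthetic_data import default_marker_panel

    return default_marker_panel()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def write_fasta_file(tmp_path):
    """Write raw FASTA text to a temp file and return its path."""

    def _write(text: str, name: str = "test.fasta"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write
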