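import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing records to a temporary FASTA file."""

    def _write(records, name="input.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rec_name, seq in records:
                fh.write(f">{rec_name}\n{seq}\n")
        return path

    return _write
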