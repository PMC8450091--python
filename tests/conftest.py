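import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from g4flank.simulate import BasisModel
from g4flank.spectra import CDSpectrum

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def basis() -> BasisModel:
    return BasisModel()


@pytest.fixture
def make_spectrum():
    """Build a CDSpectrum straight from (wavelengths, values)."""

    def _make(wavelengths, values, **metadata):
        return CDSpectrum(np.asarray(wavelengths, float), np.asarray(values, float), metadata)

    return _make


@pytest.fixture
def spectrum_file(tmp_path):
    """Write rows to a spectrum CSV and return the path."""

    def _write(rows, name="spec.csv", delim=",", header=None):
        path = tmp_path / name
        lines = [] if header is None else [header]
        lines += [delim.join(str(x) for x in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
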