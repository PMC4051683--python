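import numpy as np
import pytest

from memdiff.synthetic import default_gel_model, write_fixtures


@pytest.fixture(scope="session")
def gel_model():
    return default_gel_model()


@pytest.fixture(scope="session")
def fixture_pack(tmp_path_factory):
    """Session-wide synthetic fixture pack (seeded, reproducible)."""
    outdir = tmp_path_factory.mktemp("fixtures")
    manifest = write_fixtures(outdir, seed=1234)
    return outdir, manifest


def model_f0(model) -> float:
    """Zeroth Fourier coefficient ∫(ρ−ρ_w)dz of a mirrored-Gaussian model."""
    return float(sum((2.0 if z > 0 else 1.0) * a * s * np.sqrt(2 * np.pi)
                     for z, s, a in model.components))
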