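import numpy as np
import pytest

from cortiq.btensor import BTensorScheme, ProtocolConfig, build_protocol_scheme


@pytest.fixture(scope="session")
def protocol_scheme() -> BTensorScheme:
    """The default four-shell, three-shape acquisition scheme."""
    return build_protocol_scheme()


@pytest.fixture(scope="session")
def small_scheme() -> BTensorScheme:
    """A lighter two-shell scheme (61 measurements) for fit-heavy tests."""
    return build_protocol_scheme(ProtocolConfig(shells=(700.0, 2000.0)))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
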