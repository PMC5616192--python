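import numpy as np
import pytest

from tbikit.scheme import make_scheme


@pytest.fixture(scope="session")
def scheme():
    """Default four-shell protocol: 6+6 low-b and 32+32 high-b directions
    plus one b=0 volume (77 volumes)."""
    return make_scheme(6, 32)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_tensors(rng, n, lo=0.1e-3, hi=1.2e-3):
    """Random SPD tensors with eigenvalues in [lo, hi] and Haar-random axes."""
    Q = np.linalg.qr(rng.normal(size=(n, 3, 3)))[0]
    ev = np.sort(rng.uniform(lo, hi, (n, 3)))[:, ::-1]
    return np.einsum("nij,nj,nkj->nik", Q, ev, Q), ev
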