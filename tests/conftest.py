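import numpy as np
import pytest

from hdcseg.phantom import PhantomSpec, make_case


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_case():
    """One deterministic 48^3 phantom (volume, labels)."""
    spec = PhantomSpec(shape=(48, 48, 48), n_cases=1, seed=11)
    return make_case(spec, np.random.default_rng(11))


def gradcheck(loss_fn, params, rng, n_coords: int = 3, eps: float = 1e-5,
              rtol: float = 1e-4) -> None:
    """Compare analytic gradients to central finite differences.

    ``loss_fn`` recomputes the scalar loss from current parameter values;
    ``params`` is a list of float64 Parameters whose .grad was already
    filled by one backward pass.
    """
    for p in params:
        assert p.grad is not None, "no gradient reached this parameter"
        flat = p.data.reshape(-1)
        gflat = p.grad.reshape(-1)
        for idx in rng.choice(flat.size, size=min(n_coords, flat.size), replace=False):
            old = flat[idx]
            flat[idx] = old + eps
            lp = loss_fn()
            flat[idx] = old - eps
            lm = loss_fn()
            flat[idx] = old
            fd = (lp - lm) / (2 * eps)
            g = gflat[idx]
            assert abs(fd - g) <= rtol * max(1.0, abs(fd) + abs(g)), \
                f"analytic {g} vs finite-difference {fd}"
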