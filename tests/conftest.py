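import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pimotif.core import PIMParams

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


def random_pim(L: int, pairs, rng, h_scale: float = 1.0,
               j_scale: float = 1.0) -> PIMParams:
    """A random pairwise model with the given active pairs."""
    h = rng.normal(0.0, h_scale, size=(L, 4))
    couplings = {tuple(sorted(p)): rng.normal(0.0, j_scale, size=(4, 4))
                 for p in pairs}
    return PIMParams(h, couplings)


def brute_force_probs(params: PIMParams) -> np.ndarray:
    """Model probabilities over all 4^L states by direct, unfactorized
    summation (independent oracle for the component-based code paths)."""
    L = params.L
    probs = np.empty(4 ** L)
    for idx in range(4 ** L):
        s = [(idx >> (2 * (L - 1 - k))) & 3 for k in range(L)]
        e = sum(params.h[k, s[k]] for k in range(L))
        e += sum(block[s[i], s[j]] for (i, j), block in params.couplings.items())
        probs[idx] = np.exp(-e)
    return probs / probs.sum()


def all_states(L: int) -> np.ndarray:
    """All 4^L encoded sequences, in index order."""
    idx = np.arange(4 ** L)
    return np.stack(
        [(idx >> (2 * (L - 1 - k))) & 3 for k in range(L)], axis=1
    ).astype(np.int8)


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
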