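import numpy as np
import pytest

from modmindy import (
    ModelParameters,
    ModulationMatrix,
    StructuredConnectivity,
    SynthConfig,
    generate_dataset,
)


def make_toy_params(m: int = 1, s_exc: float = 1.0, s_inh: float = 1.0,
                    d: float = 0.5) -> ModelParameters:
    """Minimal 2-population (1 E, 1 I) model with hand-chosen weights."""
    W = StructuredConnectivity(
        n_exc=1, n_inh=1,
        Wee=np.array([[0.3]]), Wie=np.array([[-0.4]]),
        Wei=np.array([[0.6]]), Wii=np.array([[-0.2]]),
        mask_ee=np.ones((1, 1), dtype=bool), mask_ei=np.ones((1, 1), dtype=bool),
    )
    gammas = [ModulationMatrix(i, np.array([1.0, 0.8]), np.array([1.1, 0.9]))
              for i in range(1, m + 1)]
    H = np.array([[1.0, 0.0]])
    return ModelParameters(
        W=W, gammas=gammas, D=np.full(2, d), s_exc=s_exc, s_inh=s_inh,
        V=np.zeros(2), C=np.zeros(2), H=H,
        Q=np.zeros((2, 2)), R=np.zeros((1, 1)),
    )


@pytest.fixture
def toy_params():
    return make_toy_params()


@pytest.fixture(scope="session")
def small_bundle():
    """Small but nontrivial ground truth with two regimes (the chain is
    made leakier than the default so both regimes occur in a short run)."""
    cfg = SynthConfig(n_exc=4, n_inh=4, m=2, T=400, hmm_leak=0.1)
    return generate_dataset(cfg, seed=11)


def oracle_step(x, params, regime, eps=None):
    """Independent elementwise evaluation of the modulated update, written
    entry by entry (no reuse of the package's vectorized path)."""
    n = params.n
    W = params.W.assemble()
    G = params.gammas[regime - 1].dense()
    s = params.slope_vector
    out = np.zeros(n)
    for i in range(n):
        acc = x[i]
        for j in range(n):
            acc += W[i, j] * G[i, j] * np.tanh(s[j] * x[j] + params.V[j])
        acc -= params.D[i] * x[i]
        acc += params.C[i]
        if eps is not None:
            acc += eps[i]
        out[i] = acc
    return out
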