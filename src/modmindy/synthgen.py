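"""Ground-truth model and synthetic recording generation.

Emulates regime-labeled mesoscale recordings (by default 250 Hz, paired
E/I populations, one channel per excitatory population) from randomly
drawn modulated network models, for parameter-recovery validation.

Connectivity construction
-------------------------
The excitatory-source blocks are built as sparse + low-rank + diagonal,

    Wee = Ws + Wl1 Wl2^T + diag(w_d),

with ``Ws`` drawn as elementwise-cubed uniforms scaled by 16/20 (cubing
skews the bulk of weights toward small values with a heavy right tail),
the low-rank factors (n x n/4) as cubed uniforms plus 0.2 x uniform, and
the self-connection vector from the same family as the low-rank entries.
The same recipe builds Wei.  After assembly a fixed random mask zeroes
75% of the off-diagonal entries of each block.  Inhibitory-source blocks
Wie/Wii are diagonal with negative entries whose magnitudes are drawn
from the low-rank entry family.

Modulations
-----------
Each regime's Gamma_i is a symmetric self outer product Gamma_ik Gamma_ik^T.
The vector's distribution is itself randomized: mean mu_i ~ N(1, 0.1); a
fair coin picks uniform vs normal; the spread sigma_i ~ N(0.4, 0.1)
(uniform branch) or N(0.05, 0.01) (normal branch); then
Gamma_ik ~ U(mu_i - sigma_i/2, mu_i + sigma_i/2) or N(mu_i, sigma_i).
Negative draws are clipped to 0.  This keeps modulation values near 1 so
the modulation rescales, rather than overwhelms, the base connectivity.

Regime switching is a hidden Markov chain with near-diagonal transition
matrix A = 0.999 I + (0.001/m)(11^T - I); its rows do not sum to exactly 1
as written, so they are renormalized (with a warning) before sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .model import (
    LabeledRecording,
    ModelParameters,
    ModulationMatrix,
    StructuredConnectivity,
    random_offdiag_mask,
    simulate,
)

__all__ = [
    "HMMSpec",
    "GroundTruthBundle",
    "SynthConfig",
    "default_transition_matrix",
    "generate_connectivity",
    "generate_modulations",
    "generate_regimes",
    "generate_dataset",
]


@dataclass
class HMMSpec:
    """Transition matrix and initial distribution of the regime chain."""

    A: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float).ravel()
        m = self.pi.size
        if self.A.shape != (m, m):
            raise ValueError("A must be square with side len(pi)")
        if np.any(self.A < 0) or np.any(self.pi < 0):
            raise ValueError("probabilities must be nonnegative")
        rows = self.A.sum(axis=1)
        if np.any(rows <= 0) or self.pi.sum() <= 0:
            raise ValueError("each row of A and pi must have positive mass")
        if not np.allclose(rows, 1.0, atol=1e-3):
            raise ValueError("rows of A must sum to ~1 (renormalize first)")
        self.A = self.A / rows[:, None]
        self.pi = self.pi / self.pi.sum()

    @property
    def m(self) -> int:
        return self.pi.size

    def stationary(self) -> np.ndarray:
        """Stationary distribution from the leading left eigenvector of A."""
        w, vl = np.linalg.eig(self.A.T)
        k = int(np.argmin(np.abs(w - 1.0)))
        p = np.real(vl[:, k])
        return p / p.sum()


def default_transition_matrix(m: int, stick: float = 0.999,
                              leak: float = 0.001) -> np.ndarray:
    """Near-diagonal transition matrix ``stick*I + (leak/m)(11^T - I)``,
    row-renormalized to be stochastic (the raw rows sum to
    ``stick + leak*(m-1)/m``)."""
    A = stick * np.eye(m) + (leak / m) * (np.ones((m, m)) - np.eye(m))
    rows = A.sum(axis=1)
    if not np.allclose(rows, 1.0):
        warnings.warn(
            "transition matrix rows sum to %.6f; renormalizing" % rows[0],
            stacklevel=2,
        )
        A = A / rows[:, None]
    return A


@dataclass
class SynthConfig:
    """Study conditions for synthetic-data generation.

    Defaults describe the standard validation conditions: 20 paired E/I
    populations, 3 regimes, 20,000 steps at 250 Hz (80 s), cubed-uniform
    sparse weights scaled by 16/20, process noise 0.25 I and a scalar
    uniform measurement variance on (0.2, 0.3).
    """

    n_exc: int = 20
    n_inh: int = 20
    m: int = 3
    T: int = 20_000
    fs: float = 250.0
    sparse_scale: float = 16.0 / 20.0
    lowrank_uniform_coeff: float = 0.2
    s_exc: float = 2.5
    s_inh: float = 1.0
    d_exc_base: float = 0.65
    d_exc_jitter: float = 0.02
    d_inh_base: float = 0.8
    d_inh_jitter: float = 0.02
    process_noise_var: float = 0.25
    meas_noise_base: float = 0.2
    meas_noise_jitter: float = 0.1
    mu_mean: float = 1.0
    mu_sd: float = 0.1
    sigma_uniform_mean: float = 0.4
    sigma_uniform_sd: float = 0.1
    sigma_normal_mean: float = 0.05
    sigma_normal_sd: float = 0.01
    hmm_stick: float = 0.999
    hmm_leak: float = 0.001
    n_channels: int | None = None  # default: one channel per E population
    pin_gamma1: bool = False

    def __post_init__(self) -> None:
        if self.m < 1 or self.T < 1:
            raise ValueError("m and T must be >= 1")
        if self.n_inh < 1 or self.n_exc < 4:
            raise ValueError("need n_exc >= 4 and n_inh >= 1")

    @property
    def channels(self) -> int:
        return self.n_exc if self.n_channels is None else self.n_channels


@dataclass
class GroundTruthBundle:
    """A synthetic model plus everything it generated, for recovery tests."""

    params: ModelParameters
    labels: np.ndarray
    states: np.ndarray
    recording: LabeledRecording
    generator_seed: int | None
    config: SynthConfig = field(default_factory=SynthConfig)


def _cubed_uniform(rng: np.random.Generator, shape) -> np.ndarray:
    return rng.uniform(0.0, 1.0, size=shape) ** 3


def _lowrank_entry_family(rng: np.random.Generator, shape,
                          coeff: float) -> np.ndarray:
    """U(0,1)^3 + coeff * U(0,1), elementwise."""
    return _cubed_uniform(rng, shape) + coeff * rng.uniform(0.0, 1.0, size=shape)


def _exc_block(rng: np.random.Generator, n: int, cfg: SynthConfig) -> np.ndarray:
    """Unmasked sparse + low-rank + diagonal excitatory-source block."""
    Ws = cfg.sparse_scale * _cubed_uniform(rng, (n, n))
    k = max(1, n // 4)  # low-rank factors are n x n/4, floored for small n
    Wl1 = _lowrank_entry_family(rng, (n, k), cfg.lowrank_uniform_coeff)
    Wl2 = _lowrank_entry_family(rng, (n, k), cfg.lowrank_uniform_coeff)
    w_diag = _lowrank_entry_family(rng, n, cfg.lowrank_uniform_coeff)
    return Ws + Wl1 @ Wl2.T + np.diag(w_diag)


def generate_connectivity(n_exc: int, n_inh: int,
                          seed: int | np.random.Generator | None = None,
                          config: SynthConfig | None = None
                          ) -> StructuredConnectivity:
    """Draw a random structured connectivity with the 75% sparsity mask
    applied to the off-diagonals of Wee and Wei."""
    if n_exc != n_inh:
        raise ValueError("generator assumes paired populations (n_exc == n_inh)")
    cfg = config or SynthConfig(n_exc=n_exc, n_inh=n_inh)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Wee = _exc_block(rng, n_exc, cfg)
    Wei = _exc_block(rng, n_exc, cfg)
    mask_ee = random_offdiag_mask(n_exc, n_exc, rng)
    mask_ei = random_offdiag_mask(n_inh, n_exc, rng)
    Wee[~mask_ee] = 0.0
    Wei[~mask_ei] = 0.0
    wie = -_lowrank_entry_family(rng, n_exc, cfg.lowrank_uniform_coeff)
    wii = -_lowrank_entry_family(rng, n_inh, cfg.lowrank_uniform_coeff)
    return StructuredConnectivity(
        n_exc, n_inh, Wee, np.diag(wie), Wei, np.diag(wii), mask_ee, mask_ei
    )


def generate_modulations(m: int, n: int,
                         seed: int | np.random.Generator | None = None,
                         config: SynthConfig | None = None,
                         pin_first: bool = False) -> list:
    """Draw m rank-1 symmetric modulations with entries concentrated near 1.

    With ``pin_first`` the first regime's modulation is the exact all-ones
    matrix (baseline regime)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    cfg = config or SynthConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for i in range(1, m + 1):
        if pin_first and i == 1:
            out.append(ModulationMatrix.ones(1, n, pinned=True))
            continue
        mu = rng.normal(cfg.mu_mean, cfg.mu_sd)
        use_uniform = rng.integers(0, 2) == 1
        if use_uniform:
            # |sigma|: a (rare) negative draw of the spread is meaningless
            sigma = abs(rng.normal(cfg.sigma_uniform_mean, cfg.sigma_uniform_sd))
            vec = rng.uniform(mu - sigma / 2.0, mu + sigma / 2.0, size=n)
        else:
            sigma = rng.normal(cfg.sigma_normal_mean, cfg.sigma_normal_sd)
            vec = rng.normal(mu, abs(sigma), size=n)
        vec = np.clip(vec, 0.0, None)
        out.append(ModulationMatrix(i, vec, vec.copy()))
    return out


def generate_regimes(hmm: HMMSpec, T: int,
                     seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Sample a length-T label sequence (values 1..m) from the chain."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.empty(T, dtype=int)
    state = int(rng.choice(hmm.m, p=hmm.pi))
    labels[0] = state + 1
    for t in range(1, T):
        state = int(rng.choice(hmm.m, p=hmm.A[state]))
        labels[t] = state + 1
    return labels


def generate_dataset(config: SynthConfig | None = None,
                     seed: int | None = None) -> GroundTruthBundle:
    """Draw a full ground-truth model, a regime sequence, and a simulated
    labeled recording.

    The lead field's excitatory block has i.i.d. standard normal entries;
    inhibitory columns are zero.  Process noise covariance is 0.25 I; the
    measurement noise variance is a single scalar drawn uniformly from
    (0.2, 0.3) and shared across channels.
    """
    cfg = config or SynthConfig()
    rng = np.random.default_rng(seed)
    n = cfg.n_exc + cfg.n_inh

    W = generate_connectivity(cfg.n_exc, cfg.n_inh, rng, cfg)
    gammas = generate_modulations(cfg.m, n, rng, cfg, pin_first=cfg.pin_gamma1)
    D = np.concatenate([
        cfg.d_exc_base + cfg.d_exc_jitter * rng.uniform(size=cfg.n_exc),
        cfg.d_inh_base + cfg.d_inh_jitter * rng.uniform(size=cfg.n_inh),
    ])
    Hexc = rng.standard_normal((cfg.channels, cfg.n_exc))
    H = np.hstack([Hexc, np.zeros((cfg.channels, cfg.n_inh))])
    Q = cfg.process_noise_var * np.eye(n)
    r_var = cfg.meas_noise_base + cfg.meas_noise_jitter * rng.uniform()
    R = r_var * np.eye(cfg.channels)
    params = ModelParameters(
        W=W, gammas=gammas, D=D, s_exc=cfg.s_exc, s_inh=cfg.s_inh,
        V=np.zeros(n), C=np.zeros(n), H=H, Q=Q, R=R,
    )
    params.validate()

    A = default_transition_matrix(cfg.m, cfg.hmm_stick, cfg.hmm_leak)
    hmm = HMMSpec(A, np.full(cfg.m, 1.0 / cfg.m))
    labels = generate_regimes(hmm, cfg.T, rng)
    states, y = simulate(params, labels, x0=np.zeros(n), seed=rng)
    rec = LabeledRecording(y=y, fs=cfg.fs, labels=labels)
    return GroundTruthBundle(
        params=params, labels=labels, states=states, recording=rec,
        generator_seed=seed, config=cfg,
    )
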