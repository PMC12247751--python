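"""Domain types and forward dynamics for modulated E/I network models.

The model describes ``n = n_exc + n_inh`` neural populations whose activity
``x`` evolves in discrete time as

    x[t+1] - x[t] = (W o Gamma_i) tanh(S x + V) - D x + C + eps,
    y[t] = H x[t] + nu,

where ``W`` is a signed, block-structured connectivity matrix, ``Gamma_i``
is a nonnegative rank-1 modulation matrix selected by the regime label
``i`` active at time ``t``, ``o`` is the Hadamard (element-wise) product,
``D`` is a positive per-population decay (leak) rate, ``S``/``V`` are the
slope and offset of the sigmoidal activation, ``C`` is a per-population
bias, and ``H`` is the lead field mapping latent populations to recorded
channels.  Process noise ``eps`` and measurement noise ``nu`` are Gaussian
with covariances ``Q`` and ``R``.

Sign convention of the decay: ``D`` is stored as a positive rate (e.g.
0.65) and enters the update with a minus sign, so the linear part of the
one-step map is ``1 - D`` per population.  With the decay rates used
throughout (0.6-0.85) this keeps the linearized dynamics contractive; the
opposite convention (``+ D x``) makes the linear part ``1 + D`` and blows
up in a handful of steps, so it cannot be the intended reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DECAY_SIGN",
    "StructuredConnectivity",
    "ModulationMatrix",
    "ModelParameters",
    "LabeledRecording",
    "step",
    "observe",
    "simulate",
]

#: Decay enters the state update as ``DECAY_SIGN * D x`` with D stored positive.
DECAY_SIGN = -1.0

OFFDIAG_SPARSITY = 0.75  # fraction of off-diagonal Wee/Wei entries forced to 0


def _as_float_array(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class StructuredConnectivity:
    """Signed block-structured connectivity with a fixed sparsity mask.

    Blocks (rows = targets, columns = sources)::

        W = [[Wee, Wie],
             [Wei, Wii]]

    ``Wee`` (E->E) and ``Wei`` (E->I) are nonnegative and dense up to a
    fixed binary mask that zeroes 75% of their off-diagonal entries.
    ``Wie`` (I->E) and ``Wii`` (I->I) are nonpositive and diagonal,
    reflecting the local-only reach of inhibitory populations.

    Masks store 1 where an entry is free and 0 where it is clamped to zero;
    diagonals are always free.
    """

    n_exc: int
    n_inh: int
    Wee: np.ndarray
    Wie: np.ndarray
    Wei: np.ndarray
    Wii: np.ndarray
    mask_ee: np.ndarray
    mask_ei: np.ndarray

    def __post_init__(self) -> None:
        self.Wee = np.asarray(self.Wee, dtype=float)
        self.Wie = np.asarray(self.Wie, dtype=float)
        self.Wei = np.asarray(self.Wei, dtype=float)
        self.Wii = np.asarray(self.Wii, dtype=float)
        self.mask_ee = np.asarray(self.mask_ee, dtype=bool)
        self.mask_ei = np.asarray(self.mask_ei, dtype=bool)
        ne, ni = self.n_exc, self.n_inh
        if self.Wee.shape != (ne, ne):
            raise ValueError(f"Wee must be {(ne, ne)}, got {self.Wee.shape}")
        if self.Wie.shape != (ne, ni):
            raise ValueError(f"Wie must be {(ne, ni)}, got {self.Wie.shape}")
        if self.Wei.shape != (ni, ne):
            raise ValueError(f"Wei must be {(ni, ne)}, got {self.Wei.shape}")
        if self.Wii.shape != (ni, ni):
            raise ValueError(f"Wii must be {(ni, ni)}, got {self.Wii.shape}")
        if self.mask_ee.shape != self.Wee.shape:
            raise ValueError("mask_ee shape mismatch")
        if self.mask_ei.shape != self.Wei.shape:
            raise ValueError("mask_ei shape mismatch")

    @property
    def n(self) -> int:
        return self.n_exc + self.n_inh

    def validate(self) -> None:
        """Raise ValueError on any structural invariant violation."""
        if np.any(self.Wee < 0) or np.any(self.Wei < 0):
            raise ValueError("Wee/Wei must be nonnegative")
        if np.any(self.Wie > 0) or np.any(self.Wii > 0):
            raise ValueError("Wie/Wii must be nonpositive")
        for name, blk in (("Wie", self.Wie), ("Wii", self.Wii)):
            off = blk.copy()
            np.fill_diagonal(off, 0.0)
            if np.any(off != 0):
                raise ValueError(f"{name} must be diagonal")
        for name, blk, mask in (
            ("Wee", self.Wee, self.mask_ee),
            ("Wei", self.Wei, self.mask_ei),
        ):
            if np.any(blk[~mask] != 0):
                raise ValueError(f"masked entries of {name} must be exactly 0")

    def assemble(self) -> np.ndarray:
        """Dense ``n x n`` matrix with the E/I block layout."""
        top = np.hstack([self.Wee, self.Wie])
        bot = np.hstack([self.Wei, self.Wii])
        return np.vstack([top, bot])

    def copy(self) -> "StructuredConnectivity":
        return StructuredConnectivity(
            self.n_exc, self.n_inh,
            self.Wee.copy(), self.Wie.copy(), self.Wei.copy(), self.Wii.copy(),
            self.mask_ee.copy(), self.mask_ei.copy(),
        )


def random_offdiag_mask(n_rows: int, n_cols: int, rng: np.random.Generator,
                        sparsity: float = OFFDIAG_SPARSITY) -> np.ndarray:
    """Binary mask keeping the diagonal and a random (1-sparsity) fraction
    of off-diagonal entries; exactly ``ceil(sparsity * n_offdiag)`` entries
    are zeroed."""
    mask = np.ones((n_rows, n_cols), dtype=bool)
    off_idx = [(i, j) for i in range(n_rows) for j in range(n_cols) if i != j]
    n_zero = int(np.ceil(sparsity * len(off_idx)))
    chosen = rng.choice(len(off_idx), size=n_zero, replace=False)
    for k in chosen:
        mask[off_idx[k]] = False
    return mask


@dataclass
class ModulationMatrix:
    """Nonnegative rank-1 regime modulation ``Gamma = u v^T``.

    ``regime_index`` is 1-based, matching regime labels at the interface.
    With ``pinned=True`` the factors are the all-ones vectors exactly, so
    ``W o Gamma = W`` (the baseline regime of real-data fits).
    """

    regime_index: int
    u: np.ndarray
    v: np.ndarray
    pinned: bool = False

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float).ravel()
        self.v = np.asarray(self.v, dtype=float).ravel()
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must have equal length")
        if self.regime_index < 1:
            raise ValueError("regime_index is 1-based and must be >= 1")
        if self.pinned:
            self.u = np.ones_like(self.u)
            self.v = np.ones_like(self.v)

    @property
    def n(self) -> int:
        return self.u.size

    def dense(self) -> np.ndarray:
        return np.outer(self.u, self.v)

    def validate(self) -> None:
        if np.any(self.u < 0) or np.any(self.v < 0):
            raise ValueError("modulation factors must be nonnegative")
        if self.pinned and (np.any(self.u != 1.0) or np.any(self.v != 1.0)):
            raise ValueError("pinned baseline modulation must be exactly all ones")

    @classmethod
    def ones(cls, regime_index: int, n: int, pinned: bool = False) -> "ModulationMatrix":
        return cls(regime_index, np.ones(n), np.ones(n), pinned=pinned)

    def copy(self) -> "ModulationMatrix":
        return ModulationMatrix(self.regime_index, self.u.copy(), self.v.copy(),
                                pinned=self.pinned)


@dataclass
class ModelParameters:
    """Full parameter bundle of a modulated network model.

    Attributes
    ----------
    W : StructuredConnectivity
    gammas : list of ModulationMatrix, one per regime, regime_index 1..m.
    D : (n,) positive decay rates; the update applies ``-D x``.
    s_exc, s_inh : sigmoid slope per population group.
    V : (n,) sigmoid offset.
    C : (n,) bias.
    H : (channels, n) lead field; inhibitory columns are all zero.
    Q : (n, n) process noise covariance (for eps).
    R : (channels, channels) measurement noise covariance (for nu).
    """

    W: StructuredConnectivity
    gammas: list
    D: np.ndarray
    s_exc: float
    s_inh: float
    V: np.ndarray
    C: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        n = self.W.n
        self.D = np.asarray(self.D, dtype=float).ravel()
        self.V = np.asarray(self.V, dtype=float).ravel()
        self.C = np.asarray(self.C, dtype=float).ravel()
        self.H = np.asarray(self.H, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.s_exc = float(self.s_exc)
        self.s_inh = float(self.s_inh)
        for name, v in (("D", self.D), ("V", self.V), ("C", self.C)):
            if v.shape != (n,):
                raise ValueError(f"{name} must have length n={n}")
        if self.H.ndim != 2 or self.H.shape[1] != n:
            raise ValueError(f"H must be (channels, {n})")
        if self.Q.shape != (n, n):
            raise ValueError(f"Q must be ({n}, {n})")
        nc = self.H.shape[0]
        if self.R.shape != (nc, nc):
            raise ValueError(f"R must be ({nc}, {nc})")
        if len(self.gammas) < 1:
            raise ValueError("need at least one modulation matrix (m >= 1)")
        for i, g in enumerate(self.gammas, start=1):
            if g.regime_index != i:
                raise ValueError("gammas must be ordered with regime_index 1..m")
            if g.n != n:
                raise ValueError("modulation dimension must equal n")

    @property
    def n(self) -> int:
        return self.W.n

    @property
    def n_exc(self) -> int:
        return self.W.n_exc

    @property
    def n_inh(self) -> int:
        return self.W.n_inh

    @property
    def n_channels(self) -> int:
        return self.H.shape[0]

    @property
    def m(self) -> int:
        return len(self.gammas)

    @property
    def slope_vector(self) -> np.ndarray:
        """Per-population slope: E slope on excitatory entries, I slope on
        inhibitory entries (excitatory populations stacked first)."""
        return np.concatenate([
            np.full(self.n_exc, self.s_exc),
            np.full(self.n_inh, self.s_inh),
        ])

    def validate(self) -> None:
        self.W.validate()
        for g in self.gammas:
            g.validate()
        if np.any(self.H[:, self.n_exc:] != 0):
            raise ValueError("inhibitory columns of H must be zero")
        for name, S in (("Q", self.Q), ("R", self.R)):
            if not np.allclose(S, S.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if np.min(np.linalg.eigvalsh(0.5 * (S + S.T))) < -1e-10:
                raise ValueError(f"{name} must be positive semidefinite")

    def gamma_for_regime(self, regime: int) -> ModulationMatrix:
        if not 1 <= regime <= self.m:
            raise IndexError(f"regime {regime} out of range 1..{self.m}")
        return self.gammas[regime - 1]

    def effective_connectivity(self, regime: int) -> np.ndarray:
        """``W o Gamma_regime`` as a dense matrix."""
        return self.W.assemble() * self.gamma_for_regime(regime).dense()

    def copy(self) -> "ModelParameters":
        return replace(
            self,
            W=self.W.copy(),
            gammas=[g.copy() for g in self.gammas],
            D=self.D.copy(), V=self.V.copy(), C=self.C.copy(),
            H=self.H.copy(), Q=self.Q.copy(), R=self.R.copy(),
        )


@dataclass
class LabeledRecording:
    """Multichannel observations with a per-timestep regime label.

    ``y`` is channels x T; ``labels`` is a length-T integer vector with
    values in 1..m.  ``session_boundaries`` optionally lists the start
    index of each concatenated session so that fitting windows can avoid
    straddling concatenation seams.
    """

    y: np.ndarray
    fs: float
    labels: np.ndarray
    channel_names: list | None = None
    session_boundaries: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if self.y.ndim != 2:
            raise ValueError("y must be channels x T")
        if self.labels.shape != (self.y.shape[1],):
            raise ValueError("labels length must equal number of timesteps")
        if self.labels.size and np.min(self.labels) < 1:
            raise ValueError("regime labels are 1-based; found label < 1")

    @property
    def n_channels(self) -> int:
        return self.y.shape[0]

    @property
    def T(self) -> int:
        return self.y.shape[1]

    @property
    def duration(self) -> float:
        return self.T / self.fs

    @property
    def m(self) -> int:
        return int(np.max(self.labels)) if self.labels.size else 0


def step(x: np.ndarray, params: ModelParameters, regime: int,
         eps: np.ndarray | None = None) -> np.ndarray:
    """One forward step of the modulated dynamics.

    Returns ``x + (W o Gamma_regime) tanh(S x + V) - D x + C + eps``
    with the slope applied elementwise per population group.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape != (params.n,):
        raise ValueError(f"state must have length n={params.n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("state contains non-finite values")
    M = params.effective_connectivity(regime)
    phi = np.tanh(params.slope_vector * x + params.V)
    out = x + M @ phi + DECAY_SIGN * params.D * x + params.C
    if eps is not None:
        out = out + np.asarray(eps, dtype=float).ravel()
    return out


def observe(x: np.ndarray, params: ModelParameters,
            nu: np.ndarray | None = None) -> np.ndarray:
    """Observation map ``y = H x + nu``."""
    x = np.asarray(x, dtype=float).ravel()
    if x.shape != (params.n,):
        raise ValueError(f"state must have length n={params.n}")
    y = params.H @ x
    if nu is not None:
        y = y + np.asarray(nu, dtype=float).ravel()
    return y


def _check_psd(S: np.ndarray, name: str) -> None:
    S = 0.5 * (S + S.T)
    if np.min(np.linalg.eigvalsh(S)) < -1e-10:
        raise ValueError(f"{name} must be positive semidefinite")


def _noise_factor(S: np.ndarray) -> np.ndarray | None:
    """Cholesky-like factor L with L L^T = S, or None when S == 0."""
    if not np.any(S):
        return None
    S = 0.5 * (S + S.T)
    w, U = np.linalg.eigh(S)
    w = np.clip(w, 0.0, None)
    return U * np.sqrt(w)


def simulate(params: ModelParameters, labels, x0: np.ndarray | None = None,
             seed: int | np.random.Generator | None = None
             ) -> tuple[np.ndarray, np.ndarray]:
    """Forward-simulate states and observations under a regime sequence.

    ``labels[t]`` selects the modulation used for the transition out of
    time ``t``.  Process and measurement noise are drawn from a generator
    seeded by ``seed``; with both covariances zero the output is
    deterministic and seed-independent.

    Returns ``(states, observations)`` of shapes (n, T) and (channels, T).
    """
    labels = np.asarray(labels, dtype=int).ravel()
    T = labels.size
    if T < 1:
        raise ValueError("need at least one timestep")
    if np.min(labels) < 1 or np.max(labels) > params.m:
        raise IndexError("regime label out of range 1..m")
    _check_psd(params.Q, "Q")
    _check_psd(params.R, "R")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, nc = params.n, params.n_channels
    Lq = _noise_factor(params.Q)
    Lr = _noise_factor(params.R)

    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).ravel().copy()
    states = np.empty((n, T))
    obs = np.empty((nc, T))
    for t in range(T):
        states[:, t] = x
        nu = Lr @ rng.standard_normal(nc) if Lr is not None else None
        obs[:, t] = observe(x, params, nu)
        eps = Lq @ rng.standard_normal(n) if Lq is not None else None
        x = step(x, params, int(labels[t]), eps)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"simulation diverged at t={t}")
    return states, obs
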