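"""Asymmetric kinetic Ising model: exact dynamics, sampling and moments.

The model is a discrete-time Markov chain over N binary spins
``s_i ∈ {-1, +1}`` updated in parallel.  Conditioned on the previous
configuration, spins are independent with

    P(s_i = +1 | s_prev) = exp(h_i) / (2 cosh h_i),
    h_i = H_i + sum_j J_ij s_j,prev,

where ``H`` are local fields and ``J`` (generally asymmetric) couples unit
``i`` at time ``t`` to unit ``j`` at time ``t - 1``.  This module provides
the exact transition rule, a vectorised trajectory sampler, empirical
moment estimators, and an exact enumeration oracle (small ``N``) used to
validate every mean-field approximation in the package.

State encoding for enumeration is a little-endian bitmask: state index
``x`` has ``bit i = (s_i + 1) / 2``, with unit 0 as the least-significant
bit.  This convention is fixed so oracle results are portable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "ModelParameters",
    "TrajectoryEnsemble",
    "MomentState",
    "MomentSeries",
    "ExactDistribution",
    "conditional_activation",
    "sample_trajectories",
    "empirical_moments",
    "enumerate_states",
    "transition_matrix",
    "evolve_exact",
    "exact_moments",
    "exact_moment_series",
    "stationary_joint",
    "EXACT_N_GUARD",
    "STATIONARY_N_GUARD",
]

#: Enumeration guards: forward propagation keeps 2^N-vectors; the
#: stationary one-step joint is effectively 4^N-sized.  Both bound memory
#: below ~1 GB.
EXACT_N_GUARD = 16
STATIONARY_N_GUARD = 12


@dataclass(frozen=True)
class ModelParameters:
    """Fields ``H`` (length N) and couplings ``J`` (N x N) of one network.

    ``J[i, j]`` couples unit ``i`` at time ``t`` to unit ``j`` at time
    ``t - 1``; no symmetry is assumed.
    """

    H: np.ndarray
    J: np.ndarray

    def __post_init__(self):
        H = np.asarray(self.H, dtype=float)
        J = np.asarray(self.J, dtype=float)
        if H.ndim != 1:
            raise ValueError("H must be a vector")
        if J.shape != (H.size, H.size):
            raise ValueError(f"J must be square with side {H.size}, got {J.shape}")
        if not (np.isfinite(H).all() and np.isfinite(J).all()):
            raise ValueError("H and J must be finite")
        object.__setattr__(self, "H", H)
        object.__setattr__(self, "J", J)

    @property
    def N(self) -> int:
        return self.H.size


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """R sampled trajectories of length T+1, entries in {-1, +1}.

    ``data`` has shape (R, T+1, N); row ``t = 0`` is the initial state.
    """

    data: np.ndarray
    seed: int | None = None
    params_id: str = ""

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError("data must have shape (R, T+1, N)")
        if not np.isin(data, (-1, 1)).all():
            raise ValueError("trajectory entries must be -1 or +1")
        object.__setattr__(self, "data", data.astype(np.int8, copy=False))

    @property
    def R(self) -> int:
        return self.data.shape[0]

    @property
    def T(self) -> int:
        return self.data.shape[1] - 1

    @property
    def N(self) -> int:
        return self.data.shape[2]


@dataclass
class MomentState:
    """Moments at one time step: rates ``m``, equal-time covariance ``C``
    and delayed covariance ``D`` (rows index time t, columns t-1)."""

    t: int
    m: np.ndarray
    C: np.ndarray
    D: np.ndarray


@dataclass
class MomentSeries:
    """Per-time moments for t = 0..T, stored as stacked arrays.

    ``m`` has shape (T+1, N); ``C`` and ``D`` have shape (T+1, N, N).
    Slot 0 holds the given initial values (``D[0]`` is conventionally 0).
    """

    m: np.ndarray
    C: np.ndarray
    D: np.ndarray

    @property
    def T(self) -> int:
        return self.m.shape[0] - 1

    @property
    def N(self) -> int:
        return self.m.shape[1]

    def state(self, t: int) -> MomentState:
        return MomentState(t=t, m=self.m[t], C=self.C[t], D=self.D[t])

    @classmethod
    def empty(cls, T: int, N: int) -> "MomentSeries":
        return cls(
            m=np.zeros((T + 1, N)),
            C=np.zeros((T + 1, N, N)),
            D=np.zeros((T + 1, N, N)),
        )


@dataclass
class ExactDistribution:
    """Probability vector over all 2^N states (little-endian encoding)."""

    p: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        n = p.size
        if n < 2 or (n & (n - 1)) != 0:
            raise ValueError("length must be a power of two")
        if (p < -1e-15).any():
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")
        object.__setattr__(self, "p", np.clip(p, 0.0, None))

    @property
    def N(self) -> int:
        return int(np.log2(self.p.size))

    @classmethod
    def point_mass(cls, s: np.ndarray) -> "ExactDistribution":
        s = _check_spins(s)
        idx = state_index(s)
        p = np.zeros(2 ** s.size)
        p[idx] = 1.0
        return cls(p)

    @classmethod
    def product(cls, m: np.ndarray) -> "ExactDistribution":
        """Independent-spin distribution with rates ``m`` (|m| <= 1)."""
        m = np.asarray(m, dtype=float)
        S = enumerate_states(m.size)
        p = np.prod((1.0 + S * m) / 2.0, axis=1)
        return cls(p)


def _check_spins(s) -> np.ndarray:
    s = np.asarray(s)
    if not np.isin(s, (-1, 1)).all():
        raise ValueError("spin entries must be -1 or +1")
    return s.astype(np.int8, copy=False)


def state_index(s: np.ndarray) -> int:
    """Little-endian index of a spin configuration (bit i = (s_i+1)/2)."""
    bits = (np.asarray(s) + 1) // 2
    return int(np.sum(bits * (1 << np.arange(bits.size))))


def enumerate_states(N: int) -> np.ndarray:
    """All 2^N spin configurations, shape (2^N, N), row x is state index x."""
    if N > EXACT_N_GUARD:
        raise ValueError(f"enumeration limited to N <= {EXACT_N_GUARD}, got {N}")
    idx = np.arange(2**N)[:, None]
    bits = (idx >> np.arange(N)[None, :]) & 1
    return (2 * bits - 1).astype(np.int8)


def conditional_activation(prev: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Per-unit probability of +1 given the previous configuration.

    Accepts a single configuration (length N) or a batch (R, N); returns
    the matching shape.  ``p_i = e^{h_i} / (2 cosh h_i) = expit(2 h_i)``.
    """
    prev = _check_spins(prev)
    if prev.shape[-1] != params.N:
        raise ValueError(
            f"configuration has {prev.shape[-1]} units, model has {params.N}"
        )
    h = params.H + prev @ params.J.T
    return expit(2.0 * h)


def sample_trajectories(
    params: ModelParameters,
    s0: np.ndarray,
    T: int,
    R: int,
    seed: int,
) -> TrajectoryEnsemble:
    """Sample R parallel-update trajectories of length T+1 from state s0.

    The sampler is vectorised across trials and deterministic per seed.
    """
    if T < 1 or R < 1:
        raise ValueError("need T >= 1 and R >= 1")
    s0 = _check_spins(s0)
    if s0.size != params.N:
        raise ValueError("initial state has wrong dimension")
    rng = np.random.default_rng(seed)
    data = np.empty((R, T + 1, params.N), dtype=np.int8)
    data[:, 0, :] = s0
    state = np.broadcast_to(s0, (R, params.N)).copy()
    for t in range(1, T + 1):
        p = conditional_activation(state, params)
        state = np.where(rng.random((R, params.N)) < p, 1, -1).astype(np.int8)
        data[:, t, :] = state
    return TrajectoryEnsemble(data=data, seed=seed)


def empirical_moments(ens: TrajectoryEnsemble) -> MomentSeries:
    """Sample moments per time step across trials.

    ``m_t`` and ``C_t`` are the mean and (population) covariance over
    trials at step t; ``D_t`` is the lag-1 cross-covariance between steps
    t and t-1.  ``D_0`` is set to zero by convention.
    """
    if ens.R < 2:
        raise ValueError("covariance needs at least 2 trials")
    X = ens.data.astype(float)
    series = MomentSeries.empty(ens.T, ens.N)
    series.m[:] = X.mean(axis=0)
    for t in range(ens.T + 1):
        xt = X[:, t, :]
        series.C[t] = xt.T @ xt / ens.R - np.outer(series.m[t], series.m[t])
        if t >= 1:
            xp = X[:, t - 1, :]
            series.D[t] = xt.T @ xp / ens.R - np.outer(series.m[t], series.m[t - 1])
    return series


def _field_table(params: ModelParameters, states: np.ndarray) -> np.ndarray:
    """Effective fields h_i for every previous state; shape (N, n_states)."""
    return params.H[:, None] + params.J @ states.T.astype(float)


def transition_matrix(params: ModelParameters) -> np.ndarray:
    """Dense transition matrix M[next, prev] (guarded at small N)."""
    N = params.N
    if N > STATIONARY_N_GUARD:
        raise ValueError(
            f"dense transition matrix limited to N <= {STATIONARY_N_GUARD}"
        )
    S = enumerate_states(N).astype(float)
    h = _field_table(params, S)  # (N, P) fields given prev state
    # log P(next | prev) = sum_i [ s_i^next h_i(prev) - log 2 cosh h_i(prev) ]
    logZ = np.sum(np.logaddexp(h, -h), axis=0)  # sum_i log(2 cosh h_i)
    return np.exp(S @ h - logZ)


def evolve_exact(
    params: ModelParameters, p0: ExactDistribution, T: int
) -> list[ExactDistribution]:
    """Propagate the full 2^N-state distribution T steps.

    Returns ``[p_0, p_1, ..., p_T]``.  Memory-bounded by processing
    previous states in chunks, so it works up to the N = 16 guard without
    materialising the full transition matrix.
    """
    N = params.N
    if N > EXACT_N_GUARD:
        raise ValueError(f"exact evolution limited to N <= {EXACT_N_GUARD}")
    if p0.N != N:
        raise ValueError("distribution size does not match model")
    P = 2**N
    S = enumerate_states(N).astype(float)
    chunk = max(1, min(P, (1 << 24) // P))
    out = [p0]
    p = p0.p
    for _ in range(T):
        nxt = np.zeros(P)
        for lo in range(0, P, chunk):
            sl = slice(lo, lo + chunk)
            h = _field_table(params, S[sl])
            logZ = np.sum(np.logaddexp(h, -h), axis=0)
            nxt += np.exp(S @ h - logZ) @ p[sl]
        nxt /= nxt.sum()
        p = nxt
        out.append(ExactDistribution(p))
    return out


def exact_moments(params: ModelParameters, p_prev: ExactDistribution) -> MomentState:
    """Exact one-step moments given the previous-state distribution.

    ``m`` and ``C`` describe the propagated marginal at time t; ``D`` is
    computed from the joint P(s_t | s_{t-1}) p_{t-1}(s_{t-1}).  Uses the
    conditional independence of spins at t, so no 2^N x 2^N object is
    formed.
    """
    N = params.N
    if N > EXACT_N_GUARD:
        raise ValueError(f"exact moments limited to N <= {EXACT_N_GUARD}")
    S = enumerate_states(N).astype(float)
    h = _field_table(params, S)  # (N, P)
    tm = np.tanh(h)  # E[s_i,t | prev]
    w = p_prev.p
    m = tm @ w
    m_prev = S.T @ w
    # E[s_i s_k] at t: tanh_i tanh_k off-diagonal, 1 on the diagonal.
    E2 = (tm * w) @ tm.T
    np.fill_diagonal(E2, 1.0)
    C = E2 - np.outer(m, m)
    D = (tm * w) @ S - np.outer(m, m_prev)
    return MomentState(t=-1, m=m, C=C, D=D)


def exact_moment_series(
    params: ModelParameters, p0: ExactDistribution, T: int
) -> MomentSeries:
    """Exact moments for t = 0..T starting from distribution p0.

    Slot 0 holds the moments of p0 itself with D_0 = 0.
    """
    dists = evolve_exact(params, p0, T)
    N = params.N
    S = enumerate_states(N).astype(float)
    series = MomentSeries.empty(T, N)
    m0 = S.T @ p0.p
    series.m[0] = m0
    E2 = (S.T * p0.p) @ S
    series.C[0] = E2 - np.outer(m0, m0)
    for t in range(1, T + 1):
        ms = exact_moments(params, dists[t - 1])
        series.m[t], series.C[t], series.D[t] = ms.m, ms.C, ms.D
    return series


def stationary_joint(
    params: ModelParameters, tol: float = 1e-13, max_iter: int = 100_000
) -> tuple[ExactDistribution, np.ndarray]:
    """Stationary distribution and one-step joint of the chain.

    Power-iterates the exact propagation until the L1 residual drops below
    ``tol``; returns the stationary marginal pi and the joint matrix
    ``joint[next, prev] = P(next | prev) pi(prev)``.  The chain is
    irreducible for finite parameters, so the fixed point is unique.
    """
    N = params.N
    if N > STATIONARY_N_GUARD:
        raise ValueError(
            f"stationary joint limited to N <= {STATIONARY_N_GUARD}"
        )
    M = transition_matrix(params)
    p = np.full(2**N, 1.0 / 2**N)
    for _ in range(max_iter):
        nxt = M @ p
        nxt /= nxt.sum()
        res = np.abs(nxt - p).sum()
        p = nxt
        if res < tol:
            break
    else:
        raise RuntimeError(
            f"stationary iteration did not converge; residual {res:.3e}"
        )
    joint = M * p[None, :]
    return ExactDistribution(p), joint
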