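"""Maximum-likelihood inverse Ising problem (Boltzmann learning).

Fields and couplings are fitted by gradient ascent on the exact
log-likelihood of observed trajectories.  The gradients are moment
mismatches: ``<S_i> - m_i`` for fields and
``<S_i S_l,prev> - (D_il + m_i m~_l)`` for couplings, where ``(m, D)``
are model statistics conditioned on the empirical previous-step
distribution.  They are computed either exactly (cost proportional to
the pooled sample count) or in a one-shot mean-field evaluation from the
pooled previous-step moments using any of the forward approximations,
which makes each iteration's cost independent of the amount of data.

Statistics are pooled over trials and time steps (stationary learning);
no per-time-step parameters are fitted and no regularisation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import ModelParameters, TrajectoryEnsemble
from .mf_gaussian import QuadratureSpec, plefka_tm1_rates_delayed
from .mf_independent import (
    SolverOptions,
    nmf_step,
    plefka_t_first,
    plefka_t_second,
    tap_step,
)
from .mf_pairwise import TwoStepMemory, plefka2_delayed

__all__ = [
    "SufficientStatistics",
    "LearningConfig",
    "pool_statistics",
    "log_likelihood",
    "gradients",
    "fit",
    "INVERSE_METHODS",
]

INVERSE_METHODS = (
    "exact",
    "nmf",
    "tap",
    "plefka_t1",
    "plefka_t2",
    "plefka_tm1",
    "plefka2_t",
)


@dataclass
class SufficientStatistics:
    """Pooled empirical moments driving the learning iterations.

    ``mean_s``/``cross_lag`` are the data-side targets; ``prev_mean``,
    ``prev_cov`` and ``prev_dcov`` summarise the empirical previous-step
    distribution for the mean-field gradients.  ``prev_states`` (the
    pooled previous-step configurations) is retained for the exact
    gradient, which needs the full empirical distribution.
    """

    mean_s: np.ndarray
    cross_lag: np.ndarray
    prev_mean: np.ndarray
    prev_cov: np.ndarray
    prev_dcov: np.ndarray
    RT: int
    prev_states: np.ndarray | None = None

    @property
    def N(self) -> int:
        return self.mean_s.size


@dataclass
class LearningConfig:
    """Gradient-ascent settings.

    Effective step sizes on the moment mismatches are ``eta_H = 0.1`` and
    ``eta_J = 1/sqrt(N)`` (the sample-count prefactor of the raw
    likelihood gradient is absorbed into the rates).
    """

    method: str = "exact"
    eta_H: float = 0.1
    eta_J: float | None = None  # default 1/sqrt(N), resolved at fit time
    max_iter: int = 10_000
    grad_tol: float = 1e-6
    solver: SolverOptions = field(default_factory=SolverOptions)
    quad: QuadratureSpec = field(default_factory=QuadratureSpec)

    def __post_init__(self):
        if self.method not in INVERSE_METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; choose from {INVERSE_METHODS}"
            )
        if self.eta_H <= 0 or self.grad_tol <= 0 or self.max_iter < 1:
            raise ValueError("rates, tolerance and iteration cap must be positive")


def pool_statistics(ens: TrajectoryEnsemble) -> SufficientStatistics:
    """Pool moments over all trials and time steps t = 1..T.

    Previous-step statistics are pooled over t-1 = 0..T-1.
    """
    if ens.R * ens.T < 2:
        raise ValueError("need at least 2 pooled samples")
    X = ens.data.astype(float)
    cur = X[:, 1:, :].reshape(-1, ens.N)  # (RT, N)
    prev = X[:, :-1, :].reshape(-1, ens.N)
    RT = cur.shape[0]
    mean_s = cur.mean(axis=0)
    prev_mean = prev.mean(axis=0)
    cross_lag = cur.T @ prev / RT
    prev_cov = prev.T @ prev / RT - np.outer(prev_mean, prev_mean)
    prev_dcov = cross_lag - np.outer(mean_s, prev_mean)
    return SufficientStatistics(
        mean_s=mean_s,
        cross_lag=cross_lag,
        prev_mean=prev_mean,
        prev_cov=prev_cov,
        prev_dcov=prev_dcov,
        RT=RT,
        prev_states=prev,
    )


def log_likelihood(ens: TrajectoryEnsemble, params: ModelParameters) -> float:
    """Exact log-likelihood of the ensemble under the model.

    ``l = sum_{t,r,i} (S_i,t h_i,t - log 2 cosh h_i,t)``; always <= 0.
    """
    if ens.N != params.N:
        raise ValueError("ensemble and model dimensions differ")
    X = ens.data.astype(float)
    cur = X[:, 1:, :]
    prev = X[:, :-1, :]
    h = params.H + prev @ params.J.T
    return float(np.sum(cur * h - np.logaddexp(h, -h)))


def _model_moments(
    stats: SufficientStatistics,
    params: ModelParameters,
    method: str,
    solver: SolverOptions,
    quad: QuadratureSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """One-shot model estimates (m, D) conditioned on the empirical
    previous-step statistics, per the chosen approximation."""
    mt, Ct = stats.prev_mean, stats.prev_cov
    if method == "nmf":
        st = nmf_step(mt, params)
    elif method == "tap":
        st = tap_step(mt, params, solver)
    elif method == "plefka_t1":
        st = plefka_t_first(mt, Ct, params)
    elif method == "plefka_t2":
        st = plefka_t_second(mt, Ct, params, solver)
    elif method == "plefka_tm1":
        return plefka_tm1_rates_delayed(mt, Ct, params, quad)
    elif method == "plefka2_t":
        mem = TwoStepMemory(
            m_prev=mt, C_prev=Ct, D_prev=stats.prev_dcov, m_prev2=mt, C_prev2=Ct
        )
        m, D = plefka2_delayed(mem, params, solver)
        return m, D
    else:  # pragma: no cover - guarded by LearningConfig
        raise ValueError(f"unknown method {method!r}")
    return st.m, st.D


def gradients(
    stats: SufficientStatistics,
    params: ModelParameters,
    method: str = "exact",
    solver: SolverOptions = SolverOptions(),
    quad: QuadratureSpec = QuadratureSpec(),
) -> tuple[np.ndarray, np.ndarray]:
    """Moment-mismatch gradients for (H, J).

    The sample-count prefactor of the raw likelihood gradient is
    omitted; callers apply it through the learning rates.
    """
    if method == "exact":
        if stats.prev_states is None:
            raise ValueError("exact gradients need the pooled previous states")
        prev = stats.prev_states
        h = params.H + prev @ params.J.T
        tm = np.tanh(h)
        m = tm.mean(axis=0)
        cross_model = tm.T @ prev / prev.shape[0]
        dH = stats.mean_s - m
        dJ = stats.cross_lag - cross_model
        return dH, dJ
    m, D = _model_moments(stats, params, method, solver, quad)
    dH = stats.mean_s - m
    dJ = stats.cross_lag - (D + np.outer(m, stats.prev_mean))
    return dH, dJ


def fit(
    ens: TrajectoryEnsemble | SufficientStatistics,
    config: LearningConfig = LearningConfig(),
) -> tuple[ModelParameters, list[float]]:
    """Gradient-ascent fit of (H, J) from trajectory data.

    Starts from ``H = 0, J = 0`` and iterates until the max-norm of the
    moment mismatch drops below ``grad_tol`` or ``max_iter`` is reached.
    Returns the fitted parameters and the per-iteration gradient-norm
    log.  Deterministic given the inputs.
    """
    stats = ens if isinstance(ens, SufficientStatistics) else pool_statistics(ens)
    N = stats.N
    eta_J = config.eta_J if config.eta_J is not None else 1.0 / np.sqrt(N)
    H = np.zeros(N)
    J = np.zeros((N, N))
    history: list[float] = []
    for _ in range(config.max_iter):
        params = ModelParameters(H=H, J=J)
        dH, dJ = gradients(stats, params, config.method, config.solver, config.quad)
        gnorm = max(np.abs(dH).max(), np.abs(dJ).max())
        history.append(gnorm)
        if not (np.isfinite(dH).all() and np.isfinite(dJ).all()):
            raise RuntimeError("gradient diverged (non-finite values)")
        if gnorm < config.grad_tol:
            break
        H = H + config.eta_H * dH
        J = J + eta_J * dJ
        if not (np.isfinite(H).all() and np.isfinite(J).all()):
            raise RuntimeError("parameters diverged during learning")
    return ModelParameters(H=H, J=J), history
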