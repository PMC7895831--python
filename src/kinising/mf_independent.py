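"""Plefka expansions around independent reference models.

Two families are implemented:

* Plefka[t-1, t] — independent reference at both time steps; the first
  order is the classical naive mean field (nMF) and the second order the
  TAP equations with an Onsager reaction term.
* Plefka[t] — independent reference at time t only, conditioning on the
  previous equal-time covariance ``C_{t-1}``; first and second order.

Each step maps previous-step statistics to a :class:`MomentState`
(rates ``m``, equal-time covariance ``C``, delayed covariance ``D``).
The diagonal of ``C`` is always set to ``1 - m**2``, exact for +-1 spins;
the expansions define off-diagonal entries only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .core_model import ModelParameters, MomentSeries, MomentState

__all__ = [
    "SolverOptions",
    "nmf_step",
    "tap_step",
    "plefka_t_first",
    "plefka_t_second",
    "rollout",
    "solve_tanh_fixed_point",
    "FORWARD_METHODS",
]


@dataclass(frozen=True)
class SolverOptions:
    """Fixed-point solver controls for the self-consistent equations."""

    tol: float = 1e-12
    max_iter: int = 200
    damping: float = 0.0
    fallback_damping: float = 0.5

    def __post_init__(self):
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")
        if not 0 <= self.damping < 1:
            raise ValueError("damping must lie in [0, 1)")


def solve_tanh_fixed_point(
    a: np.ndarray, b: np.ndarray, opts: SolverOptions, x0: np.ndarray | None = None
) -> np.ndarray:
    """Solve ``x = tanh(a - b * x)`` elementwise.

    ``b >= 0`` (the usual case: Onsager-type reaction coefficients)
    guarantees a unique root.  Plain damped iteration from the nMF value
    ``tanh(a)``; on failure, retries with heavier damping and finally
    falls back to per-element bracketed root finding.
    """
    a = np.asarray(a, dtype=float)
    b = np.broadcast_to(np.asarray(b, dtype=float), a.shape)
    x = np.tanh(a) if x0 is None else np.asarray(x0, dtype=float).copy()
    for damping in (opts.damping, opts.fallback_damping):
        xi = x.copy()
        for _ in range(opts.max_iter):
            nxt = np.tanh(a - b * xi)
            res = np.max(np.abs(nxt - xi))
            xi = damping * xi + (1 - damping) * nxt
            if res < opts.tol:
                return xi
    # Bracketed fallback: g(x) = x - tanh(a - b x) is monotone for b > -1.
    out = np.empty_like(a)
    flat_a, flat_b = a.ravel(), b.ravel()
    flat_out = out.ravel()
    for k in range(flat_a.size):
        ak, bk = flat_a[k], flat_b[k]
        if bk <= -1:
            raise RuntimeError(
                f"non-monotone self-consistent equation (b={bk:.3g} <= -1)"
            )
        flat_out[k] = brentq(
            lambda x: x - np.tanh(ak - bk * x), -1.0, 1.0, xtol=opts.tol
        )
    return out


def _check_rates(m_prev: np.ndarray, params: ModelParameters) -> np.ndarray:
    m_prev = np.asarray(m_prev, dtype=float)
    if m_prev.shape != (params.N,):
        raise ValueError("m_prev has wrong dimension")
    if (np.abs(m_prev) > 1 + 1e-12).any():
        raise ValueError("rates must satisfy |m| <= 1")
    return np.clip(m_prev, -1.0, 1.0)


def _with_exact_diag(C: np.ndarray, m: np.ndarray) -> np.ndarray:
    np.fill_diagonal(C, 1.0 - m**2)
    return C


def nmf_step(m_prev: np.ndarray, params: ModelParameters) -> MomentState:
    """Naive mean-field update (first-order Plefka[t-1, t]).

    ``m_i = tanh(H_i + sum_j J_ij m_j_prev)``; equal-time covariances
    vanish off-diagonal; ``D_il = J_il (1 - m_i^2)(1 - m_l_prev^2)``.
    """
    m_prev = _check_rates(m_prev, params)
    m = np.tanh(params.H + params.J @ m_prev)
    a_i = 1.0 - m**2
    a_l = 1.0 - m_prev**2
    C = _with_exact_diag(np.zeros((params.N, params.N)), m)
    D = params.J * np.outer(a_i, a_l)
    return MomentState(t=-1, m=m, C=C, D=D)


def tap_step(
    m_prev: np.ndarray, params: ModelParameters, opts: SolverOptions = SolverOptions()
) -> MomentState:
    """TAP update (second-order Plefka[t-1, t]).

    The rate equation is self-consistent: ``m_i`` appears inside the
    Onsager reaction term ``- m_i sum_j J_ij^2 (1 - m_j_prev^2)``.
    Correlations pick up the second-order corrections, including the
    ``(1 + 2 J_il m_i m_l_prev)`` factor in the delayed covariance.
    """
    m_prev = _check_rates(m_prev, params)
    J = params.J
    a_l = 1.0 - m_prev**2
    field = params.H + J @ m_prev
    onsager = (J**2) @ a_l
    m = solve_tanh_fixed_point(field, onsager, opts)
    a_i = 1.0 - m**2
    C = np.outer(a_i, a_i) * ((J * a_l[None, :]) @ J.T)
    C = _with_exact_diag(C, m)
    D = J * np.outer(a_i, a_l) * (1.0 + 2.0 * J * np.outer(m, m_prev))
    return MomentState(t=-1, m=m, C=C, D=D)


def plefka_t_first(
    m_prev: np.ndarray, C_prev: np.ndarray, params: ModelParameters
) -> MomentState:
    """First-order Plefka[t]: nMF rates, delayed covariance driven by C_prev.

    ``D_il = (1 - m_i^2) sum_j J_ij C_jl_prev``; reduces to the nMF result
    when ``C_prev`` is the independent-model covariance diag(1 - m_prev^2).
    """
    m_prev = _check_rates(m_prev, params)
    C_prev = np.asarray(C_prev, dtype=float)
    m = np.tanh(params.H + params.J @ m_prev)
    a_i = 1.0 - m**2
    C = _with_exact_diag(np.zeros((params.N, params.N)), m)
    D = a_i[:, None] * (params.J @ C_prev)
    return MomentState(t=-1, m=m, C=C, D=D)


def plefka_t_second(
    m_prev: np.ndarray,
    C_prev: np.ndarray,
    params: ModelParameters,
    opts: SolverOptions = SolverOptions(),
) -> MomentState:
    """Second-order Plefka[t], conditioned on the previous covariance.

    The reaction coefficient generalises TAP's to the full quadratic form
    ``sum_jl J_ij J_il C_jl_prev``; equal-time covariances are transported
    through the couplings as ``(1-m_i^2)(1-m_k^2) [J C_prev J^T]_ik``.
    With ``C_prev = diag(1 - m_prev^2)`` this reproduces TAP exactly.
    """
    m_prev = _check_rates(m_prev, params)
    C_prev = np.asarray(C_prev, dtype=float)
    J = params.J
    field = params.H + J @ m_prev
    JCJ = J @ C_prev @ J.T
    m = solve_tanh_fixed_point(field, np.diag(JCJ), opts)
    a_i = 1.0 - m**2
    C = np.outer(a_i, a_i) * JCJ
    C = _with_exact_diag(C, m)
    D = a_i[:, None] * (J @ C_prev) * (1.0 + 2.0 * J * np.outer(m, m_prev))
    return MomentState(t=-1, m=m, C=C, D=D)


def _step_dispatch(method: str):
    table = {
        "nmf": lambda m, C, params, opts: nmf_step(m, params),
        "tap": lambda m, C, params, opts: tap_step(m, params, opts),
        "plefka_t1": lambda m, C, params, opts: plefka_t_first(m, C, params),
        "plefka_t2": lambda m, C, params, opts: plefka_t_second(m, C, params, opts),
    }
    if method not in table:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(table)}")
    return table[method]


FORWARD_METHODS = ("nmf", "tap", "plefka_t1", "plefka_t2")


def rollout(
    method: str,
    params: ModelParameters,
    m0: np.ndarray,
    C0: np.ndarray | None = None,
    D0: np.ndarray | None = None,
    T: int = 1,
    opts: SolverOptions = SolverOptions(),
) -> MomentSeries:
    """Recursively apply the chosen mean-field step for T time steps.

    Plefka[t] variants propagate the approximated ``C_t`` into the next
    step; nMF/TAP consume rates only.  Solver failures are annotated with
    the time index at which they occurred.
    """
    step = _step_dispatch(method)
    N = params.N
    m0 = _check_rates(m0, params)
    C0 = np.zeros((N, N)) if C0 is None else np.asarray(C0, dtype=float)
    D0 = np.zeros((N, N)) if D0 is None else np.asarray(D0, dtype=float)
    series = MomentSeries.empty(T, N)
    series.m[0], series.C[0], series.D[0] = m0, C0, D0
    m, C = m0, C0
    for t in range(1, T + 1):
        try:
            state = step(m, C, params, opts)
        except RuntimeError as exc:
            raise RuntimeError(f"{method} step failed at t={t}: {exc}") from exc
        series.m[t], series.C[t], series.D[t] = state.m, state.C, state.D
        m, C = state.m, state.C
    return series
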