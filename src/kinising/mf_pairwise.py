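"""Plefka2[t]: second-order expansion around pairwise reference models.

For every ordered pair of units the reference distribution preserves a
single coupling — between ``s_i`` at time t and ``s_l`` at time t-1 for
delayed covariances, or between ``s_i`` and ``s_k`` both at time t for
equal-time covariances — while all other units are reduced to
independent marginals.  Each pair yields a small set of implicit scalar
equations of the form ``theta = a - b * tanh(theta)``; their solutions
give per-pair conditional rates from which means and covariances follow
by averaging over the conditioning spin.

This pairwise construction is the package's most accurate forward
method near the maximally fluctuating (critical) regime, where the
classical independent-reference expansions under- or over-estimate
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import ModelParameters, MomentSeries
from .mf_independent import SolverOptions

__all__ = [
    "TwoStepMemory",
    "solve_theta_scalar",
    "plefka2_delayed",
    "plefka2_equal_time",
    "plefka2_rollout",
]

_ATANH_CLIP = 1.0 - 1e-12


@dataclass
class TwoStepMemory:
    """Statistics of the two preceding steps driving one pairwise update.

    ``m_prev``/``C_prev`` refer to time t-1, ``m_prev2``/``C_prev2`` to
    t-2 and ``D_prev`` couples t-1 to t-2.  At the first step after a
    known initial condition, ``m_prev2`` and ``C_prev2`` are ``None`` and
    the conditioning-unit parameter is taken as ``arctanh(m_prev)``.
    """

    m_prev: np.ndarray
    C_prev: np.ndarray
    D_prev: np.ndarray
    m_prev2: np.ndarray | None = None
    C_prev2: np.ndarray | None = None


def solve_theta_scalar(
    a: float | np.ndarray,
    b: float | np.ndarray,
    opts: SolverOptions = SolverOptions(),
) -> float | np.ndarray:
    """Solve ``x = a - b * tanh(x)`` (elementwise for arrays).

    The equation is monotone with a unique root whenever ``b > -1``.
    Damped fixed-point iteration from ``x0 = a``; elements that fail to
    converge fall back to vectorised bisection on the bracket
    ``[a - |b|, a + |b|]``, which always terminates.
    """
    a_arr = np.atleast_1d(np.asarray(a, dtype=float))
    b_arr = np.broadcast_to(np.asarray(b, dtype=float), a_arr.shape).copy()
    if (b_arr <= -1).any():
        raise ValueError("need b > -1 for a unique root")
    x = a_arr.copy()
    for damping in (opts.damping, opts.fallback_damping):
        xi = x.copy()
        for _ in range(opts.max_iter):
            nxt = a_arr - b_arr * np.tanh(xi)
            res = np.abs(nxt - xi)
            xi = damping * xi + (1 - damping) * nxt
            if res.max() < opts.tol:
                return xi.reshape(np.shape(a)) if np.ndim(a) else float(xi[0])
        bad = res >= opts.tol
    # Bisection on the still-unconverged entries.
    out = xi
    lo = a_arr[bad] - np.abs(b_arr[bad]) - 1e-9
    hi = a_arr[bad] + np.abs(b_arr[bad]) + 1e-9
    ab, bb = a_arr[bad], b_arr[bad]
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        g = mid + bb * np.tanh(mid) - ab
        hi = np.where(g > 0, mid, hi)
        lo = np.where(g > 0, lo, mid)
        if (hi - lo).max() < opts.tol:
            break
    out[bad] = 0.5 * (lo + hi)
    return out.reshape(np.shape(a)) if np.ndim(a) else float(out[0])


def _theta_cond_prev(
    mem: TwoStepMemory, params: ModelParameters, opts: SolverOptions
) -> np.ndarray:
    """Independent parameters Theta* of the conditioning units at t-1.

    Computed TAP-style from the t-2 statistics when available; at the
    boundary after a known initial condition, Theta* is the arctanh of
    the given initial rates (the exact m-projection of that state).
    """
    if mem.m_prev2 is None:
        return np.arctanh(np.clip(mem.m_prev, -_ATANH_CLIP, _ATANH_CLIP))
    J = params.J
    a = params.H + J @ mem.m_prev2
    b = np.einsum("lm,mn,ln->l", J, mem.C_prev2, J)
    return solve_theta_scalar(a, b, opts)


def plefka2_delayed(
    mem: TwoStepMemory,
    params: ModelParameters,
    opts: SolverOptions = SolverOptions(),
    return_diagnostic: bool = False,
):
    """Rates ``m_t`` and delayed covariances ``D_t`` from pairwise references.

    For each pair (i, l) the conditional parameter ``theta_i(s_l = +-1)``
    solves an implicit equation whose linear term carries the direct
    coupling ``J_il`` plus a D-mediated indirect term, and whose reaction
    term excludes the conditioned unit from the variance correction.
    ``m_i,t`` is averaged over the conditioning spin and, across pairs,
    over l; the spread across pairs is an optional diagnostic that
    vanishes at J = 0.
    """
    J = params.J
    N = params.N
    m_prev = np.asarray(mem.m_prev, dtype=float)
    C_prev = np.asarray(mem.C_prev, dtype=float)
    D_prev = np.asarray(mem.D_prev, dtype=float)

    theta_cond = _theta_cond_prev(mem, params, opts)
    m_q = np.tanh(theta_cond)  # conditioning-unit rates under Q*

    a_base = params.H + J @ m_prev
    # Indirect coupling V_il = sum_{j != l, n} J_ij J_ln D_prev[j, n]
    V = J @ D_prev @ J.T - J * (J * D_prev).sum(axis=1)[None, :]
    # Reaction term b_il = sum_{j != l, n != l} J_ij J_in C_prev[j, n]
    JCJ = J @ C_prev @ J.T
    JC = J @ C_prev
    b = np.diag(JCJ)[:, None] - 2.0 * J * JC + (J**2) * np.diag(C_prev)[None, :]

    eff = J + V
    A_plus = a_base[:, None] + eff * (1.0 - m_q[None, :])
    A_minus = a_base[:, None] + eff * (-1.0 - m_q[None, :])
    try:
        t_plus = np.tanh(solve_theta_scalar(A_plus, b, opts))
        t_minus = np.tanh(solve_theta_scalar(A_minus, b, opts))
    except (ValueError, RuntimeError) as exc:
        raise RuntimeError(f"pairwise delayed solve failed: {exc}") from exc

    p_plus = (1.0 + m_q) / 2.0
    p_minus = (1.0 - m_q) / 2.0
    m_pairs = t_plus * p_plus[None, :] + t_minus * p_minus[None, :]
    corr = t_plus * p_plus[None, :] - t_minus * p_minus[None, :]
    D = corr - m_pairs * m_q[None, :]
    m = m_pairs.mean(axis=1)
    if return_diagnostic:
        spread = m_pairs.max(axis=1) - m_pairs.min(axis=1)
        return m, D, float(spread.max())
    return m, D


def plefka2_equal_time(
    m_prev: np.ndarray,
    C_prev: np.ndarray,
    params: ModelParameters,
    opts: SolverOptions = SolverOptions(),
) -> np.ndarray:
    """Equal-time covariance ``C_t`` from same-time pairwise references.

    Unit k's independent parameter solves the second-order reaction
    equation (the Plefka[t] rate equation); the conditional parameter of
    unit i given ``s_k`` shifts linearly through the transported
    covariance ``[J C_prev J^T]_ik``.  The two ordered estimates C_ik and
    C_ki are averaged, and the diagonal is set to ``1 - m^2``.
    """
    J = params.J
    N = params.N
    m_prev = np.asarray(m_prev, dtype=float)
    C_prev = np.asarray(C_prev, dtype=float)
    a_base = params.H + J @ m_prev
    JCJ = J @ C_prev @ J.T
    b = np.diag(JCJ)
    theta_cond = solve_theta_scalar(a_base, b, opts)
    m_k = np.tanh(theta_cond)

    A_plus = a_base[:, None] + JCJ * (1.0 - m_k[None, :])
    A_minus = a_base[:, None] + JCJ * (-1.0 - m_k[None, :])
    t_plus = np.tanh(solve_theta_scalar(A_plus, b[:, None], opts))
    t_minus = np.tanh(solve_theta_scalar(A_minus, b[:, None], opts))
    p_plus = (1.0 + m_k) / 2.0
    p_minus = (1.0 - m_k) / 2.0
    m_pairs = t_plus * p_plus[None, :] + t_minus * p_minus[None, :]
    corr = t_plus * p_plus[None, :] - t_minus * p_minus[None, :]
    C = corr - m_pairs * m_k[None, :]
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 1.0 - m_k**2)
    return C


def plefka2_rollout(
    params: ModelParameters,
    m0: np.ndarray,
    C0: np.ndarray | None = None,
    D0: np.ndarray | None = None,
    T: int = 1,
    opts: SolverOptions = SolverOptions(),
) -> MomentSeries:
    """Recursive Plefka2[t] forward prediction for T steps.

    Maintains the two-step memory (m, C at t-1 and t-2, D at t-1) across
    the recursion; the first step conditions on the given initial moments
    exactly.
    """
    N = params.N
    m0 = np.asarray(m0, dtype=float)
    C0 = np.zeros((N, N)) if C0 is None else np.asarray(C0, dtype=float)
    D0 = np.zeros((N, N)) if D0 is None else np.asarray(D0, dtype=float)
    series = MomentSeries.empty(T, N)
    series.m[0], series.C[0], series.D[0] = m0, C0, D0
    mem = TwoStepMemory(m_prev=m0, C_prev=C0, D_prev=D0)
    for t in range(1, T + 1):
        try:
            m_t, D_t = plefka2_delayed(mem, params, opts)
            C_t = plefka2_equal_time(mem.m_prev, mem.C_prev, params, opts)
        except RuntimeError as exc:
            raise RuntimeError(f"plefka2 step failed at t={t}: {exc}") from exc
        series.m[t], series.C[t], series.D[t] = m_t, C_t, D_t
        mem = TwoStepMemory(
            m_prev=m_t,
            C_prev=C_t,
            D_prev=D_t,
            m_prev2=mem.m_prev,
            C_prev2=mem.C_prev,
        )
    return series
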