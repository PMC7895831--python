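"""Entropy production, stationary mean-field solution and critical point.

Entropy production — the KL divergence rate between forward and
time-reversed path probabilities — quantifies the irreversibility of
the dynamics.  It vanishes under detailed balance (symmetric couplings)
and, at a non-equilibrium steady state, reduces to the coupling-weighted
asymmetry of the delayed covariance:

    sigma = sum_ij (J_ij - J_ji) D_ij.

The stationary mean-field solution of the asymmetric SK ensemble in the
thermodynamic limit describes each unit's effective field as a Gaussian
around ``H + beta*J0*m_bar`` with uniform field disorder on
``[-beta*H0, beta*H0]``.  Because couplings are fully asymmetric, the
coupling-disorder noise acts on +-1 spins (unit second moment), so the
total Gaussian smear is ``Delta_total = beta^2 Jsigma^2`` — the static
site-to-site dispersion ``beta^2 Jsigma^2 q`` of ``sum_j J_ij m_j`` plus
the dynamic part ``beta^2 Jsigma^2 (1 - q)``, where ``q`` is the
population-averaged squared magnetisation.  The ferromagnetic critical
point is where the ``m_bar = 0`` branch loses stability:

    beta * J0 * < int Dx sech^2(H + x * beta * Jsigma) >_H = 1.

With the ensemble defaults (H0 = 0.5, J0 = 1, Jsigma = 0.1) the root is
beta_c ~ 1.1108; field disorder shifts it up from the Curie-Weiss value
1/J0 at H0 = 0.

Disorder averages use Gauss-Legendre quadrature over the field interval
nested with Gauss-Hermite for the Gaussian noise — fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core_model import ModelParameters, stationary_joint
from .forward import run_forward, sampled_moments
from .mf_gaussian import QuadratureSpec
from .mf_independent import SolverOptions
from .sk_ensemble import SKEnsembleSpec, rescale

__all__ = [
    "StationarySolution",
    "entropy_production_mf",
    "entropy_production_exact",
    "stationary_mf",
    "critical_beta",
    "beta_scan",
    "reconstruction_experiment",
]


@dataclass(frozen=True)
class StationarySolution:
    """Order parameters of the stationary SK mean-field solution."""

    m_bar: float
    q: float
    Delta: float


def entropy_production_mf(params: ModelParameters, D: np.ndarray) -> float:
    """Steady-state entropy production from a delayed covariance.

    ``sigma = sum_ij (J_ij - J_ji) D_ij``; exactly zero for symmetric
    couplings.  The caller must supply a steady-state ``D`` (rollout tail
    or the exact stationary covariance).
    """
    D = np.asarray(D, dtype=float)
    if D.shape != params.J.shape:
        raise ValueError("D must match the coupling matrix shape")
    return float(np.sum((params.J - params.J.T) * D))


def entropy_production_exact(
    params: ModelParameters, tol: float = 1e-13
) -> float:
    """Entropy production as the forward/backward path KL divergence.

    Evaluated on the exact stationary joint distribution (guarded at
    small N).  Nonnegative up to numerical tolerance; zero iff the chain
    satisfies detailed balance.
    """
    pi, joint = stationary_joint(params, tol=tol)
    # joint[next, prev]; backward weight of the (prev, next) transition is
    # the same kernel run from `next`, i.e. joint transposed.
    F = joint
    B = joint.T
    mask = F > 0
    return float(np.sum(F[mask] * (np.log(F[mask]) - np.log(B[mask]))))


def _disorder_rule(half_width: float, nodes: int = 64):
    """Nodes/weights averaging over H ~ U(-half_width, half_width)."""
    if half_width == 0.0:
        return np.array([0.0]), np.array([1.0])
    x, w = np.polynomial.legendre.leggauss(nodes)
    return x * half_width, w / 2.0


def _mf_expectations(
    arg_shift: float,
    Delta: float,
    half_width: float,
    quad: QuadratureSpec,
    field_nodes: int,
):
    """Disorder-and-noise averages of tanh, tanh^2 and sech^2 of
    H + arg_shift + x sqrt(Delta)."""
    Hn, Hw = _disorder_rule(half_width, field_nodes)
    x, xw = quad.probabilists_rule()
    u = Hn[:, None] + arg_shift + x[None, :] * np.sqrt(max(Delta, 0.0))
    th = np.tanh(u)
    m = Hw @ (th @ xw)
    q = Hw @ ((th**2) @ xw)
    chi = Hw @ ((1.0 - th**2) @ xw)
    return float(m), float(q), float(chi)


def stationary_mf(
    spec: SKEnsembleSpec,
    tol: float = 1e-12,
    max_iter: int = 10_000,
    quad: QuadratureSpec = QuadratureSpec(),
    field_nodes: int = 64,
    m_init: float = 0.9,
) -> StationarySolution:
    """Stationary self-consistent solution of the SK mean-field equations.

    The mean magnetisation sees the full Gaussian smear
    ``Delta_total = beta^2 Jsigma^2``; damped fixed-point iteration from
    a positive initial value reaches the stable ordered branch when it
    exists.  The order parameter ``q`` is then resolved by splitting the
    smear into its static (quenched, weight q) and dynamic (weight 1-q)
    components and iterating the squared site magnetisation.
    """
    beta = spec.beta
    Delta_total = beta**2 * spec.Jsigma**2
    m = m_init
    damp = 0.5
    for _ in range(max_iter):
        m_new, _, _ = _mf_expectations(
            beta * spec.J0 * m, Delta_total, beta * spec.H0, quad, field_nodes
        )
        res = abs(m_new - m)
        m = damp * m + (1 - damp) * m_new
        if res < tol:
            break
    else:
        raise RuntimeError(f"stationary solution did not converge; residual {res:.3e}")

    # q = <E_y[ m(H, y)^2 ]>_H with m(H, y) = E_x tanh(H + bJ0 m + sd(y sqrt(q) + x sqrt(1-q)))
    Hn, Hw = _disorder_rule(beta * spec.H0, field_nodes)
    x, xw = quad.probabilists_rule()
    sd = np.sqrt(Delta_total)
    q = m**2
    for _ in range(max_iter):
        u = (
            Hn[:, None, None]
            + beta * spec.J0 * m
            + sd * (x[:, None] * np.sqrt(max(q, 0.0)) + x[None, :] * np.sqrt(max(1 - q, 0.0)))
        )
        m_site = np.tanh(u) @ xw  # (H, y)
        q_new = float(Hw @ ((m_site**2) @ xw))
        res_q = abs(q_new - q)
        q = damp * q + (1 - damp) * q_new
        if res_q < tol:
            break
    else:
        raise RuntimeError(f"q iteration did not converge; residual {res_q:.3e}")
    return StationarySolution(
        m_bar=m, q=q, Delta=beta**2 * spec.Jsigma**2 * (1.0 - q)
    )


def _paramagnetic_stability(
    beta: float,
    H0: float,
    J0: float,
    Jsigma: float,
    quad: QuadratureSpec,
    field_nodes: int,
) -> float:
    """Stability function of the m_bar = 0 branch; the critical point is
    its root.  Positive once the ordered solution exists."""
    Delta_total = beta**2 * Jsigma**2
    _, _, chi = _mf_expectations(0.0, Delta_total, beta * H0, quad, field_nodes)
    return beta * J0 * chi - 1.0


def critical_beta(
    H0: float = 0.5,
    J0: float = 1.0,
    Jsigma: float = 0.1,
    quad: QuadratureSpec = QuadratureSpec(),
    field_nodes: int = 64,
    xtol: float = 1e-10,
    bracket: tuple[float, float] = (1e-6, 10.0),
) -> float:
    """Inverse temperature where the zero-magnetisation branch loses
    stability (ferromagnetic critical point of the SK ensemble).

    At H0 = 0 and Jsigma = 0 this reduces to the Curie-Weiss condition
    beta * J0 = 1.  Field disorder raises the critical point.
    """
    if J0 <= 0:
        raise ValueError("J0 must be positive")

    def f(beta):
        return _paramagnetic_stability(beta, H0, J0, Jsigma, quad, field_nodes)

    lo, hi = bracket
    if f(lo) >= 0 or f(hi) <= 0:
        raise ValueError("stability function does not change sign on the bracket")
    return float(brentq(f, lo, hi, xtol=xtol))


def beta_scan(
    base_params: ModelParameters,
    betas,
    method: str,
    T: int = 128,
    R: int = 10_000,
    seed: int = 0,
    opts: SolverOptions = SolverOptions(),
    quad: QuadratureSpec = QuadratureSpec(),
) -> pd.DataFrame:
    """Final-step fluctuations and entropy production across temperatures.

    ``base_params`` is one disorder instance (conventionally at beta = 1);
    each row rescales it by beta, rolls the chosen method (or the
    trajectory sampler for ``method="sample"``) T steps from the all-ones
    start, and reports the mean off-diagonal equal-time covariance, mean
    delayed covariance and steady-state entropy production at t = T.
    """
    N = base_params.N
    off = ~np.eye(N, dtype=bool)
    rows = []
    for i, beta in enumerate(betas):
        params = rescale(base_params, float(beta))
        if method == "sample":
            series = sampled_moments(params, T, R, seed + i)
        else:
            series = run_forward(method, params, T, opts=opts, quad=quad)
        C_T, D_T = series.C[T], series.D[T]
        sigma = entropy_production_mf(params, D_T)
        rows.append(
            {
                "beta": float(beta),
                "mean_C": float(C_T[off].mean()),
                "mean_D": float(D_T.mean()),
                "ep": sigma,
                "exp_ep": float(np.exp(sigma)),
                "method": method,
            }
        )
    return pd.DataFrame(rows)


def reconstruction_experiment(
    ens,
    betas_tilde,
    forward_method: str,
    inverse_method: str = "exact",
    T: int = 128,
    R: int = 10_000,
    seed: int = 0,
    learning=None,
) -> tuple[pd.DataFrame, ModelParameters]:
    """Fit (H, J) from data recorded near the critical point, then scan a
    fictitious inverse temperature rescaling the fitted parameters.

    Returns the scan table plus the fitted parameters.  The peak of the
    reconstructed fluctuation curves locates the inferred model's own
    maximally fluctuating regime.
    """
    from .inverse_learning import LearningConfig, fit

    config = learning or LearningConfig(method=inverse_method)
    fitted, _ = fit(ens, config)
    table = beta_scan(fitted, betas_tilde, forward_method, T=T, R=R, seed=seed)
    return table, fitted
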