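"""Plefka[t-1]: Gaussian effective-field approximation (first order).

The reference model is independent at time t-1, so the effective field
``h_i = H_i + sum_j J_ij s_j,prev`` is a sum of independent bounded terms
and is treated as Gaussian with mean ``g_i = H_i + sum_j J_ij m_j,prev``
and variance ``Delta_i = sum_j J_ij^2 (1 - m_j,prev^2)``.  Rates follow
from univariate Gaussian averages of tanh; equal-time covariances from a
bivariate Gaussian with field correlation rho_ik; the delayed covariance
is linear in the previous covariance with a Gaussian-averaged
susceptibility factor.  Exact for fully asymmetric networks in the
thermodynamic limit.

Integrals use Gauss-Hermite quadrature (default 40 nodes); bivariate
integrals use tensor-product nodes after a Cholesky transform of the 2x2
correlation matrix.  Zero-variance fields collapse to a point mass and
bypass quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import ModelParameters, MomentState

__all__ = [
    "QuadratureSpec",
    "GaussianFieldStats",
    "gaussian_field_stats",
    "gauss_expect",
    "plefka_tm1_step",
    "plefka_tm1_rates_delayed",
]

_RHO_CLIP = 1.0 - 1e-12


@dataclass(frozen=True)
class QuadratureSpec:
    """Gauss-Hermite node count for the Gaussian field averages."""

    nodes: int = 40

    def probabilists_rule(self) -> tuple[np.ndarray, np.ndarray]:
        """Nodes/weights for integrals against the standard normal measure."""
        x, w = np.polynomial.hermite.hermgauss(self.nodes)
        return x * np.sqrt(2.0), w / np.sqrt(np.pi)


@dataclass
class GaussianFieldStats:
    """Mean ``g``, variance ``Delta`` and correlation ``rho`` of the
    Gaussian effective fields."""

    g: np.ndarray
    Delta: np.ndarray
    rho: np.ndarray


def gaussian_field_stats(
    m_prev: np.ndarray, params: ModelParameters
) -> GaussianFieldStats:
    """Moments of the effective fields under independent previous spins.

    Where ``Delta_i = 0`` the field is deterministic; off-diagonal
    correlations involving such units are set to 0 by convention.
    """
    m_prev = np.asarray(m_prev, dtype=float)
    if m_prev.shape != (params.N,):
        raise ValueError("m_prev has wrong dimension")
    J = params.J
    a_l = 1.0 - m_prev**2
    g = params.H + J @ m_prev
    Delta = (J**2) @ a_l
    cov = (J * a_l[None, :]) @ J.T
    sd = np.sqrt(Delta)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = cov / np.outer(sd, sd)
    rho[~np.isfinite(rho)] = 0.0
    np.fill_diagonal(rho, np.where(Delta > 0, 1.0, 0.0))
    return GaussianFieldStats(g=g, Delta=Delta, rho=np.clip(rho, -1.0, 1.0))


def gauss_expect(
    kind: str,
    mean: float | np.ndarray,
    var: float | np.ndarray,
    quad: QuadratureSpec = QuadratureSpec(),
) -> float | np.ndarray:
    """Gaussian expectation of tanh-type integrands.

    ``kind`` is ``"tanh"`` or ``"tanh_sq"``; computes
    ``int Dx f(mean + x sqrt(var))`` with Dx the standard normal measure.
    ``var = 0`` returns ``f(mean)`` exactly.  Broadcasts over arrays.
    """
    f = {"tanh": np.tanh, "tanh_sq": lambda u: np.tanh(u) ** 2}[kind]
    mean = np.asarray(mean, dtype=float)
    var = np.asarray(var, dtype=float)
    if (var < 0).any():
        raise ValueError("variance must be nonnegative")
    x, w = quad.probabilists_rule()
    vals = f(mean[..., None] + x * np.sqrt(var)[..., None]) @ w
    return vals if vals.ndim else float(vals)


def _bivariate_tanh_expect(
    g: np.ndarray,
    sd: np.ndarray,
    rho: np.ndarray,
    pairs: tuple[np.ndarray, np.ndarray],
    quad: QuadratureSpec,
) -> np.ndarray:
    """E[tanh(g_i + x sd_i) tanh(g_k + y sd_k)] under correlated normals.

    Vectorised over the index pairs; uses y = rho x + sqrt(1-rho^2) z
    with x, z independent standard normals (Cholesky of the 2x2 matrix).
    """
    x, w = quad.probabilists_rule()
    ii, kk = pairs
    r = np.clip(rho[ii, kk], -_RHO_CLIP, _RHO_CLIP)[:, None, None]
    X = x[None, :, None]
    Z = x[None, None, :]
    Y = r * X + np.sqrt(1.0 - r**2) * Z
    ti = np.tanh(g[ii, None, None] + sd[ii, None, None] * X)
    tk = np.tanh(g[kk, None, None] + sd[kk, None, None] * Y)
    return np.einsum("pxz,x,z->p", ti * tk, w, w)


def plefka_tm1_rates_delayed(
    m_prev: np.ndarray,
    C_prev: np.ndarray,
    params: ModelParameters,
    quad: QuadratureSpec = QuadratureSpec(),
) -> tuple[np.ndarray, np.ndarray]:
    """Rates and delayed covariance only (univariate integrals).

    Skips the bivariate equal-time quadrature; used where ``C_t`` is not
    needed, e.g. inside inverse-learning iterations.
    """
    stats = gaussian_field_stats(m_prev, params)
    C_prev = np.asarray(C_prev, dtype=float)
    m = gauss_expect("tanh", stats.g, stats.Delta, quad)
    suscept = 1.0 - gauss_expect("tanh_sq", stats.g, stats.Delta, quad)
    D = suscept[:, None] * (params.J @ C_prev)
    return m, D


def plefka_tm1_step(
    m_prev: np.ndarray,
    C_prev: np.ndarray,
    params: ModelParameters,
    quad: QuadratureSpec = QuadratureSpec(),
) -> MomentState:
    """One Plefka[t-1] first-order update of (m, C, D).

    ``m_i = <tanh>`` under the unit-i Gaussian field; ``C_ik`` couples the
    two fields through rho_ik; ``D_il = (sum_j J_ij C_jl,prev) <1-tanh^2>_i``.
    """
    stats = gaussian_field_stats(m_prev, params)
    C_prev = np.asarray(C_prev, dtype=float)
    g, Delta, rho = stats.g, stats.Delta, stats.rho
    sd = np.sqrt(Delta)
    m = gauss_expect("tanh", g, Delta, quad)
    if not np.isfinite(m).all():
        raise RuntimeError("quadrature produced non-finite rates")
    N = params.N
    C = np.zeros((N, N))
    iu = np.triu_indices(N, k=1)
    if iu[0].size:
        Ett = _bivariate_tanh_expect(g, sd, rho, iu, quad)
        C[iu] = Ett - m[iu[0]] * m[iu[1]]
        C = C + C.T
    np.fill_diagonal(C, 1.0 - m**2)
    suscept = 1.0 - gauss_expect("tanh_sq", g, Delta, quad)
    D = suscept[:, None] * (params.J @ C_prev)
    return MomentState(t=-1, m=m, C=C, D=D)
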