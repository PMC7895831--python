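"""Asymmetric Sherrington-Kirkpatrick (SK) disorder ensemble.

Instances are drawn with fields ``H_i ~ U(-beta*H0, beta*H0)`` and
couplings ``J_ij ~ N(beta*J0/N, beta^2*Jsigma^2/N)`` with no
symmetrisation (defaults H0 = 0.5, J0 = 1, Jsigma = 0.1).  Because the
inverse temperature beta multiplies the sampled parameters, rescaling a
beta = 1 instance by beta is distributionally identical to sampling at
beta — so one pinned instance can be swept across temperatures with
shared disorder.  Self-couplings J_ii are sampled like any other entry
unless ``zero_diag`` is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import ModelParameters

__all__ = ["SKEnsembleSpec", "sample_sk", "rescale"]


@dataclass(frozen=True)
class SKEnsembleSpec:
    """Size, inverse temperature and disorder scales of one SK ensemble."""

    N: int
    beta: float = 1.0
    H0: float = 0.5
    J0: float = 1.0
    Jsigma: float = 0.1

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.beta < 0 or self.H0 < 0 or self.Jsigma < 0:
            raise ValueError("beta, H0 and Jsigma must be nonnegative")


def sample_sk(
    spec: SKEnsembleSpec, seed: int, zero_diag: bool = False
) -> ModelParameters:
    """Draw one asymmetric SK instance; deterministic per seed."""
    rng = np.random.default_rng(seed)
    N, beta = spec.N, spec.beta
    H = rng.uniform(-beta * spec.H0, beta * spec.H0, size=N)
    J = rng.normal(beta * spec.J0 / N, beta * spec.Jsigma / np.sqrt(N), size=(N, N))
    if beta == 0:
        H = np.zeros(N)
        J = np.zeros((N, N))
    if zero_diag:
        J = J.copy()
        np.fill_diagonal(J, 0.0)
    return ModelParameters(H=H, J=J)


def rescale(params: ModelParameters, beta_tilde: float) -> ModelParameters:
    """Multiply fields and couplings by a (fictitious) inverse temperature."""
    if beta_tilde < 0:
        raise ValueError("beta_tilde must be nonnegative")
    return ModelParameters(H=beta_tilde * params.H, J=beta_tilde * params.J)
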