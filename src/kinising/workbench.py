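"""Experiment orchestration: method comparisons with squared-error metrics.

The error metrics follow the field's convention for comparing a
prediction (superscript p) with the original model (superscript o):

    eps_m = << (m^o - m^p)^2 >_i >_t        (rates)
    eps_C = << (C^o - C^p)^2 >_{i != k} >_t (equal-time covariances)
    eps_D = << (D^o - D^p)^2 >_{il} >_t     (delayed covariances)
    eps_H = < (H^o - H^p)^2 >_i,  eps_J = < (J^o - J^p)^2 >_ij

Ground truth comes from trajectory sampling, or from exact enumeration
when the network is small enough.  Time averages run over t = 1..T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (
    ExactDistribution,
    ModelParameters,
    MomentSeries,
    exact_moment_series,
    sample_trajectories,
)
from .forward import ALL_METHODS, run_forward, sampled_moments
from .inverse_learning import LearningConfig, fit, pool_statistics
from .mf_gaussian import QuadratureSpec
from .mf_independent import SolverOptions
from .sk_ensemble import SKEnsembleSpec, rescale, sample_sk

__all__ = [
    "ExperimentConfig",
    "forward_errors",
    "parameter_errors",
    "compare_forward",
    "compare_inverse",
]

#: Desk-scale defaults; the full published protocol (N = 512, R = 10^6,
#: 21 temperatures) is available as the ``paper_scale`` preset.
DESK_SCALE = dict(N=64, R=10_000, T=128)
PAPER_SCALE = dict(N=512, R=1_000_000, T=128)


@dataclass
class ExperimentConfig:
    """Settings for one comparison experiment over methods and betas."""

    spec: SKEnsembleSpec
    T: int = 128
    R: int = 10_000
    betas: tuple = (1.0,)
    methods: tuple = ALL_METHODS
    seed: int = 0
    exact_truth: bool = False  # enumeration oracle instead of sampling
    solver: SolverOptions = field(default_factory=SolverOptions)
    quad: QuadratureSpec = field(default_factory=QuadratureSpec)

    def __post_init__(self):
        if not self.methods or not self.betas:
            raise ValueError("methods and betas must be non-empty")


def forward_errors(
    truth: MomentSeries, pred: MomentSeries, t_start: int = 1
) -> dict[str, float]:
    """Time- and unit-averaged squared errors of (m, C, D).

    C is averaged over off-diagonal pairs only; averages run over
    t = t_start..T.
    """
    N = truth.N
    off = ~np.eye(N, dtype=bool)
    sl = slice(t_start, None)
    return {
        "eps_m": float(((truth.m[sl] - pred.m[sl]) ** 2).mean()),
        "eps_C": float(((truth.C[sl][:, off] - pred.C[sl][:, off]) ** 2).mean()),
        "eps_D": float(((truth.D[sl] - pred.D[sl]) ** 2).mean()),
    }


def parameter_errors(
    true: ModelParameters, fitted: ModelParameters
) -> dict[str, float]:
    """Mean squared errors of inferred fields and couplings."""
    return {
        "eps_H": float(((true.H - fitted.H) ** 2).mean()),
        "eps_J": float(((true.J - fitted.J) ** 2).mean()),
    }


def _ground_truth(
    params: ModelParameters, cfg: ExperimentConfig, seed: int
) -> MomentSeries:
    if cfg.exact_truth:
        p0 = ExactDistribution.point_mass(np.ones(params.N, dtype=np.int8))
        return exact_moment_series(params, p0, cfg.T)
    return sampled_moments(params, cfg.T, cfg.R, seed)


def compare_forward(cfg: ExperimentConfig, base_seed: int | None = None) -> pd.DataFrame:
    """Forward-problem error table over betas and methods.

    One disorder instance is drawn at beta = 1 and rescaled to every
    beta, so all temperatures share disorder; each method is rolled out
    from the all-ones start and scored against the ground truth.
    """
    base = sample_sk(
        SKEnsembleSpec(
            N=cfg.spec.N, beta=1.0, H0=cfg.spec.H0,
            J0=cfg.spec.J0, Jsigma=cfg.spec.Jsigma,
        ),
        seed=cfg.seed if base_seed is None else base_seed,
    )
    rows = []
    for i, beta in enumerate(cfg.betas):
        params = rescale(base, float(beta))
        truth = _ground_truth(params, cfg, cfg.seed + 1000 + i)
        for method in cfg.methods:
            pred = run_forward(
                method, params, cfg.T, opts=cfg.solver, quad=cfg.quad
            )
            row = {"beta": float(beta), "method": method}
            row.update(forward_errors(truth, pred))
            rows.append(row)
    return pd.DataFrame(rows)


def compare_inverse(cfg: ExperimentConfig, learning: LearningConfig | None = None) -> pd.DataFrame:
    """Inverse-problem error table (eps_H, eps_J) over betas and methods."""
    base = sample_sk(
        SKEnsembleSpec(
            N=cfg.spec.N, beta=1.0, H0=cfg.spec.H0,
            J0=cfg.spec.J0, Jsigma=cfg.spec.Jsigma,
        ),
        seed=cfg.seed,
    )
    rows = []
    for i, beta in enumerate(cfg.betas):
        params = rescale(base, float(beta))
        ens = sample_trajectories(
            params, np.ones(params.N, dtype=np.int8), cfg.T, cfg.R,
            seed=cfg.seed + 2000 + i,
        )
        stats = pool_statistics(ens)
        for method in cfg.methods:
            config = LearningConfig(
                method=method,
                max_iter=learning.max_iter if learning else 10_000,
                grad_tol=learning.grad_tol if learning else 1e-6,
            )
            fitted, _ = fit(stats, config)
            row = {"beta": float(beta), "method": method}
            row.update(parameter_errors(params, fitted))
            rows.append(row)
    return pd.DataFrame(rows)
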