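"""Unified forward rollout across every mean-field method.

Thin dispatch layer so that experiment drivers (method comparisons,
temperature scans, reconstruction) can treat all approximations — and
the trajectory sampler used as ground truth — uniformly.
"""

from __future__ import annotations

import numpy as np

from .core_model import (
    ModelParameters,
    MomentSeries,
    empirical_moments,
    sample_trajectories,
)
from .mf_gaussian import QuadratureSpec, plefka_tm1_step
from .mf_independent import FORWARD_METHODS, SolverOptions, rollout
from .mf_pairwise import plefka2_rollout

__all__ = ["ALL_METHODS", "run_forward", "sampled_moments"]

ALL_METHODS = FORWARD_METHODS + ("plefka_tm1", "plefka2_t")


def run_forward(
    method: str,
    params: ModelParameters,
    T: int,
    m0: np.ndarray | None = None,
    C0: np.ndarray | None = None,
    D0: np.ndarray | None = None,
    opts: SolverOptions = SolverOptions(),
    quad: QuadratureSpec = QuadratureSpec(),
) -> MomentSeries:
    """Roll the chosen approximation forward T steps.

    ``m0`` defaults to the all-ones start with ``C0 = D0 = 0``.
    """
    N = params.N
    m0 = np.ones(N) if m0 is None else np.asarray(m0, dtype=float)
    if method in FORWARD_METHODS:
        return rollout(method, params, m0, C0, D0, T, opts)
    if method == "plefka2_t":
        return plefka2_rollout(params, m0, C0, D0, T, opts)
    if method == "plefka_tm1":
        C = np.zeros((N, N)) if C0 is None else np.asarray(C0, dtype=float)
        D = np.zeros((N, N)) if D0 is None else np.asarray(D0, dtype=float)
        series = MomentSeries.empty(T, N)
        series.m[0], series.C[0], series.D[0] = m0, C, D
        m = m0
        for t in range(1, T + 1):
            state = plefka_tm1_step(m, C, params, quad)
            series.m[t], series.C[t], series.D[t] = state.m, state.C, state.D
            m, C = state.m, state.C
        return series
    raise ValueError(f"unknown method {method!r}; choose from {ALL_METHODS}")


def sampled_moments(
    params: ModelParameters, T: int, R: int, seed: int, s0: np.ndarray | None = None
) -> MomentSeries:
    """Monte-Carlo ground truth: sample R trajectories and take moments."""
    s0 = np.ones(params.N, dtype=np.int8) if s0 is None else s0
    ens = sample_trajectories(params, s0, T, R, seed)
    return empirical_moments(ens)
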