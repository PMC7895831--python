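# Methods

## Model

The kinetic Ising model is a discrete-time Markov chain over `N` binary
spins `s_i ∈ {−1, +1}` with parallel updates: conditioned on the full
configuration at `t−1`, the spins at `t` are independent with

    P(s_{i,t} | s_{t−1}) = exp(s_{i,t} h_{i,t}) / (2 cosh h_{i,t}),
    h_{i,t} = H_i + Σ_j J_ij s_{j,t−1}.

`H_i` (dimensionless local field) biases unit `i`; `J_ij` couples unit
`i` at time `t` to unit `j` at `t−1` and need not be symmetric.
Asymmetry makes the chain irreversible: the stationary state is a
non-equilibrium steady state with positive entropy production.

The statistics tracked throughout are the activation rates
`m_{i,t} = <s_{i,t}>`, the equal-time covariances
`C_{ik,t} = <s_i s_k>_t − m_i m_k` and the delayed covariances
`D_{il,t} = <s_{i,t} s_{l,t−1}> − m_{i,t} m_{l,t−1}`.  `m` and `D` are
sufficient statistics for maximum-likelihood inference of `(H, J)`.

Conventions fixed across the package: spins are strictly `{−1, +1}`
(loaders reject `{0, 1}` rasters unless conversion is requested);
`t = 0` is the initial condition and statistics are defined for
`t ≥ 1`; state enumeration uses a little-endian bitmask with
`bit i = (s_i + 1)/2`; the diagonal of every returned `C` is set to
`1 − m²`, which is exact for binary spins.

## Exact layer

For `N ≤ 16` the marginal distribution is propagated exactly
(`evolve_exact`), chunking over previous states so memory stays below
roughly a gigabyte; the dense transition matrix and the stationary
one-step joint are limited to `N ≤ 12` for the same reason.  Moments of
the propagated distribution exploit the conditional independence of
spins at `t` (no `2^N × 2^N` object is ever formed for moments).  The
stationary distribution comes from power iteration to an L1 residual
below `1e−13`; a test cross-checks it against the leading eigenvector
of the transition matrix.  This layer is the oracle that validates every
approximation.

## The mean-field family

All approximations derive from expansions around tractable reference
models and differ in what the reference preserves:

* **nMF** (`nmf`): `m = tanh(H + J m_prev)`; `C` diagonal;
  `D_il = J_il (1−m_i²)(1−m_l²)`.  First order; cheapest.
* **TAP** (`tap`): adds the Onsager reaction term, making the rate
  equation self-consistent: `m_i = tanh(H_i + Σ_j J_ij m_j −
  m_i Σ_j J_ij² (1−m_j²))`.  Second order.
* **Plefka[t]** (`plefka_t1`, `plefka_t2`): conditions on the previous
  covariance `C_{t−1}`.  The second order generalises TAP's reaction
  coefficient to the quadratic form `Σ_jl J_ij J_il C_jl` and transports
  covariances as `C_t = (1−m²)(1−m²) J C_{t−1} Jᵀ` off-diagonal.  With
  `C_{t−1} = diag(1−m²)` it reduces exactly to TAP (tested to 1e−10).
* **Plefka[t−1]** (`plefka_tm1`): treats the effective field as Gaussian
  with mean `H + J m_prev`, variance `Δ_i = Σ_j J_ij²(1−m_j²)` and
  pair correlation `ρ_ik`; rates and susceptibilities are univariate
  Gaussian averages of `tanh`, equal-time covariances bivariate ones.
  Exact for fully asymmetric networks in the thermodynamic limit.  Only
  the first order is implemented; the second order's cost is not
  justified by its accuracy.  The printed form of the pair-correlation
  and bivariate-integral expressions indexes one variance inconsistently
  (`Δ_j` where the pair index `k` is expected); we read both as `Δ_k`,
  consistent with the symmetry of `C`.
* **Plefka2[t]** (`plefka2_t`): the pairwise reference.  For each
  ordered pair the reference distribution keeps one coupling — `(i,t)`
  with `(l,t−1)` for delayed covariances, `(i,t)` with `(k,t)` for
  equal-time ones — and reduces everything else to independent
  marginals.  Each pair yields implicit scalar equations
  `θ = a − b·tanh(θ)` whose linear term carries the direct coupling plus
  an indirect term mediated by `D_{t−1}`, and whose reaction term
  excludes the conditioned unit.  Means and covariances follow by
  averaging over the conditioning spin under its reference marginal.

### Plefka2[t] design choices

The pairwise equations leave three genuinely open choices, resolved as
follows.  (1) Each pair produces its own estimate of `m_{i,t}`; the
rollout uses the average over conditioning units `l`, which is symmetric
and collapses to the common value when pairs agree (they do at `J = 0`;
the spread is available as a diagnostic).  (2) The conditioning unit's
reference parameter `Θ_{l,t−1}` is computed TAP-style from the `t−2`
statistics, as the second-order equations prescribe; at the first step
after a known initial state it is `arctanh(m_0)` (clamped), the exact
projection of that state.  Inside a pair, the conditioning unit's rate
is `tanh Θ*` everywhere for internal consistency, while background
units use the recursion's previous rates; the two differ only beyond
the expansion's order.  (3) In the delayed equations the index
restriction on the double sums is read as: `j ≠ l` with `n`
unrestricted in the `D`-mediated term, and both `j ≠ l` and `n ≠ l` in
the variance correction — the conditioned unit must not appear in its
own reaction term.

### Numerical choices

Self-consistent equations are solved by fixed-point iteration (plain,
then damped at 0.5 on retry) to residual `1e−12`; remaining failures
fall back to bracketed root finding — `brentq` for the vector TAP-type
equations, vectorised bisection for the pairwise scalar equations,
whose form `x = a − b tanh x` is monotone with a unique root whenever
`b > −1`.  Gaussian integrals use Gauss–Hermite quadrature with 40
nodes (doubling the nodes moves results by far less than `1e−8` at the
ensemble's field-variance scale); bivariate integrals use
tensor-product nodes after a Cholesky transform, with `ρ` clipped to
`±(1 − 1e−12)`.  Zero-variance fields bypass quadrature.

### Stability near criticality

At the critical point the equal-time covariance recursion of
Plefka[t] second order has uniform-mode gain `(βJ0 ⟨1−m²⟩)² ≈ 1`; it is
marginally unstable, which at large `N` appears as the well-known
overestimation of correlations and at `N ≲ 100` can grow into outright
divergence within ~100 steps (the growing covariance feeds the reaction
term, suppresses the rates, and raises the gain).  This is a property
of the truncated equations, not of the implementation — the one-step
update with exact inputs is accurate.  The pairwise method does not
share this failure mode at the sizes we test.

## Inverse problem

Parameters are fitted by gradient ascent on the exact log-likelihood,

    ℓ = Σ_{t,r,i} ( S_{i,t} h_{i,t} − log 2 cosh h_{i,t} ),

whose gradients are moment mismatches: `<S_i> − m_i` for fields,
`<S_i S_l,prev> − (D_il + m_i m̃_l)` for couplings, with the model-side
`(m, D)` conditioned on the pooled empirical previous-step distribution.
`method="exact"` evaluates them on the pooled configurations (cost
proportional to the sample count); the mean-field methods produce them
in one shot from the pooled moments `(m̃, C̃, D̃)`, making the
per-iteration cost independent of the data volume.  Learning is pooled
over trials and times (one stationary parameter set), starts from
`H = J = 0` with effective step sizes `0.1` on field mismatches and
`1/√N` on coupling mismatches, and stops when the max-norm mismatch
falls below `grad_tol` (default `1e−6`) or at `max_iter` (default
`10⁴`) — the stopping rule is this package's choice.  No regularisation
is applied.

## Entropy production

Irreversibility is quantified as the KL divergence rate between forward
and time-reversed path probabilities.  `entropy_production_exact`
evaluates it on the exact stationary joint (small `N`); at a steady
state it reduces to `σ = Σ_ij (J_ij − J_ji) D_ij`
(`entropy_production_mf`), which vanishes identically for symmetric
couplings.  The reduction is verified numerically to `1e−8`.  The
mean-field form assumes a steady-state `D`; callers pass a rollout tail
or the exact stationary covariance.

## The asymmetric SK ensemble and its critical point

Disorder instances draw `H_i ~ U(−βH0, βH0)` and
`J_ij ~ N(βJ0/N, β²Jσ²/N)` with defaults `H0 = 0.5, J0 = 1, Jσ = 0.1`
and no symmetrisation.  Because `β` multiplies the parameters,
rescaling a `β = 1` draw is distributionally identical to sampling at
`β`, so temperature sweeps share disorder.  Self-couplings are sampled
like any other entry (a flag zeroes them).

In the thermodynamic limit the stationary state is described by the
population-averaged magnetisation `m̄` and squared magnetisation `q`.
Because couplings are fully asymmetric, the coupling-disorder noise in
the effective field acts on ±1 spins (unit second moment): the total
Gaussian smear around `H + βJ0 m̄` is `Δ_total = β²Jσ²` — the static
site-to-site dispersion `β²Jσ² q` of `Σ_j J_ij m_j` plus the dynamic
part `β²Jσ²(1−q)`.  The ferromagnetic critical point is where the
`m̄ = 0` branch loses stability,

    β J0 ⟨∫Dx sech²(H + x βJσ)⟩_H = 1,

located by bisection to `1e−10` with Gauss–Legendre (64 nodes) over the
field interval nested with Gauss–Hermite (40 nodes) — fully
deterministic, no disorder sampling.  With the default ensemble this
gives `β_c = 1.1108`; removing the disorder (`H0 = 0, Jσ → 0`) recovers
the Curie–Weiss condition `βJ0 = 1` exactly.  Keeping the `(1−q)`
factor alone in the smear (i.e. ignoring the static dispersion) would
instead give `β_c ≈ 1.1097`; the total-variance form is the one
consistent with the dynamical treatment of fully asymmetric couplings.

## Synthetic data and what the tests show

All experiments regenerate their data from the SK sampler and the
trajectory sampler; no external datasets are used.  The generator
reproduces the ensemble's stated parameter distributions and the
all-ones initial condition of the forward protocol.  It does not emulate
features of real recordings — subsampling, measurement noise, slow
nonstationarity of parameters, or non-binary activity — so passing
tests demonstrate correctness of the methods on the model class, not
robustness to those artefacts.

Desk-scale problem sizes are used throughout the suite: `N = 64`,
`R = 10⁴`, `T = 128` for forward comparisons (the published protocol at
`N = 512`, `R = 10⁶` is available as a preset), `N ≤ 8` for everything
involving exact enumeration, and a 13-point temperature grid with six
disorder realisations for the fluctuation-peak experiment.  At `N = 64`
the fluctuation maximum sits slightly above the thermodynamic-limit
`β_c` (the disorder-averaged peak lands at the +10% grid point):
finite-size trial-splitting between the two ferromagnetic basins
inflates across-trial covariances above the transition, an effect that
recedes with system size.

## Known limitations

* Parallel (synchronous) discrete-time dynamics only; no asynchronous
  Glauber updates or continuous time.
* Exact computations are guarded at `N = 16` (forward) and `N = 12`
  (stationary); beyond that only approximations and sampling apply.
* Plefka[t] second order can diverge near criticality at moderate `N`
  (see above); Plefka[t−1] is first order only; pairwise references
  with more than two units are not implemented.
* Inference assumes stationary parameters pooled over time; no
  regularisation paths or model selection.
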