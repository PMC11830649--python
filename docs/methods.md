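# Methods

## Model and scope

rfekit works with conservative first-order (unimolecular) kinetics on a
finite state set: `dn/dt = A n` with nonnegative off-diagonal rates and
zero column sums.  Rates are stored in the column convention
`A[i, j] = λ_{j→i}` so that the ODE reads without a transpose; the JSON
interchange format stores the edge list `(from, to, rate)` explicitly so
the orientation cannot be misread.  Bimolecular or Michaelis–Menten
kinetics are outside the linear reduction; the two nonlinear worked models
(feed-forward loop, nonlinear polymerization) treat the nonlinearity at the
level of the response functional instead.

Given a partition of the states into compartments, the package computes
the exact waiting-time kernels of the reduced renewal system from the
blocks of A, analyses them, and solves the reduced equations numerically.
All kernel-level quantities that admit closed forms (total masses, first
moments, Laplace transforms) are evaluated through resolvents of the
compartment blocks rather than by quadrature whenever the kernels were
derived from a network ("ode" provenance).  Purely tabulated kernels are
supported everywhere with quadrature fallbacks; the provenance is carried
on the `KernelFamily` object, and analyses dispatch on it.

## Numerical choices

**Kernel tabulation.**  One scaling-and-squaring matrix exponential per
compartment block and per grid; the time series is generated by repeated
multiplication with `exp(dt·A_αα)`, which is exact on the uniform grid by
the semigroup property.  Kernel values at t = 0 come from the closed form
(`G(0) = A_{αβ}`), never from extrapolation.

**Volterra solver.**  Trapezoidal convolution quadrature on a uniform
grid.  The `s = t` endpoint makes each step implicit through
`I − (dt/2)·kernel(0)`; one dense factorization of that matrix (size
Σ|α|, or |X| in the scalar case) serves all steps.  The scheme is second
order; the ODE-equivalence tests confirm the ~4× error reduction under
step halving.  A nearly singular implicit factor (dt too large relative to
the fastest rate) is reported with the offending condition number.

**Deflated resolvents.**  Compartment blocks are sub-generators whose zero
eigenvalue (present when the block contains a trap with no outflow) is
always semisimple.  Masses and moments therefore use the null-space
projection `P0 = lim e^{tA}` built from the left and right null spaces,
plus a least-squares solve of `A Y = −(I − P0)`.  The null-space ambiguity
of `Y` is harmless: trapped states carry no outflow, so the rows through
which `Y` enters any observable annihilate it.  The retained mass
`e^T P0 e_{i_α}` is reported as the sink diagnostic.

**Improper integrals of tabulated kernels.**  Trapezoid on the grid plus a
single-exponential tail fitted to the last tenth of the samples; a
non-decaying tail is flagged rather than extrapolated.  Laplace transforms
of tabulated kernels use Simpson quadrature.

**Characteristic root and residue.**  `ρ(M(z))` is evaluated by
eigendecomposition (the matrices are |X|×|X|, so power iteration buys
nothing) and Brent-solved on a bracket; the default lower end is
`−0.9 ×` the smallest positive decay rate of the blocks, where the
transforms are still finite.  The asymptotic profile uses the residue
formula `c₀v₀ = v₀ (u₀ᵀB̂⁰(0)) / (u₀ᵀ(∫tΦ)v₀)` with the left and right
Perron vectors normalized to `u₀ᵀv₀ = 1`; `∫tΦ` and `∫B⁰` are exact
(squared resolvents, forcing resolvents) for ODE-derived inputs.  A
vanishing denominator — the pole at the origin not simple, which
irreducibility excludes — is an explicit error.  Irreducibility itself is
checked by strong connectivity of the compartment digraph induced by the
kernel masses.

**Markovianity decision.**  The characterization (exponential kernels ⇔
Markovian totals) is exact; numerics need a threshold.  The test estimates
`λ_{αβ} = Φ_{αβ}(0)` and decides by a sup-norm fit against
`λ_{αβ} e^{−Λ_α t}` at relative tolerance 1e−6 by default.  A kernel with
`Φ(0) = 0` but positive mass (any Erlang-type law) fails immediately, as
it must.

**Detailed balance.**  The equilibrium is computed from the null space of
A; a multi-dimensional null space (reducible network) is reported as a
status, never guessed around.  Reversibility is decided from the maximal
pairwise flux imbalance `|A_{ij}μ_j − A_{ji}μ_i|` at relative tolerance
1e−8.  The completely monotone decomposition symmetrizes each block with
`diag(√μ)` restricted to the block and eigendecomposes symmetrically
(`eigh`), so the weights are squared entries of an orthonormal basis and
their unit sum is structural, not numerical.

**Phase-type construction.**  The Erlangization rule assigns shape j−1 the
target's CDF increment on `((j−1)/M, j/M]` and dumps the tail mass on the
last shape — the standard constructive scheme behind the density theorem;
moment-matching or EM fitting is deliberately out of scope.  Convergence
diagnostics use the Kolmogorov–Smirnov distance (an upper bound for the
Lévy–Prokhorov metric) with Wasserstein-1 as a secondary diagnostic.  In
the full network realization the kernel measured from the entrance node
necessarily includes that node's own exponential stage, so the realized
kernel is the mixture density with every shape shifted up by one; the pair
masses `∫Ψ_{αβ} = p_{αβ}` are exact.  All mixtures leaving one compartment
must share the stage rate M, otherwise the branch probabilities at the
entrance would distort the masses — enforced with an explicit error.

**Age-structured solver.**  Time and age share one step, so transport
along characteristics is exact and the only discretization sits in the
survival exponent (trapezoid) and the renewal boundary integral
(trapezoid).  The density is stored split at the moving support front
ξ = t — cohorts born after t = 0 below, the transported initial history
above — because the density genuinely jumps there and a quadrature rule
straddling the jump would degrade the scheme to first order.  The
simultaneous boundary values of different compartments couple through the
first quadrature cell; a per-step |X|×|X| linear solve keeps that coupling
implicit.  History atoms are transported as weighted particles.  The
kernels↔rates conversions use Simpson cumulatives, and the survival
identity `e^{−∫Λ} = 1 − ∫Σ_β Φ_{αβ}` is exploited analytically wherever it
closes an integral.  The rates-from-kernels direction fails loudly
("survival exhausted") when the cumulative kernel mass reaches one inside
the grid — kernels with bounded support have no bounded-rate transport
twin.  The generalized (multi-entrance) system is handled by reduction:
every entry state becomes its own sub-compartment with vanishing internal
rates.

**Worked models.**  The proofreading analyses evaluate every printed
quantity twice — closed form versus resolvent numerics — and refuse to
return on disagreement.  The closed-form mean production time includes the
mean residence `1/λ` of the committed complex before product release.  The
`T/T̄ ≈ θ²` speed asymptotics requires the production channel ordering
`β e^{E1} ≪ α ≪ e^{E1}` on top of the scale separations
(`λ ≪ βη e^{E1}`, `α/Q ≪ β e^{E1}`, `e^{E1} ≫ 1`); with the direct
`C → S*` route dominant the ratio degrades to first order in θ.  The
feed-forward loop's limiting kernel contains a Dirac factor that is
applied analytically (a single exponential convolution multiplied by the
instantaneous signal), never discretized.  Impulse inputs are realized as
initial conditions throughout.  The nonlinear polymerization integrator
(Heun with trapezoid history convolutions) disables attachment at the
truncation size, logs the suppressed boundary flux, and conserves the
discrete size-weighted mass identically by construction.

## Synthetic data

The random network generator is the package's source of test systems.  It
draws a partition into contiguous blocks, a Hamiltonian-style ring of
rates (guaranteeing strong connectivity when requested), and uniform rates
on [0.5, 1.5]×scale, with three structural options: `single_entrance`
(cross-compartment jumps land only on designated entrance states),
`detailed_balance` (rates `λ_{i→j} = s_{ij}/μ_i` with symmetric s and a
random positive equilibrium μ, making reversibility exact by
construction), and `strongly_connected` (verified post hoc with a graph
search; draws are rejected and resampled up to a bounded retry count).
These fixtures emulate the *structure* of reduced biochemical networks —
conservativity, sparsity, entrance discipline — but not the extreme rate
separations (10⁴-fold and more) of real proofreading systems, which enter
only through the dedicated model builders.  Passing tests on these
fixtures therefore certify the reduction and the analyses, not numerical
robustness at arbitrary stiffness.

## Problem sizes and limitations

The test suite and the acceptance script run desk-scale problems: networks
of 2–10 states, grids of 10²–10⁴ nodes, horizons of a few mean waiting
times (the Volterra solver is O(n²) in the node count, the transport
solver O(n²) in time×age).  Known limitations: no adaptive stepping or
stiffness-aware convolution quadrature (grids are user-chosen); complex
Laplace arguments and oscillatory corrections to the long-time asymptotics
are out of scope (the exponential approach is verified empirically, its
constants are not estimated); measure-valued age densities are restricted
to tabulated densities plus finitely many atoms; and stochastic path
simulation of the semi-Markov process is not provided — the package works
at the level of densities and fluxes.
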