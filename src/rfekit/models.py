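"""Worked biochemical models expressed through response functions.

Ready-made builders and analyses for:

* **Hopfield–Ninio kinetic proofreading** — a substrate complex ``C``
  binds reversibly to ``S`` and (via an energy-consuming, detailed-balance
  violating step) to the phosphorylated ``S*`` that synthesizes product
  ``P``; degradation sends ``C`` to the empty state.  The response function
  ``Phi(t) = lambda S*(t)`` under a unit impulse of ``C`` summarizes the
  whole cascade; the ratio of total productions of two competing substrates
  approaches the squared equilibrium discrimination factor
  ``theta^2 = e^{-2(Ebar1 - E1)}`` in the proofreading limit.
* **Linear polymerization with proofreading** — each elongation step is
  non-Markovian with waiting density ``Psi``; iterated convolution yields a
  size-space concentration front travelling at speed ``1 / mean(Psi)``.
* **Linear adaptation** (Barkai–Leibler flavour) — a 2x2 internal module
  whose response kernel integrates to zero, so a constant stimulus produces
  a transient excursion and perfect return to baseline.
* **Coherent type-1 feed-forward loop** — the output is a *quadratic*
  functional of the signal history with a two-time kernel; it delays the
  response to signal onset but not to signal removal (sign-sensitive
  delay).
* **Nonlinear polymerization** — Becker–Döring-like growth in which monomer
  attachment completes after a non-Markovian transient, coupling the flux
  to the history of the monomer pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.linalg import expm

from .kernels import TimeGrid
from .network import (
    CompartmentNetwork,
    Partition,
    build_compartment_network,
    validate_rate_matrix,
)

# ---------------------------------------------------------------------------
# signals


@dataclass(frozen=True)
class SignalFunction:
    """A time signal with declared support, usable as chemical input."""

    fn: Callable[[np.ndarray], np.ndarray]
    support: tuple[float, float] = (-np.inf, np.inf)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.asarray(self.fn(t), dtype=float)

    @staticmethod
    def step_on(t0: float = 0.0) -> "SignalFunction":
        return SignalFunction(lambda t: (t >= t0).astype(float), (t0, np.inf))

    @staticmethod
    def step_off(t_bar: float) -> "SignalFunction":
        return SignalFunction(lambda t: (t <= t_bar).astype(float), (-np.inf, t_bar))

    @staticmethod
    def constant(value: float) -> "SignalFunction":
        return SignalFunction(lambda t: np.full_like(t, value, dtype=float))


# ---------------------------------------------------------------------------
# Hopfield proofreading


@dataclass(frozen=True)
class HopfieldParams:
    """Rates and energies of the proofreading scheme.

    ``k, alpha, beta, lam, mu, Q`` are positive rates/factors; ``E1`` is the
    binding energy of the correct substrate relative to ``C``, ``E1_bar``
    the (larger) one of the competitor; ``E2`` the energy of the
    phosphorylated complex.  The difference ``E2 - E1`` is substrate
    independent (phosphorylation happens far from the recognition site), so
    a single ``eta = e^{E2 - E1}`` serves both.  ``Q > 1`` quantifies how
    strongly the phosphorylation step breaks detailed balance.
    """

    k: float = 1.0
    alpha: float = 1e-2
    beta: float = 1e-4
    lam: float = 2e-4
    mu: float = 1e-2
    Q: float = 1e4
    e_E1: float = 2.0
    e_E2: float = 400.0
    e_E1_bar: float | None = None

    @property
    def xi(self) -> float:
        return self.e_E1

    @property
    def eta(self) -> float:
        return self.e_E2 / self.e_E1

    @property
    def theta(self) -> float:
        if self.e_E1_bar is None:
            return 1.0
        return self.e_E1 / self.e_E1_bar  # e^{-(Ebar1 - E1)}

    def barred(self) -> "HopfieldParams":
        """Parameters of the competing substrate (same eta, Ebar1 for E1)."""
        if self.e_E1_bar is None:
            raise ValueError("e_E1_bar not set")
        return HopfieldParams(
            k=self.k,
            alpha=self.alpha,
            beta=self.beta,
            lam=self.lam,
            mu=self.mu,
            Q=self.Q,
            e_E1=self.e_E1_bar,
            e_E2=self.e_E1_bar * self.eta,
            e_E1_bar=None,
        )

    @staticmethod
    def scaling_preset(eps: float = 0.01, s: float = 0.5) -> "HopfieldParams":
        """The proofreading scaling limit family.

        ``alpha = mu = eps``, ``beta = eps^2``, ``Q = eps^-2``,
        ``lambda = 2 eps^2``, ``e^{E1} = 2``, ``e^{E2} = 4 / eps^s`` and the
        competitor energies ``e^{Ebar1} = 8``, ``e^{Ebar2} = 16 / eps^s``
        (so ``lambda / eta = eps^{2+s}`` and ``theta = 1/4``).
        """
        return HopfieldParams(
            k=1.0,
            alpha=eps,
            beta=eps**2,
            lam=2.0 * eps**2,
            mu=eps,
            Q=eps**-2,
            e_E1=2.0,
            e_E2=4.0 / eps**s,
            e_E1_bar=8.0,
        )


_HOPFIELD_STATES = ("C", "S", "Sstar", "empty", "P")


def hopfield_network(p: HopfieldParams) -> CompartmentNetwork:
    """The 5-state proofreading network with partition {C,S,S*,0} | {P}."""
    k, a, b, lam, mu, Q = p.k, p.alpha, p.beta, p.lam, p.mu, p.Q
    eE1, eE2 = p.e_E1, p.e_E2
    states = _HOPFIELD_STATES
    idx = {s: i for i, s in enumerate(states)}
    A = np.zeros((5, 5))

    def add(src: str, dst: str, rate: float) -> None:
        A[idx[dst], idx[src]] += rate

    add("C", "S", k)
    add("S", "C", k * eE1)
    add("C", "Sstar", b)
    add("Sstar", "C", b * eE2)
    add("S", "Sstar", a)
    add("Sstar", "S", (a / Q) * (eE2 / eE1))
    if mu > 0:
        add("C", "empty", mu)
    if lam > 0:
        add("Sstar", "P", lam)
    np.fill_diagonal(A, -A.sum(axis=0))
    rm = validate_rate_matrix(A, states=states)
    partition = Partition(
        names=("complex", "product"),
        members=(("C", "S", "Sstar", "empty"), ("P",)),
    )
    return build_compartment_network(rm, partition)


def _core_generator(p: HopfieldParams, mu: float | None = None) -> np.ndarray:
    """3x3 sub-generator over (C, S, S*) including the losses mu and lambda."""
    k, a, b, lam, Q = p.k, p.alpha, p.beta, p.lam, p.Q
    eE1, eE2 = p.e_E1, p.e_E2
    if mu is None:
        mu = p.mu
    rev = (a / Q) * (eE2 / eE1)
    return np.array(
        [
            [-(k + b + mu), k * eE1, b * eE2],
            [k, -(k * eE1 + a), rev],
            [b, a, -(rev + b * eE2 + lam)],
        ]
    )


def hopfield_response(p: HopfieldParams, grid: TimeGrid) -> np.ndarray:
    """Response function ``Phi(t) = lambda S*(t)`` under a unit impulse of C.

    Solving the impulse problem is equivalent to integrating the network
    for ``t > 0`` from ``C(0) = 1``, ``S(0) = S*(0) = 0``.
    """
    A3 = _core_generator(p)
    P = expm(grid.dt * A3)
    x = np.array([1.0, 0.0, 0.0])
    out = np.empty(grid.n_points)
    out[0] = p.lam * x[2]
    for m in range(1, grid.n_points):
        x = P @ x
        out[m] = p.lam * x[2]
    return out


def hopfield_total_production(
    p: HopfieldParams,
    mu: float | None = None,
    t_end: float | None = None,
    n_points: int = 8001,
) -> float:
    """Total product ``lambda * int_0^inf S*`` by quadrature plus exact tail.

    The trajectory is integrated on ``[0, t_end]`` (default: several times
    the slowest relaxation time) by trapezoid; the remainder is added in
    closed form as ``lambda e_{S*}^T (-A^{-1}) x(T)``, exact because the
    tail of a linear system is again linear.
    """
    A3 = _core_generator(p, mu=mu)
    w = np.linalg.eigvals(A3)
    slowest = float(np.min(-w.real))
    if t_end is None:
        t_end = 5.0 / slowest
    grid = TimeGrid(t_end=t_end, n_points=n_points)
    P = expm(grid.dt * A3)
    xs = np.empty((grid.n_points, 3))
    xs[0] = (1.0, 0.0, 0.0)
    for m in range(1, grid.n_points):
        xs[m] = P @ xs[m - 1]
    from scipy.integrate import simpson

    body = p.lam * simpson(xs[:, 2], x=grid.nodes)
    tail = p.lam * float(np.linalg.solve(-A3, xs[-1])[2])
    return float(body + tail)


def production_ratio(p: HopfieldParams, cross_check_tol: float = 1e-8) -> float:
    """Discrimination ratio ``Pbar_inf / P_inf`` of the two substrates.

    Computed two ways and cross-checked: (a) the Laplace transform at zero
    of both impulse problems (a linear solve per substrate), (b) the closed
    form in ``theta = e^{-(Ebar1-E1)}``, ``xi = e^{E1}``,
    ``eta = e^{E2-E1}``.  The ratio always exceeds ``theta^2`` and
    approaches it in the proofreading limit.
    """
    pbar = p.barred()
    num = _p_infinity(pbar)
    den = _p_infinity(p)
    ratio_numeric = num / den

    # the closed form is written in the time unit where k = 1; rescaling all
    # rates by 1/k changes neither total productions nor their ratio
    a, b, lam, mu, Q = (p.alpha / p.k, p.beta / p.k, p.lam / p.k,
                        p.mu / p.k, p.Q)
    th, xi, eta = p.theta, p.xi, p.eta
    mid = (b + mu) * lam / (mu * b * eta) + a / (b * Q) + a
    last = (1 + b + mu) * a * lam / (mu * b * eta)
    ratio_closed = (
        th**2
        * (1 + b + b * xi / (a * th))
        / (1 + b + b * xi / a)
        * (xi**2 + xi * mid + last)
        / (xi**2 + th * xi * mid + th**2 * last)
    )
    if abs(ratio_numeric - ratio_closed) > cross_check_tol * abs(ratio_numeric):
        raise RuntimeError(
            f"closed-form/numeric production ratios disagree: "
            f"{ratio_closed:.12g} vs {ratio_numeric:.12g}"
        )
    return float(ratio_numeric)


def _p_infinity(p: HopfieldParams) -> float:
    """Total production ``P_inf = lambda * Shat*(0)`` for one substrate."""
    A3 = _core_generator(p)
    x = np.linalg.solve(-A3, np.array([1.0, 0.0, 0.0]))
    return p.lam * float(x[2])


def mean_production_time(p: HopfieldParams, cross_check_tol: float = 1e-6) -> float:
    """Mean time to produce P in the degradation-free system (mu = 0).

    Without degradation every impulse eventually makes product
    (``int Phi = 1``), so the first moment of ``Phi`` is the mean production
    time; it equals ``Chat(0) + Shat(0) + Shat*(0)``.  Both the printed
    closed form and the numeric moment ``lambda e_{S*}^T A^{-2} e_C`` are
    evaluated and cross-checked.
    """
    A3 = _core_generator(p, mu=0.0)
    e1 = np.array([1.0, 0.0, 0.0])
    # int t Phi = lam * [A^{-2}]_{S*, C}; A^{-2} e1 via two solves
    y = np.linalg.solve(A3, np.linalg.solve(A3, e1))
    T_numeric = p.lam * float(y[2])

    k, a, b, lam, Q = p.k, p.alpha, p.beta, p.lam, p.Q
    eE1 = p.e_E1
    eta = p.eta
    # rational closed form of Chat(0) + Shat(0) + Shat*(0); the final 1/lam
    # is the mean residence of the committed complex in S* before release
    T_closed = (
        (lam + b * eta * eE1) * (k * eE1 + a)
        + (a / Q) * eta * k * eE1
        + (k + b) * (a * eta / Q)
        + k * (lam + b * eta * eE1)
    ) / (lam * (b * k * eE1 + a * k + a * b)) + 1.0 / lam
    if abs(T_numeric - T_closed) > cross_check_tol * abs(T_closed):
        raise RuntimeError(
            f"closed-form/numeric mean production times disagree: "
            f"{T_closed:.10g} vs {T_numeric:.10g}"
        )
    return float(T_numeric)


# ---------------------------------------------------------------------------
# linear polymerization


@dataclass
class PolymerizationResult:
    grid: TimeGrid
    n: np.ndarray  # (L_max, n_points): n_ell(t), ell = 1..L_max
    I: np.ndarray  # fluxes I_ell(t)
    mean_step: float
    front_times: np.ndarray  # first time n_ell exceeds half its plateau
    front_speed: float


def linear_polymerization(
    psi: np.ndarray,
    L_max: int,
    grid: TimeGrid,
    I1: SignalFunction | np.ndarray | None = None,
) -> PolymerizationResult:
    """Iterated-convolution solution of the linear growth chain.

    ``I_ell = psi * I_{ell-1}`` (trapezoid convolution), sizes by
    integration of ``I_ell - I_{ell+1}``.  With a unit monomer flux the size
    distribution develops a front ``n_ell ~ mu * 1[t > ell mu]`` travelling
    at speed ``1/mu``, ``mu = int s psi(s) ds``.
    """
    t = grid.nodes
    dt = grid.dt
    psi = np.asarray(psi, dtype=float)
    mass = float(np.trapezoid(psi, t))
    if abs(mass - 1.0) > 1e-3:
        raise ValueError(f"psi must integrate to 1 on the grid (got {mass:.4g})")
    mu = float(np.trapezoid(t * psi, t))
    if I1 is None:
        I1 = np.ones_like(t)
    elif isinstance(I1, SignalFunction):
        I1 = I1(t)
    else:
        I1 = np.asarray(I1, dtype=float)

    n_pts = grid.n_points
    I = np.zeros((L_max + 1, n_pts))
    I[0] = I1  # I_1 stored at row 0
    for ell in range(1, L_max + 1):
        I[ell] = _conv(psi, I[ell - 1], dt)
    from scipy.integrate import cumulative_trapezoid

    n = np.zeros((L_max, n_pts))
    for ell in range(L_max):
        n[ell] = cumulative_trapezoid(I[ell] - I[ell + 1], t, initial=0.0)

    front_times = np.full(L_max, np.nan)
    for ell in range(L_max):
        above = n[ell] > 0.5 * mu
        if above.any():
            front_times[ell] = t[int(np.argmax(above))]
    # speed from the deepest resolved front
    ells = np.arange(1, L_max + 1)
    okm = ~np.isnan(front_times)
    speed = float(ells[okm][-1] / front_times[okm][-1]) if okm.any() else np.nan
    return PolymerizationResult(
        grid=grid, n=n, I=I, mean_step=mu, front_times=front_times,
        front_speed=speed,
    )


def _conv(k: np.ndarray, x: np.ndarray, dt: float) -> np.ndarray:
    n = len(x)
    out = np.zeros(n)
    for m in range(1, n):
        acc = 0.5 * dt * (k[m] * x[0] + k[0] * x[m])
        if m > 1:
            acc += dt * np.dot(k[m - 1:0:-1], x[1:m])
        out[m] = acc
    return out


# ---------------------------------------------------------------------------
# adaptation


@dataclass(frozen=True)
class AdaptationKernel:
    """Closed-form zero-mean response kernel of the adaptation module.

    ``Phi(t) = C_+ e^{lambda_+ t} + C_- e^{lambda_- t}`` with
    ``lambda_± = (-b ± sqrt(b^2 - 4a)) / 2``; ``Phi(0) = b`` and
    ``int_0^inf Phi = 0`` (the signature of perfect adaptation).
    """

    a: float
    b: float
    lam_plus: float
    lam_minus: float
    C_plus: float
    C_minus: float

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.C_plus * np.exp(self.lam_plus * t) + self.C_minus * np.exp(
            self.lam_minus * t
        )

    @property
    def integral(self) -> float:
        """Analytic total integral ``C_+/|lambda_+| + C_-/|lambda_-|``."""
        return self.C_plus / (-self.lam_plus) + self.C_minus / (-self.lam_minus)


def adaptation_response(a: float, b: float) -> AdaptationKernel:
    """Kernel of the 2x2 adaptation module ``[[-b, a], [-1, 0]]``.

    Requires ``b^2 > 4a`` (overdamped, two real decay rates).
    """
    if not (a > 0 and b > 0):
        raise ValueError("a, b must be positive")
    disc = b * b - 4.0 * a
    if disc <= 0:
        raise ValueError("need b^2 > 4a for two real decay rates")
    root = np.sqrt(disc)
    lam_p = 0.5 * (-b + root)
    lam_m = 0.5 * (-b - root)
    C_p = b * lam_p / root
    C_m = -b * lam_m / root
    return AdaptationKernel(
        a=a, b=b, lam_plus=lam_p, lam_minus=lam_m, C_plus=C_p, C_minus=C_m
    )


def adaptation_output(
    kernel: AdaptationKernel, s: SignalFunction, grid: TimeGrid
) -> np.ndarray:
    """Receptor activity ``X(t) = 1 + (1/b) int_0^t Phi(v) (s(t-v) - b) dv``.

    If ``s`` tends to a constant the output returns to the setpoint 1.
    """
    t = grid.nodes
    phi = kernel(t)
    sv = s(t)
    shifted = (sv - kernel.b)
    out = np.empty_like(t)
    for m in range(len(t)):
        v = t[: m + 1]
        out[m] = 1.0 + np.trapezoid(phi[: m + 1] * shifted[m::-1], v) / kernel.b
    return out


# ---------------------------------------------------------------------------
# coherent type-1 feed-forward loop


def c1ffl_kernel(a: float, b: float, c: float, eta, xi) -> np.ndarray:
    """Two-time kernel ``K(eta, xi)`` of the C1FFL output.

    Closed-form evaluation of
    ``K = int_{-min(eta,xi)}^0 e^{(c-2a)s} e^{-a(xi+eta)}
    (1 - e^{-(b-a)(xi+s)})/(b-a) ds``; the parameters must avoid the
    resonances ``c = 2a`` and ``c = a + b`` (handled by a tiny shift).
    """
    eta = np.asarray(eta, dtype=float)
    xi = np.asarray(xi, dtype=float)
    m = np.minimum(eta, xi)
    p = c - 2.0 * a
    q = c - a - b
    if abs(p) < 1e-9:
        p = 1e-9
    if abs(q) < 1e-9:
        q = 1e-9
    term1 = (1.0 - np.exp(-p * m)) / p
    term2 = np.exp(-(b - a) * xi) * (1.0 - np.exp(-q * m)) / q
    return np.exp(-a * (xi + eta)) * (term1 - term2) / (b - a)


@dataclass
class C1FFLResult:
    grid: TimeGrid
    Z_ode: np.ndarray
    Z_kernel: np.ndarray
    X: np.ndarray
    Y: np.ndarray


def c1ffl_response(
    a: float, b: float, c: float, S: SignalFunction, grid: TimeGrid
) -> C1FFLResult:
    """Output of the feed-forward loop, by ODE cascade and by double kernel.

    The ODE route integrates ``X' = S - aX``, ``Y' = X - bY``,
    ``Z' = XY - cZ`` (exact exponential stepping of each linear stage); the
    kernel route evaluates the quadratic functional
    ``Z(t) = double-int K(t-v, t-w) S(v) S(w)`` with the closed-form
    ``K``.  Signals are assumed to vanish before ``t = 0``.
    """
    t = grid.nodes
    dt = grid.dt
    sv = S(t)
    # exact exponential integrators for the linear cascade stages
    X = _lowpass(sv, a, dt)
    Y = _lowpass(X, b, dt)
    Z = _lowpass(X * Y, c, dt)

    # kernel route: Z(t_m) = sum_{v,w <= t_m} K(t_m - v, t_m - w) S(v) S(w)
    Zk = np.zeros_like(t)
    for m in range(1, grid.n_points):
        tau = t[m] - t[: m + 1]
        Kmat = c1ffl_kernel(a, b, c, tau[:, None], tau[None, :])
        wts = np.ones(m + 1)
        wts[0] = wts[-1] = 0.5
        Zk[m] = dt * dt * float(wts @ (Kmat * np.outer(sv[: m + 1], sv[: m + 1])) @ wts)
    return C1FFLResult(grid=grid, Z_ode=Z, Z_kernel=Zk, X=X, Y=Y)


def _lowpass(u: np.ndarray, rate: float, dt: float) -> np.ndarray:
    """Exact exponential step for ``x' = u - rate x`` with x(0)=0, u piecewise linear."""
    n = len(u)
    x = np.zeros(n)
    ed = np.exp(-rate * dt)
    # integral of e^{-rate(dt-s)} * linear interpolant of u over one step
    c0 = (ed - 1.0 + rate * dt) / (rate * rate * dt)  # weight of u_{m}
    c1 = (1.0 - ed - rate * dt * ed) / (rate * rate * dt)  # weight of u_{m-1}
    for m in range(1, n):
        x[m] = ed * x[m - 1] + c1 * u[m - 1] + c0 * u[m]
    return x


def c1ffl_limit_response(S_bar: SignalFunction, grid: TimeGrid) -> np.ndarray:
    """Rescaled output ``xi(tau) = Sbar(tau) int_{-inf}^tau e^{-(tau-s)} Sbar(s) ds``.

    The fast-activation limit of the loop: the Dirac factor of the limiting
    two-time kernel is applied analytically, leaving a single exponential
    convolution multiplied by the instantaneous signal.  A step-on signal
    saturates at 1 over times of order one; a step-off signal drops to 0
    immediately.
    """
    t = grid.nodes
    sv = S_bar(t)
    # contribution of the signal's past on (-inf, 0]
    lo, _ = S_bar.support
    conv = np.zeros_like(t)
    if lo == -np.inf:
        # signal constant-in-the-past: int_{-inf}^0 e^{-(t-s)} Sbar(s) ds
        past = float(S_bar(np.array([-1.0]))[0])
        conv += past * np.exp(-t)
    # on-grid part, exact exponential stepping
    conv += _lowpass_exp(sv, grid.dt)
    return sv * conv


def _lowpass_exp(u: np.ndarray, dt: float) -> np.ndarray:
    """Exact ``int_0^t e^{-(t-s)} u(s) ds`` for piecewise-linear u."""
    return _lowpass(u, 1.0, dt)


# ---------------------------------------------------------------------------
# nonlinear polymerization


@dataclass
class NonlinearPolymerizationResult:
    grid: TimeGrid
    n1: np.ndarray
    n: np.ndarray  # (L_max, n_points) sizes 1..L_max (row 0 duplicates n1)
    w: np.ndarray  # (L_max + 1, n_points) intermediates, index = size
    mass_residual: float
    boundary_flux: float


def nonlinear_polymerization(
    psi: np.ndarray,
    S: SignalFunction | np.ndarray,
    L_max: int,
    grid: TimeGrid,
) -> NonlinearPolymerizationResult:
    """Becker–Döring-like growth with a non-Markovian attachment transient.

    Monomer attachment to a size-``(l-1)`` polymer first forms an
    intermediate ``w_l`` which matures into a size-``l`` polymer with
    waiting density ``psi``; the maturation flux is the history convolution
    ``I_l(t) = int psi(t-s) n1(s) n_{l-1}(s) ds``.  Spontaneous monomer
    shedding (rate 1) closes the loop.  Integration: Heun (explicit
    trapezoidal) stepping with trapezoid convolutions over the stored
    history.  Attachment is disabled at ``l = L_max`` (absorbing last size);
    the would-be flux past the boundary is accumulated and reported.

    Mass accounting: ``sum_l l n_l + sum_l l w_l`` grows exactly at the rate
    of the monomer source ``S``; the discrete residual is returned.
    """
    t = grid.nodes
    dt = grid.dt
    psi = np.asarray(psi, dtype=float)
    sv = S(t) if isinstance(S, SignalFunction) else np.asarray(S, dtype=float)
    n_pts = grid.n_points

    n = np.zeros((L_max + 1, n_pts))  # n[l] for sizes 1..L_max at index l
    w = np.zeros((L_max + 2, n_pts))
    prod = np.zeros((L_max + 1, n_pts))  # history n1 * n_{l-1} feeding w_l

    def fluxes(m: int) -> np.ndarray:
        """I_l(t_m) for l = 2..L_max via trapezoid over stored history."""
        out = np.zeros(L_max + 1)
        for l in range(2, L_max + 1):
            h = prod[l, : m + 1]
            if m >= 1:
                out[l] = np.trapezoid(psi[m::-1] * h, t[: m + 1])
        return out

    def rhs(m: int, n_cur: np.ndarray, I: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dn = np.zeros(L_max + 1)
        dw = np.zeros(L_max + 2)
        n1 = n_cur[1]
        # polymers l >= 2
        for l in range(2, L_max + 1):
            attach = n1 * n_cur[l] if l < L_max else 0.0
            shed_in = n_cur[l + 1] if l + 1 <= L_max else 0.0
            dn[l] = -attach + shed_in - n_cur[l] + I[l]
            dw[l] = n1 * n_cur[l - 1] - I[l]
        # monomers
        attach_sum = sum(n1 * n_cur[l] for l in range(2, L_max))
        shed_sum = sum(n_cur[l + 1] for l in range(2, L_max + 1) if l + 1 <= L_max)
        dn[1] = 2.0 * n_cur[2] - attach_sum - 2.0 * n1 * n1 + shed_sum + sv[m]
        return dn, dw

    boundary = 0.0
    for m in range(n_pts - 1):
        n_cur = n[:, m]
        I = fluxes(m)
        dn, dw = rhs(m, n_cur, I)
        # predictor
        n_pred = np.clip(n_cur + dt * dn, 0.0, None)
        prod[:, m + 1] = 0.0
        for l in range(2, L_max + 1):
            prod[l, m + 1] = n_pred[1] * n_pred[l - 1]
        I2 = fluxes(m + 1)
        dn2, dw2 = rhs(m + 1, n_pred, I2)
        n[:, m + 1] = np.clip(n_cur + 0.5 * dt * (dn + dn2), 0.0, None)
        w[: L_max + 2, m + 1] = w[: L_max + 2, m] + 0.5 * dt * (dw + dw2)
        for l in range(2, L_max + 1):
            prod[l, m + 1] = n[1, m + 1] * n[l - 1, m + 1]
        boundary += dt * n[1, m] * n[L_max, m]  # suppressed attachment flux

    sizes = np.arange(L_max + 1)
    total = sizes @ n + np.arange(L_max + 2) @ w
    from scipy.integrate import cumulative_trapezoid

    injected = cumulative_trapezoid(sv, t, initial=0.0)
    mass_residual = float(np.abs((total - total[0]) - injected).max())
    return NonlinearPolymerizationResult(
        grid=grid,
        n1=n[1],
        n=n[1:],
        w=w,
        mass_residual=mass_residual,
        boundary_flux=boundary,
    )
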