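"""Age-structured (transport) reformulation of the renewal system.

The scalar renewal equations have a Markovian twin: a structured-population
transport PDE in the residence age ``xi`` (time since entering the current
compartment),

    d_t f_a(t, xi) + d_xi f_a(t, xi) = -Lambda_a(xi) f_a(t, xi),
    f_a(t, 0) = sum_{b != a} int lambda_{b a}(xi) f_b(t, xi) dxi,

with age-dependent jump rates ``lambda_{ab}(xi)`` and total exit rate
``Lambda_a = sum_b lambda_{ab}``.  The two formalisms interconvert:

* rates -> kernels:  ``Phi_{ab}(t) = lambda_{ab}(t) exp(-int_0^t Lambda_a)``
  (:func:`kernels_from_rates`);
* kernels -> rates:  ``lambda_{ab}(t) = Phi_{ab}(t) / (1 - int_0^t k_a)``
  (:func:`rates_from_kernels`), defined while the survival probability in
  the denominator stays positive;
* a past-occupancy history ``m_a`` on negative times generates the renewal
  forcing by convolution (:func:`forcing_from_history`).

The solver transports along characteristics on a shared step ``h = dt =
dxi`` so the advection is exact (no numerical diffusion); only the survival
exponent and the boundary integral are quadratures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_simpson, cumulative_trapezoid

from .kernels import ForcingSet, KernelFamily, TimeGrid


class AgeStructureError(RuntimeError):
    pass


@dataclass
class AgeRates:
    """Tabulated age-dependent jump rates ``lambda_{ab}(xi)`` on a grid.

    ``rates[(a, b)]`` holds samples on ``grid.nodes`` (interpreted as the
    age axis).  Rates must be nonnegative and bounded; the maximum is
    reported by :meth:`bound`.
    """

    grid: TimeGrid
    compartments: tuple[str, ...]
    rates: dict[tuple[str, str], np.ndarray]

    def __post_init__(self) -> None:
        for key, lam in self.rates.items():
            lam = np.asarray(lam, dtype=float)
            if lam.shape != (self.grid.n_points,):
                raise ValueError(f"rate {key} has shape {lam.shape}")
            if np.any(lam < -1e-12):
                raise ValueError(f"rate {key} has negative entries")
            self.rates[key] = np.clip(lam, 0.0, None)

    def Lambda(self, a: str) -> np.ndarray:
        out = np.zeros(self.grid.n_points)
        for (x, _), lam in self.rates.items():
            if x == a:
                out = out + lam
        return out

    def bound(self) -> float:
        return max((float(v.max()) for v in self.rates.values()), default=0.0)


@dataclass
class History:
    """Past occupancy of one compartment, as a measure on ages ``xi >= 0``.

    ``density[j]`` is the occupancy density at age ``xi_j`` (i.e. at time
    ``-xi_j``); ``point_masses`` is a list of ``(age, weight)`` atoms.  An
    atom at age 0 encodes "everything entered exactly at t = 0".
    """

    density: np.ndarray | None = None
    point_masses: tuple[tuple[float, float], ...] = ()


@dataclass
class AgeDensity:
    """Solution of the transport system on an aligned (t, xi) lattice.

    The density is stored split at the moving support front ``xi = t``:
    ``f_born[a][m, j]`` (valid for ``j <= m``) holds the cohorts that
    entered after time zero, ``f_hist[a][m, j]`` (valid for ``j >= m``) the
    transported initial history.  Both are genuinely smooth on their side of
    the front, so trapezoid quadrature stays second order; summing the two
    arrays reproduces the full density for inspection.  Transported history
    atoms are tracked as particles with decayed weights.
    """

    t_grid: TimeGrid
    xi_nodes: np.ndarray
    compartments: tuple[str, ...]
    f_born: dict[str, np.ndarray]
    f_hist: dict[str, np.ndarray]
    particle_ages: dict[str, np.ndarray] = field(default_factory=dict)
    particle_weights: dict[str, np.ndarray] = field(default_factory=dict)
    # particle_weights[a][m, p]: weight of atom p of compartment a at t_m

    def density(self, a: str) -> np.ndarray:
        """Full (born + history) density table; the front node is the
        left limit of the born part."""
        return self.f_born[a] + self.f_hist[a]


def aggregate(sol: AgeDensity) -> dict[str, np.ndarray]:
    """Per-compartment totals ``N_a(t) = int f_a(t, dxi)``.

    Trapezoid on each side of the support front plus the transported
    point-mass weights.
    """
    out: dict[str, np.ndarray] = {}
    xi = sol.xi_nodes
    n_t = sol.t_grid.n_points
    for a in sol.compartments:
        N = np.empty(n_t)
        born, hist = sol.f_born[a], sol.f_hist[a]
        for m in range(n_t):
            acc = 0.0
            if m >= 1:
                acc += np.trapezoid(born[m, : m + 1], xi[: m + 1])
            acc += np.trapezoid(hist[m, m:], xi[m:])
            N[m] = acc
        if a in sol.particle_weights and sol.particle_weights[a].size:
            N = N + sol.particle_weights[a].sum(axis=1)
        out[a] = N
    return out


def _interp_rate(lam: np.ndarray, grid: TimeGrid, xi: np.ndarray) -> np.ndarray:
    return np.interp(xi, grid.nodes, lam, left=lam[0], right=lam[-1])


def spe_solve(
    rates: AgeRates,
    histories: dict[str, History],
    t_grid: TimeGrid,
) -> AgeDensity:
    """March the transport system along characteristics.

    Requires the time step to equal the age step of the rate tabulation
    (characteristics then pass exactly through lattice points, so advection
    is exact).  The one-step survival factor uses a trapezoid in the
    exponent; the renewal boundary value integrates the inflow by trapezoid
    on each side of the support front, plus atom contributions.
    """
    h = t_grid.dt
    if abs(h - rates.grid.dt) > 1e-12 * max(h, rates.grid.dt):
        raise AgeStructureError(
            f"time step {h:g} must equal the age step {rates.grid.dt:g}"
        )
    comps = rates.compartments
    n_t = t_grid.n_points

    # age axis: history support + simulated horizon
    max_hist = 0.0
    for a in comps:
        hist = histories.get(a, History())
        if hist.density is not None:
            max_hist = max(max_hist, rates.grid.t_end)
        for age, _ in hist.point_masses:
            max_hist = max(max_hist, age)
    n_xi = int(np.ceil((max_hist + t_grid.t_end) / h)) + 2
    xi = np.arange(n_xi) * h

    Lam = {a: _interp_rate(rates.Lambda(a), rates.grid, xi) for a in comps}
    lam_x = {
        key: _interp_rate(v, rates.grid, xi) for key, v in rates.rates.items()
    }
    # one-step survival along the characteristic from xi_j to xi_{j+1}
    surv = {a: np.exp(-0.5 * h * (Lam[a][:-1] + Lam[a][1:])) for a in comps}

    born = {a: np.zeros((n_t, n_xi)) for a in comps}
    histf = {a: np.zeros((n_t, n_xi)) for a in comps}
    p_ages: dict[str, np.ndarray] = {}
    p_w: dict[str, np.ndarray] = {}
    cumLam = {a: cumulative_trapezoid(Lam[a], xi, initial=0.0) for a in comps}
    for a in comps:
        hist = histories.get(a, History())
        if hist.density is not None:
            dens = np.asarray(hist.density, dtype=float)
            if dens.shape != (rates.grid.n_points,):
                raise ValueError(
                    f"history density of {a!r} must sit on the rate grid"
                )
            m0 = np.interp(xi, rates.grid.nodes, dens, right=0.0)
            histf[a][0] = m0 * np.exp(-cumLam[a])
        ages = np.array([age for age, _ in hist.point_masses])
        w0 = np.array([w for _, w in hist.point_masses])
        # initial decay over the atom's age already spent in the compartment
        decay = np.exp(-np.interp(ages, xi, cumLam[a]))
        p_ages[a] = ages
        p_w[a] = np.zeros((n_t, len(ages)))
        if len(ages):
            p_w[a][0] = w0 * decay

    def boundary_rhs(a: str, m: int) -> float:
        """Inflow to ``a`` at t_m, with the simultaneous boundary values of
        the source compartments (node xi = 0) left out — they enter through
        the per-step coupling solve below."""
        inflow = 0.0
        for b in comps:
            if b == a or (b, a) not in lam_x:
                continue
            lam = lam_x[(b, a)]
            if m >= 1:
                w = lam[: m + 1] * born[b][m, : m + 1]
                w[0] = 0.0
                inflow += np.trapezoid(w, xi[: m + 1])
            inflow += np.trapezoid(lam[m:] * histf[b][m, m:], xi[m:])
            if p_ages[b].size:
                cur = p_ages[b] + m * h
                inflow += float(np.sum(p_w[b][m] * np.interp(cur, xi, lam)))
        return inflow

    # coupling of the simultaneous boundary values through the first
    # trapezoid cell: inflow_a += (h/2) lam_{ba}(0) * born_b(t, 0)
    nC = len(comps)
    W = np.zeros((nC, nC))
    for bi, b in enumerate(comps):
        for ai, a in enumerate(comps):
            if a != b and (b, a) in lam_x:
                W[ai, bi] = 0.5 * h * lam_x[(b, a)][0]
    IW = np.linalg.inv(np.eye(nC) - W)

    for ai, a in enumerate(comps):
        born[a][0, 0] = boundary_rhs(a, 0)
    for m in range(1, n_t):
        # transport both parts and the atoms
        for a in comps:
            born[a][m, 1:] = born[a][m - 1, :-1] * surv[a]
            histf[a][m, 1:] = histf[a][m - 1, :-1] * surv[a]
            if p_ages[a].size:
                cur = p_ages[a] + (m - 1) * h
                step_surv = np.exp(
                    -0.5 * h * (
                        np.interp(cur, xi, Lam[a])
                        + np.interp(cur + h, xi, Lam[a])
                    )
                )
                p_w[a][m] = p_w[a][m - 1] * step_surv
        r = np.array([boundary_rhs(a, m) for a in comps])
        x = IW @ r
        for ai, a in enumerate(comps):
            born[a][m, 0] = x[ai]

    return AgeDensity(
        t_grid=t_grid,
        xi_nodes=xi,
        compartments=comps,
        f_born=born,
        f_hist=histf,
        particle_ages=p_ages,
        particle_weights=p_w,
    )


def kernels_from_rates(rates: AgeRates) -> KernelFamily:
    """Waiting-time kernels induced by age-dependent rates.

    ``Phi_{ab}(t) = lambda_{ab}(t) S_a(t)`` with the survival function
    ``S_a(t) = exp(-int_0^t Lambda_a)`` (Simpson in the exponent), and
    ``k_a = Lambda_a S_a``.  The identity ``S_a(t) = 1 - int_0^t k_a`` is
    asserted internally: the cumulative kernel mass is computed through the
    survival function, for which the relation is exact.
    """
    grid = rates.grid
    t = grid.nodes
    Phi: dict[tuple[str, str], np.ndarray] = {}
    k: dict[str, np.ndarray] = {}
    for a in rates.compartments:
        Lam = rates.Lambda(a)
        I = cumulative_simpson(Lam, x=t, initial=0.0)
        S = np.exp(-I)
        k[a] = Lam * S
        # survival identity: S = 1 - int k  (exact through the exponent)
        mass = 1.0 - S
        recon = cumulative_simpson(k[a], x=t, initial=0.0)
        if np.abs(mass - recon).max() > 1e-4:
            raise AgeStructureError(
                "survival identity violated beyond quadrature error; "
                "refine the age grid"
            )
        for b in rates.compartments:
            if b == a or (a, b) not in rates.rates:
                continue
            Phi[(a, b)] = rates.rates[(a, b)] * S
    return KernelFamily.from_scalar(grid, rates.compartments, Phi, k)


def rates_from_kernels(fam: KernelFamily, floor: float = 1e-8) -> AgeRates:
    """Recover age-dependent rates from scalar kernels.

    ``lambda_{ab}(t) = Phi_{ab}(t) / (1 - int_0^t sum_g Phi_{ag})``.  The
    denominator is the survival probability; when it falls below ``floor``
    anywhere on the grid the conversion fails with "survival exhausted"
    (the rates would be unbounded — e.g. kernels of bounded support).

    Round trip: ``kernels_from_rates(rates_from_kernels(fam))`` reproduces
    the kernels to quadrature accuracy (Simpson; ~1e-8 on smooth kernels
    over fine grids).
    """
    if not fam.has_scalar:
        raise ValueError("scalar kernels required")
    grid = fam.grid
    t = grid.nodes
    out: dict[tuple[str, str], np.ndarray] = {}
    for a in fam.compartments:
        ka = np.zeros(grid.n_points)
        for b in fam.compartments:
            if b != a and (a, b) in fam.Phi:
                ka = ka + fam.Phi[(a, b)]
        denom = 1.0 - cumulative_simpson(ka, x=t, initial=0.0)
        if np.any(denom < floor):
            j = int(np.argmax(denom < floor))
            raise AgeStructureError(
                f"survival exhausted for compartment {a!r} at t = {t[j]:.4g} "
                f"(denominator {denom[j]:.3g} < floor {floor:g})"
            )
        for b in fam.compartments:
            if b != a and (a, b) in fam.Phi:
                out[(a, b)] = fam.Phi[(a, b)] / denom
    return AgeRates(grid=grid, compartments=fam.compartments, rates=out)


def forcing_from_history(
    fam: KernelFamily, histories: dict[str, History]
) -> ForcingSet:
    """Renewal forcing generated by past occupancies.

    ``B0_a(t) = sum_b int Phi_{ba}(t + u) m_b(du)`` over ages ``u >= 0``
    (the history measure lives on negative times), and similarly
    ``D0_a(t) = int k_a(t + u) m_a(du)``.  Kernels are extended by zero
    beyond the grid (histories should be truncated where the kernels have
    decayed).
    """
    grid = fam.grid
    t = grid.nodes
    n = grid.n_points
    comps = fam.compartments

    def conv(kernel: np.ndarray, hist: History) -> np.ndarray:
        out = np.zeros(n)
        if hist.density is not None:
            dens = np.asarray(hist.density, dtype=float)
            # sum over ages u on the same grid: kernel(t + u) * dens(u)
            for m in range(n):
                shifted = np.interp(t[m] + t, t, kernel, right=0.0)
                out[m] = np.trapezoid(shifted * dens, t)
        for age, w in hist.point_masses:
            out += w * np.interp(t + age, t, kernel, right=0.0)
        return out

    B0: dict[str, np.ndarray] = {}
    D0: dict[str, np.ndarray] = {}
    N0: dict[str, float] = {}
    for a in comps:
        b0 = np.zeros(n)
        for b in comps:
            if b == a or (b, a) not in fam.Phi:
                continue
            hist = histories.get(b)
            if hist is None:
                continue
            b0 += conv(fam.Phi[(b, a)], hist)
        B0[a] = b0
        hist = histories.get(a, History())
        D0[a] = conv(fam.k.get(a, np.zeros(n)), hist)
        mass = 0.0
        if hist.density is not None:
            # survival of the history up to time 0 is the caller's business;
            # N0 counts what is present at t = 0
            mass += float(np.trapezoid(hist.density, t))
        mass += sum(w for _, w in hist.point_masses)
        N0[a] = mass
    return ForcingSet.from_scalar(grid, comps, B0, D0, N0)


def generalized_rates(
    mu: dict[tuple[str, str], np.ndarray],
    compartment_of: dict[str, str],
    grid: TimeGrid,
) -> AgeRates:
    """Reduce the generalized (per entry-state) system to the scalar one.

    In the generalized transport system the unknown is indexed by pairs
    (compartment, entry state); it is a special case of the scalar system in
    which every entry state is its own sub-compartment and sub-compartments
    of the same parent are not connected.  ``mu[(i, j)]`` is the
    age-dependent rate of jumping from entry state ``i`` to entry state
    ``j``; pairs within one parent compartment must be absent (or zero).
    The returned :class:`AgeRates` treats each state as a compartment;
    aggregate the solved densities with :func:`aggregate` and sum states per
    parent via ``compartment_of``.
    """
    states = tuple(sorted(compartment_of))
    rates: dict[tuple[str, str], np.ndarray] = {}
    for (i, j), lam in mu.items():
        lam = np.asarray(lam, dtype=float)
        if compartment_of[i] == compartment_of[j]:
            if np.any(lam != 0):
                raise AgeStructureError(
                    f"states {i!r}, {j!r} share a compartment; internal "
                    "rates must vanish in the generalized reduction"
                )
            continue
        rates[(i, j)] = lam
    return AgeRates(grid=grid, compartments=states, rates=rates)


@dataclass
class VectorHistory:
    """Past occupancy of one compartment, per entry state.

    ``ages``/``density`` tabulate a density over ages (``density`` has shape
    ``(len(ages), |compartment|)``); ``atoms`` is a list of
    ``(age, weight_vector)`` point masses.
    """

    ages: np.ndarray | None = None
    density: np.ndarray | None = None
    atoms: tuple[tuple[float, np.ndarray], ...] = ()


def admissible_history(
    net, n0, histories: dict[str, VectorHistory], rtol: float = 1e-6
) -> tuple[bool, float]:
    """Check whether a candidate history reproduces the ODE initial state.

    A history ``m_b`` is admissible when
    ``n^0_b = int e^{-xi A_{bb}} m_b(dxi)`` over ages: the occupancy that
    entered at time ``-xi``, evolved through the compartment block and
    survived until ``t = 0`` must add up to the prescribed initial state.
    The integral is evaluated by eigen-propagation (trapezoid over the
    density table plus the atoms).  Returns ``(admissible, residual)`` with
    the residual in the max norm.
    """
    if isinstance(n0, dict):
        n0 = np.array([n0.get(s, 0.0) for s in net.states], dtype=float)
    else:
        n0 = np.asarray(n0, dtype=float)
    resid = 0.0
    scale = max(float(np.abs(n0).max()), 1e-30)
    for b in net.compartments:
        ib = net.state_indices(b)
        target = n0[ib]
        Abb = net.block(b, b)
        w, V = np.linalg.eig(Abb)
        Vi = np.linalg.inv(V)

        def propagate(age: float, vec: np.ndarray) -> np.ndarray:
            # e^{-age * A_bb} vec ; A_bb has nonpositive spectrum so the
            # factor grows with age — admissibility is a genuine constraint
            return (V @ (np.exp(-age * w) * (Vi @ vec))).real

        hist = histories.get(b, VectorHistory())
        acc = np.zeros(len(ib))
        if hist.density is not None:
            ages = np.asarray(hist.ages, dtype=float)
            dens = np.atleast_2d(np.asarray(hist.density, dtype=float))
            if dens.shape != (len(ages), len(ib)):
                raise ValueError(
                    f"history density of {b!r} must have shape "
                    f"({len(ages)}, {len(ib)})"
                )
            vals = np.stack([propagate(x, dens[j]) for j, x in enumerate(ages)])
            acc = acc + np.trapezoid(vals, ages, axis=0)
        for age, vec in hist.atoms:
            acc = acc + propagate(float(age), np.asarray(vec, dtype=float))
        resid = max(resid, float(np.abs(acc - target).max()))
    return resid <= rtol * scale, resid
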