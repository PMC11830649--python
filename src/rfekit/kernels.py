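"""Response kernels and forcing functions of the compartment reduction.

Reducing ``dn/dt = A n`` over a partition ``X`` replaces the Markovian state
dynamics by a renewal (Volterra) system for the per-compartment influx and
outflux histories.  The data of that system are matrix-valued kernels

    G_{beta alpha}(t) = A_{alpha beta} exp(t A_{beta beta})      (influx)
    K_alpha(t)        = C_alpha exp(t A_{alpha alpha})           (outflux)

and forcing functions built from the initial state,

    S^0_alpha(t) = sum_{beta != alpha} G_{beta alpha}(t) n^0_beta,
    J^0_alpha(t) = K_alpha(t) n^0_alpha.

When every compartment has at most one entrance point the system collapses
to scalar renewal equations with waiting-time densities
``Phi_{alpha beta}(t) = (A_{beta alpha} e^{t A_{alpha alpha}})_{i_beta, i_alpha}``
(the probability density of the time an element entering ``alpha`` at its
entrance state needs to exit towards ``beta``) and total exit densities
``k_alpha = sum_beta Phi_{alpha beta}``.

Kernels derived from a network carry their generator (``provenance="ode"``),
so time-integrals and Laplace transforms are evaluated exactly through
resolvent formulas rather than quadrature.  Purely tabulated kernels are
supported everywhere with quadrature fallbacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .network import CompartmentNetwork


@dataclass(frozen=True)
class TimeGrid:
    """Uniform closed grid ``t_m = m * dt`` on ``[0, t_end]``."""

    t_end: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("need at least two grid points")
        if not self.t_end > 0:
            raise ValueError("t_end must be positive")

    @property
    def dt(self) -> float:
        return self.t_end / (self.n_points - 1)

    @property
    def nodes(self) -> np.ndarray:
        return np.linspace(0.0, self.t_end, self.n_points)


@dataclass
class KernelFamily:
    """Matrix (and optionally scalar) response kernels on a time grid.

    ``G[(src, dst)]`` has shape ``(n_points, |dst|, |src|)`` and tabulates
    ``G_{src,dst}(t) = A_{dst,src} e^{t A_{src,src}}``; ``K[alpha]`` has shape
    ``(n_points, |alpha|, |alpha|)``.  ``Phi[(alpha, beta)]`` and
    ``k[alpha]`` are scalar sequences, populated only for single-entrance
    partitions.  ``provenance`` is ``"ode"`` (with ``net`` set) or
    ``"tabulated"``.
    """

    grid: TimeGrid
    compartments: tuple[str, ...]
    G: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    K: dict[str, np.ndarray] = field(default_factory=dict)
    Phi: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    k: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: str = "tabulated"
    net: CompartmentNetwork | None = None
    entrances: dict[str, str | None] = field(default_factory=dict)

    @property
    def has_scalar(self) -> bool:
        return bool(self.Phi) or bool(self.k)

    def phi(self, alpha: str, beta: str) -> np.ndarray:
        """Scalar kernel Phi_{alpha beta} (zeros when absent)."""
        if (alpha, beta) in self.Phi:
            return self.Phi[(alpha, beta)]
        return np.zeros(self.grid.n_points)

    @classmethod
    def from_scalar(
        cls,
        grid: TimeGrid,
        compartments: tuple[str, ...] | list[str],
        Phi: dict[tuple[str, str], np.ndarray],
        k: dict[str, np.ndarray] | None = None,
    ) -> "KernelFamily":
        """Build a tabulated family from scalar kernels only.

        When ``k`` is omitted it is synthesized as the row sum
        ``k_alpha = sum_beta Phi_{alpha beta}``.
        """
        compartments = tuple(compartments)
        Phi = {key: np.asarray(v, dtype=float) for key, v in Phi.items()}
        for key, v in Phi.items():
            if v.shape != (grid.n_points,):
                raise ValueError(f"kernel {key} has shape {v.shape}")
            if np.any(v < -1e-12):
                raise ValueError(f"kernel {key} has negative entries")
        if k is None:
            k = {}
            for a in compartments:
                ka = np.zeros(grid.n_points)
                for b in compartments:
                    if b != a and (a, b) in Phi:
                        ka = ka + Phi[(a, b)]
                k[a] = ka
        return cls(
            grid=grid,
            compartments=compartments,
            Phi=Phi,
            k={a: np.asarray(v, dtype=float) for a, v in k.items()},
            provenance="tabulated",
        )


def _propagators(net: CompartmentNetwork, grid: TimeGrid) -> dict[str, np.ndarray]:
    """Per-compartment semigroup samples ``exp(t_m A_{aa})``.

    One scaling-and-squaring ``expm`` per block; the series is generated by
    repeated multiplication with ``exp(dt A_{aa})``, which is exact on the
    grid by the semigroup property.
    """
    out: dict[str, np.ndarray] = {}
    for a in net.compartments:
        Aaa = net.block(a, a)
        na = Aaa.shape[0]
        P = expm(grid.dt * Aaa)
        series = np.empty((grid.n_points, na, na))
        series[0] = np.eye(na)
        for m in range(1, grid.n_points):
            series[m] = P @ series[m - 1]
        out[a] = series
    return out


def grfe_kernels(net: CompartmentNetwork, grid: TimeGrid) -> KernelFamily:
    """Matrix kernels ``G_{beta alpha}`` and ``K_alpha`` of the reduction."""
    prop = _propagators(net, grid)
    G: dict[tuple[str, str], np.ndarray] = {}
    K: dict[str, np.ndarray] = {}
    for src in net.compartments:
        E = prop[src]
        for dst in net.compartments:
            if dst == src:
                continue
            Ab = net.block(dst, src)
            if np.all(Ab == 0):
                G[(src, dst)] = np.zeros((grid.n_points, Ab.shape[0], Ab.shape[1]))
            else:
                G[(src, dst)] = np.einsum("ij,mjk->mik", Ab, E)
        Ca = net.C[src]
        K[src] = np.einsum("ij,mjk->mik", Ca, E)
    fam = KernelFamily(
        grid=grid,
        compartments=net.compartments,
        G=G,
        K=K,
        provenance="ode",
        net=net,
    )
    return fam


@dataclass
class ForcingSet:
    """Transient forcing of the renewal system from an initial state.

    ``S0[alpha]`` / ``J0[alpha]`` have shape ``(n_points, |alpha|)``;
    ``B0``/``D0`` are their scalar (single-entrance) counterparts; ``N0``
    holds the initial compartment totals.
    """

    grid: TimeGrid
    compartments: tuple[str, ...]
    S0: dict[str, np.ndarray] = field(default_factory=dict)
    J0: dict[str, np.ndarray] = field(default_factory=dict)
    B0: dict[str, np.ndarray] = field(default_factory=dict)
    D0: dict[str, np.ndarray] = field(default_factory=dict)
    N0: dict[str, float] = field(default_factory=dict)
    net: "CompartmentNetwork | None" = None
    n0: np.ndarray | None = None

    @classmethod
    def from_scalar(
        cls,
        grid: TimeGrid,
        compartments: tuple[str, ...] | list[str],
        B0: dict[str, np.ndarray],
        D0: dict[str, np.ndarray],
        N0: dict[str, float],
    ) -> "ForcingSet":
        compartments = tuple(compartments)
        return cls(
            grid=grid,
            compartments=compartments,
            B0={a: np.asarray(v, dtype=float) for a, v in B0.items()},
            D0={a: np.asarray(v, dtype=float) for a, v in D0.items()},
            N0=dict(N0),
        )


def grfe_forcing(
    net: CompartmentNetwork, n0, grid: TimeGrid, kernels: KernelFamily | None = None
) -> ForcingSet:
    """Forcing functions ``S^0, J^0`` induced by an initial state ``n0``.

    ``n0`` is indexed by the network's states (array or mapping).  Scalar
    forms ``B0``/``D0`` are also filled when the partition is
    single-entrance.
    """
    if isinstance(n0, dict):
        n0 = np.array([n0.get(s, 0.0) for s in net.states], dtype=float)
    else:
        n0 = np.asarray(n0, dtype=float)
    if n0.shape != (len(net.states),):
        raise ValueError("n0 must be indexed by the network states")
    if np.any(n0 < 0):
        raise ValueError("n0 entries must be nonnegative")
    if kernels is None:
        kernels = grfe_kernels(net, grid)
    S0: dict[str, np.ndarray] = {}
    J0: dict[str, np.ndarray] = {}
    N0: dict[str, float] = {}
    n0_by = {a: n0[net.state_indices(a)] for a in net.compartments}
    for a in net.compartments:
        na = len(net.partition[a])
        s0 = np.zeros((grid.n_points, na))
        for b in net.compartments:
            if b == a:
                continue
            s0 += kernels.G[(b, a)] @ n0_by[b]
        S0[a] = s0
        J0[a] = kernels.K[a] @ n0_by[a]
        N0[a] = float(n0_by[a].sum())
    f = ForcingSet(
        grid=grid, compartments=net.compartments, S0=S0, J0=J0, N0=N0,
        net=net, n0=n0,
    )
    # scalar reduction when applicable
    try:
        ent = net.single_entrance()
    except Exception:
        return f
    part = net.partition
    for a in net.compartments:
        ia = ent[a]
        if ia is None:
            f.B0[a] = np.zeros(grid.n_points)
        else:
            f.B0[a] = S0[a][:, part[a].index(ia)]
        f.D0[a] = J0[a].sum(axis=1)
    return f


def scalar_kernels(
    net: CompartmentNetwork,
    grid: TimeGrid,
    entrances: dict[str, str] | None = None,
) -> KernelFamily:
    """Scalar waiting-time kernels for a single-entrance partition.

    ``Phi_{alpha beta}(t)`` is the density of the time an element entering
    compartment ``alpha`` (at its entrance state) takes to jump into
    ``beta``; ``k_alpha`` is the total exit density.  Compartments without
    an entrance point get identically zero kernels.  A compartment with
    several entrance points is an error unless ``entrances`` overrides the
    reference state explicitly (used e.g. to probe impulse responses of
    source compartments that nothing ever enters).
    """
    fam = grfe_kernels(net, grid)
    if entrances is None:
        ent = net.single_entrance()
    else:
        ent = {a: None for a in net.compartments}
        ent.update(entrances)
        for a, pts in net.entrance_points.items():
            if ent[a] is None and len(pts) == 1:
                ent[a] = pts[0]
    part = net.partition
    for a in net.compartments:
        ia = ent.get(a)
        if ia is None:
            fam.k[a] = np.zeros(grid.n_points)
            continue
        ja = part[a].index(ia)
        fam.k[a] = fam.K[a][:, :, ja].sum(axis=1)
        for b in net.compartments:
            if b == a:
                continue
            ib = ent.get(b)
            if ib is None:
                # target has no entrance: no cross edge can land there
                continue
            jb = part[b].index(ib)
            phi = fam.G[(a, b)][:, jb, ja]
            fam.Phi[(a, b)] = phi
    fam.entrances = dict(ent)
    return fam


def _kernel_pieces(A: np.ndarray, ztol: float = 1e-10):
    """Spectral projection onto the kernel of ``A`` and a deflated inverse.

    Returns ``(P0, Y)`` with ``P0`` the projection onto the null space of
    the sub-generator (so ``lim_{t->inf} e^{tA} = P0``; the zero eigenvalue
    of a generator block is always semisimple) and ``Y`` solving
    ``A Y = -(I - P0)``, i.e. ``-A^{-1}`` on the decaying invariant
    subspace.  ``Y`` may differ from the spectral inverse by null-space
    components, which carry no outflow and therefore never contribute to
    kernel masses or moments.
    """
    from scipy.linalg import lstsq, null_space

    n = A.shape[0]
    N = null_space(A, rcond=ztol)
    if N.shape[1]:
        Nl = null_space(A.T, rcond=ztol)
        P0 = N @ np.linalg.solve(Nl.T @ N, Nl.T)
        rhs = -(np.eye(n) - P0)
        Y = lstsq(A, rhs)[0]
    else:
        P0 = np.zeros((n, n))
        Y = np.linalg.solve(A, -np.eye(n))
    return P0, Y


@dataclass
class KernelMassReport:
    """Exact (or tail-corrected) total masses of the scalar kernels.

    ``pair_mass[(alpha, beta)]`` is the total integral of
    ``Phi_{alpha beta}``; ``total_mass[alpha]`` its sum over targets (1 for
    a non-sink compartment whose interior has no trap); ``limit_term``
    is ``lim_t e^{t A_{aa}}`` mass retained at the entrance column — a
    positive value diagnoses a sink inside the compartment.
    """

    pair_mass: dict[tuple[str, str], float]
    total_mass: dict[str, float]
    limit_term: dict[str, float]
    tail_flagged: list[tuple[str, str]] = field(default_factory=list)


def kernel_mass(fam: KernelFamily) -> KernelMassReport:
    """Integrate the scalar kernels over ``[0, infinity)``.

    For ODE-derived kernels the masses are closed-form:
    ``int Phi_{ab} = -[A_{ba} A_{aa}^{-1}]`` at the entrance entries,
    evaluated on the non-singular invariant subspace (the zero eigenspace is
    projected out and reported as the limit term).  Tabulated kernels use a
    trapezoid on the grid plus a single-exponential tail fitted on the last
    decade of samples; an unreliable (non-decaying) tail is flagged.
    """
    pair: dict[tuple[str, str], float] = {}
    total: dict[str, float] = {}
    limit: dict[str, float] = {}
    flagged: list[tuple[str, str]] = []
    if fam.provenance == "ode" and fam.net is not None:
        net = fam.net
        part = net.partition
        ent = fam.entrances or {
            a: (pts[0] if len(pts) == 1 else None)
            for a, pts in net.entrance_points.items()
        }
        for a in net.compartments:
            ia = ent.get(a)
            if ia is None:
                limit[a] = 0.0
                total[a] = 0.0
                continue
            ja = part[a].index(ia)
            P0, Y = _kernel_pieces(net.block(a, a))
            limit[a] = float(P0.sum(axis=0)[ja])
            tot = 0.0
            for b in net.compartments:
                if b == a:
                    continue
                ib = ent.get(b)
                if ib is None:
                    continue
                jb = part[b].index(ib)
                m = float((net.block(b, a) @ Y)[jb, ja])
                pair[(a, b)] = m
                tot += m
            total[a] = tot
        return KernelMassReport(pair, total, limit)

    # tabulated route
    t = fam.grid.nodes
    for (a, b), phi in fam.Phi.items():
        m, ok = _trapz_with_tail(t, phi)
        pair[(a, b)] = m
        if not ok:
            flagged.append((a, b))
    for a in fam.compartments:
        total[a] = sum(v for (x, _), v in pair.items() if x == a)
        limit[a] = 0.0
    return KernelMassReport(pair, total, limit, flagged)


def _trapz_with_tail(t: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    base = float(np.trapezoid(y, t))
    n_tail = max(len(t) // 10, 3)
    ts, ys = t[-n_tail:], y[-n_tail:]
    if y[-1] <= 0 or np.any(ys <= 0):
        return base, True  # decayed to zero: no tail needed
    slope = np.polyfit(ts, np.log(ys), 1)[0]
    if slope >= 0:
        return base, False  # non-decaying tail: unreliable
    return base + float(y[-1] / (-slope)), True


class LaplaceSingularError(ValueError):
    """``z I - A_{beta beta}`` is singular at the requested ``z``."""


def laplace_kernel(fam: KernelFamily, z: float) -> tuple[np.ndarray, np.ndarray]:
    """Laplace-transformed kernel matrices ``M(z)`` and ``Q(z)``.

    ``(M(z))_{alpha beta} = Phi^_{beta alpha}(z)`` (zero diagonal) and
    ``Q(z)`` is diagonal with ``Q_{alpha alpha} = k^_alpha(z)``.  For
    ODE-derived kernels the transforms use the exact resolvent
    ``Phi^_{ba}(z) = [A_{ab} (zI - A_{bb})^{-1}]_{i_a, i_b}``; tabulated
    kernels are transformed by quadrature of ``e^{-zt} Phi(t)``.
    """
    comps = fam.compartments
    nX = len(comps)
    M = np.zeros((nX, nX))
    Q = np.zeros((nX, nX))
    if fam.provenance == "ode" and fam.net is not None:
        net = fam.net
        part = net.partition
        ent = fam.entrances or net.single_entrance()
        for bi, b in enumerate(comps):  # b = source compartment
            ib = ent.get(b)
            if ib is None:
                continue
            jb = part[b].index(ib)
            Abb = net.block(b, b)
            n = Abb.shape[0]
            zi = z * np.eye(n) - Abb
            if np.linalg.cond(zi) > 1e13:
                if z == 0.0:
                    # block singular at the origin (interior trap or sink):
                    # the transform of the kernels is still finite and is
                    # given by the deflated inverse -A^{-1}(I - P0)
                    _, R = _kernel_pieces(Abb)
                else:
                    raise LaplaceSingularError(
                        f"z = {z:g} is (numerically) an eigenvalue of block {b!r}"
                    )
            else:
                R = np.linalg.solve(zi, np.eye(n))
            for ai, a in enumerate(comps):
                if a == b:
                    continue
                ia = ent.get(a)
                if ia is None:
                    continue
                ja = part[a].index(ia)
                M[ai, bi] = (net.block(a, b) @ R)[ja, jb]
            Q[bi, bi] = float((net.C[b].diagonal() @ R)[jb])
        return M, Q

    from scipy.integrate import simpson

    t = fam.grid.nodes
    w = np.exp(-z * t)
    for (a, b), phi in fam.Phi.items():
        ai, bi = comps.index(a), comps.index(b)
        M[bi, ai] = simpson(w * phi, x=t)
    for a, ka in fam.k.items():
        ai = comps.index(a)
        Q[ai, ai] = simpson(w * ka, x=t)
    return M, Q
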