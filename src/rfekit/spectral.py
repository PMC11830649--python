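"""Spectral analyses of response kernels.

Three families of results about the scalar kernels of a single-entrance
reduction live here:

* **Reversibility**: when the underlying network satisfies detailed balance,
  every waiting-time kernel is completely monotone — an explicit nonnegative
  mixture of decaying exponentials obtained by symmetrizing the compartment
  block with the square-root equilibrium weights
  (:func:`cm_decompose`).
* **Markovianity**: the compartment totals evolve as a finite Markov jump
  process iff every kernel is a pure exponential
  ``Phi_{ab}(t) = lambda_ab exp(-Lambda_a t)`` with ``Lambda_a`` the total
  exit rate (:func:`markovianity_test`).
* **Long-time behaviour**: for irreducible conservative kernels the
  Laplace-domain characteristic equation ``rho(M(z)) = 1`` has its unique
  real root at ``z = 0``; the Perron eigenvector there gives the asymptotic
  flux profile and, through the residue of ``(I - M(z))^{-1}``, the limiting
  compartment contents (:func:`characteristic_root`,
  :func:`asymptotic_profile`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import brentq

from .kernels import ForcingSet, KernelFamily, kernel_mass, laplace_kernel
from .network import CompartmentNetwork, check_detailed_balance


class SpectralError(RuntimeError):
    pass


@dataclass
class CMRepresentation:
    """Completely monotone form ``Phi(t) = prefactor * sum w_j exp(-nu_j t)``.

    ``prefactor`` is the entrance-to-entrance jump rate; weights are squared
    orthogonal-eigenvector components, hence nonnegative with unit sum;
    decays are the negated eigenvalues of the symmetrized block.
    """

    prefactor: float
    weights: np.ndarray
    decays: np.ndarray

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.prefactor * np.sum(
            self.weights[:, None] * np.exp(-np.outer(self.decays, t)), axis=0
        )

    @property
    def weight_sum(self) -> float:
        return float(self.weights.sum())


def cm_decompose(net: CompartmentNetwork, src: str, dst: str) -> CMRepresentation:
    """Exponential-mixture form of the kernel from ``src`` towards ``dst``.

    Requires detailed balance (refused otherwise, with the violation report
    attached) and single entrance points ``i_src``, ``i_dst``.  The block
    ``A_{src,src}`` is symmetrized by the diagonal square-root equilibrium
    ``diag(sqrt(mu))`` restricted to ``src``; its orthonormal eigenbasis
    yields weights ``Q_{i_src, j}^2`` (summing to one) and decays ``-nu_j``.
    The reconstruction matches the directly computed kernel pointwise.
    """
    report = check_detailed_balance(net.rate_matrix)
    if not report.has_detailed_balance:
        raise SpectralError(
            "network does not satisfy detailed balance "
            f"(max violation {report.max_violation:.3g}, status {report.status!r})"
        )
    ent = net.single_entrance()
    i_src, i_dst = ent[src], ent[dst]
    if i_src is None or i_dst is None:
        raise SpectralError(f"compartments {src!r}/{dst!r} need entrance points")
    part = net.partition
    js = part[src].index(i_src)
    jd = part[dst].index(i_dst)
    lam = float(net.block(dst, src)[jd, js])  # rate i_src -> i_dst

    mu = report.mu[net.state_indices(src)]
    Msqrt = np.sqrt(mu)
    Ass = net.block(src, src)
    D = (Ass * Msqrt[None, :]) / Msqrt[:, None]  # M^-1 A M with M = diag(sqrt mu)
    D = 0.5 * (D + D.T)  # symmetric up to round-off
    nu, Q = np.linalg.eigh(D)
    weights = Q[js, :] ** 2
    return CMRepresentation(prefactor=lam, weights=weights, decays=-nu)


@dataclass
class MarkovianityReport:
    is_markovian: bool
    rates: dict[tuple[str, str], float]
    generator: np.ndarray
    max_residual: float


def markovianity_test(fam: KernelFamily, tol: float = 1e-6) -> MarkovianityReport:
    """Decide whether scalar kernels generate Markovian compartment totals.

    Estimates ``lambda_ab = Phi_ab(0)`` and the common decay
    ``Lambda_a = sum_g lambda_ag``, then tests the sup-norm fit
    ``|Phi_ab(t) - lambda_ab exp(-Lambda_a t)| <= tol * lambda_ab`` on the
    grid for every pair (and ``Phi_ab ≡ 0`` when the initial value
    vanishes).  Returns the induced compartment-level generator in the same
    column convention as the state matrices (``A[i, j] = rate j -> i``).
    """
    if not fam.has_scalar:
        raise ValueError("scalar kernels required")
    comps = fam.compartments
    nX = len(comps)
    t = fam.grid.nodes
    rates: dict[tuple[str, str], float] = {}
    lam0 = np.zeros((nX, nX))
    for (a, b), phi in fam.Phi.items():
        lam0[comps.index(a), comps.index(b)] = phi[0]
    Lambda = lam0.sum(axis=1)
    ok = True
    max_res = 0.0
    for (a, b), phi in fam.Phi.items():
        ai = comps.index(a)
        lam = lam0[ai, comps.index(b)]
        rates[(a, b)] = float(lam)
        model = lam * np.exp(-Lambda[ai] * t)
        res = float(np.abs(phi - model).max())
        max_res = max(max_res, res)
        scale = lam if lam > 0 else 1.0
        if res > tol * scale:
            ok = False
    gen = np.zeros((nX, nX))
    for (a, b), lam in rates.items():
        gen[comps.index(b), comps.index(a)] = lam  # column convention
    np.fill_diagonal(gen, -gen.sum(axis=0))
    return MarkovianityReport(
        is_markovian=ok, rates=rates, generator=gen, max_residual=max_res
    )


@dataclass
class CharacteristicSolution:
    """Real root of ``rho(M(z)) = 1`` with its Perron eigenvector."""

    root: float
    v: np.ndarray
    curve: list[tuple[float, float]] = field(default_factory=list)


def _spectral_radius(M: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(M))))


def _check_irreducible(fam: KernelFamily) -> None:
    masses = kernel_mass(fam).pair_mass
    g = nx.DiGraph()
    g.add_nodes_from(fam.compartments)
    for (a, b), m in masses.items():
        if m > 1e-14:
            g.add_edge(a, b)
    if len(fam.compartments) > 1 and not nx.is_strongly_connected(g):
        raise SpectralError(
            "kernel matrix M(z) is reducible: the compartment digraph is not "
            "strongly connected, so the Perron root need not be simple"
        )


def characteristic_root(
    fam: KernelFamily, z_bracket: tuple[float, float] | None = None
) -> CharacteristicSolution:
    """Locate the real solution of the renewal characteristic equation.

    Brent-solves ``rho(M(z)) = 1`` on the bracket; for conservative
    irreducible kernel families the root sits at ``z = 0`` because the
    column sums of ``M(0)`` (total kernel masses) are one.  ``rho(M(z))`` is
    strictly decreasing in ``z``, so the bracket only needs to straddle the
    sign change.  The Perron eigenvector at the root is returned with unit
    1-norm.
    """
    _check_irreducible(fam)
    if z_bracket is None:
        lo = -0.5
        if fam.provenance == "ode" and fam.net is not None:
            decs = []
            for a in fam.compartments:
                w = np.linalg.eigvals(fam.net.block(a, a))
                decs.extend(-w.real[w.real < -1e-12])
            if decs:
                lo = -0.9 * float(min(decs))
        z_bracket = (lo, 10.0)

    def g(z: float) -> float:
        M, _ = laplace_kernel(fam, z)
        return _spectral_radius(M) - 1.0

    lo, hi = z_bracket
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        raise SpectralError(
            f"bracket [{lo:g}, {hi:g}] does not straddle rho(M(z)) = 1 "
            f"(values {glo + 1:.4g}, {ghi + 1:.4g})"
        )
    root = brentq(g, lo, hi, xtol=1e-12, rtol=1e-14)
    M, _ = laplace_kernel(fam, root)
    w, V = np.linalg.eig(M)
    i = int(np.argmax(w.real))
    v = V[:, i].real
    v = np.abs(v) / np.abs(v).sum()
    curve = [(z, _spectral_radius(laplace_kernel(fam, z)[0])) for z in
             np.linspace(max(lo, root - 0.2), root + 2.0, 9)]
    return CharacteristicSolution(root=float(root), v=v, curve=curve)


@dataclass
class AsymptoticProfile:
    """Limit of the compartment totals for conservative irreducible kernels."""

    c0: float
    v0: np.ndarray
    N_inf: np.ndarray
    decays: bool = True


def _first_moments(fam: KernelFamily) -> tuple[np.ndarray, np.ndarray]:
    """``int t Phi_{ab}`` arranged as M'(0) entries, and ``int t k_a``.

    Exact via the squared resolvent for ODE-derived kernels (on the decaying
    subspace); trapezoid otherwise.
    """
    comps = fam.compartments
    nX = len(comps)
    Mp = np.zeros((nX, nX))  # entries: int t Phi_{b a} at (a_row, b_col)
    mk = np.zeros(nX)
    if fam.provenance == "ode" and fam.net is not None:
        from .kernels import _kernel_pieces

        net = fam.net
        part = net.partition
        ent = fam.entrances or net.single_entrance()
        for bi, b in enumerate(comps):
            ib = ent.get(b)
            if ib is None:
                continue
            jb = part[b].index(ib)
            _, Y = _kernel_pieces(net.block(b, b))  # Y = -A^{-1} deflated
            Y2 = Y @ Y  # = A^{-2} on the decaying subspace
            for ai, a in enumerate(comps):
                if a == b:
                    continue
                ia = ent.get(a)
                if ia is None:
                    continue
                ja = part[a].index(ia)
                Mp[ai, bi] = float((net.block(a, b) @ Y2)[ja, jb])
            mk[bi] = float((net.C[b].diagonal() @ Y2)[jb])
        return Mp, mk

    t = fam.grid.nodes
    for (a, b), phi in fam.Phi.items():
        Mp[comps.index(b), comps.index(a)] = np.trapezoid(t * phi, t)
    for a, ka in fam.k.items():
        mk[comps.index(a)] = np.trapezoid(t * ka, t)
    return Mp, mk


def asymptotic_profile(fam: KernelFamily, forcing: ForcingSet) -> AsymptoticProfile:
    """Long-time limit ``N_inf`` of the compartment totals.

    Computes the simple-pole residue of ``(I - M(z))^{-1} B^0(z)`` at
    ``z = 0`` via the Perron eigenvector formula

        c0 v0 = v0 * (u0^T B^0(0)) / (-u0^T M'(0) v0),

    with ``u0, v0`` the left/right Perron vectors of ``M(0)`` (normalized so
    ``u0^T v0 = 1``) and ``M'(0)`` the matrix of negated kernel first
    moments.  The limiting totals follow as
    ``(N_inf)_alpha = (c0 v0)_alpha * int t k_alpha(t) dt``.
    """
    _check_irreducible(fam)
    comps = fam.compartments
    M0, _ = laplace_kernel(fam, 0.0)
    w, V = np.linalg.eig(M0)
    wl, U = np.linalg.eig(M0.T)
    iR = int(np.argmax(w.real))
    iL = int(np.argmax(wl.real))
    v0 = np.abs(V[:, iR].real)
    u0 = np.abs(U[:, iL].real)
    v0 = v0 / v0.sum()
    u0 = u0 / (u0 @ v0)

    moments, mk = _first_moments(fam)
    Mprime = -moments  # d/dz of e^{-zt} brings down -t
    denom = float(-(u0 @ Mprime @ v0))  # = u0^T (int t Phi) v0 > 0
    if abs(denom) < 1e-13:
        raise SpectralError("pole of (I - M(z))^{-1} at z = 0 is not simple")

    b0 = np.zeros(len(comps))
    if forcing.net is not None and forcing.n0 is not None:
        # exact forcing mass: int S^0_a = sum_b A_{ab} (-A_{bb}^{-1}) n0_b
        from .kernels import _kernel_pieces

        net = forcing.net
        for i, a in enumerate(comps):
            acc = 0.0
            for b in comps:
                if b == a:
                    continue
                _, Y = _kernel_pieces(net.block(b, b))
                n0b = forcing.n0[net.state_indices(b)]
                acc += float((net.block(a, b) @ (Y @ n0b)).sum())
            b0[i] = acc
    else:
        t = forcing.grid.nodes
        for i, a in enumerate(comps):
            if a in forcing.B0:
                b0[i] = np.trapezoid(forcing.B0[a], t)
            elif a in forcing.S0:
                b0[i] = np.trapezoid(forcing.S0[a].sum(axis=1), t)
    c0 = float(u0 @ b0) / denom
    N_inf = c0 * v0 * mk
    return AsymptoticProfile(c0=c0, v0=v0, N_inf=N_inf)
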