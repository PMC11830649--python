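"""Phase-type (Erlang-mixture) approximation of waiting-time distributions.

Any probability measure on the positive half line can be approximated
arbitrarily well, in the weak topology, by mixtures of Erlang densities
sharing a single rate,

    f(t) = sum_j q_j gamma_{M, m_j}(t),
    gamma_{M, m}(t) = M^{m+1} t^m e^{-M t} / m!,

(``gamma_{M,m}`` is the law of a sum of ``m + 1`` independent
exponential-``M`` stages).  Such a mixture is realized exactly by a linear
reaction chain: a start node branching into ``L`` sequential chains at rates
``q_j M``, every internal hop at rate ``M``, all chains merging in a common
end node.  The flux into the end node under a unit impulse at the start node
reproduces ``f`` exactly.

:func:`erlang_fit` implements the constructive "Erlangization" rule
(CDF increments on the ``1/M`` lattice), :func:`realize_chain` builds the
single-chain network, and :func:`realize_network` assembles a full
conservative, single-entrance network whose scalar kernels carry prescribed
pair masses ``p_{alpha beta}`` and mixture shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .network import (
    CompartmentNetwork,
    Partition,
    build_compartment_network,
    validate_rate_matrix,
)


@dataclass(frozen=True)
class ErlangMixture:
    """Mixture of Erlang densities with common rate ``M``.

    ``components`` is a list of ``(weight, shape)`` pairs with positive
    weights summing to one and integer shapes ``m >= 0`` (shape ``m`` means
    ``m + 1`` exponential stages).  The density integrates to one
    analytically.
    """

    M: float
    components: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        if self.M <= 0:
            raise ValueError("rate M must be positive")
        if not self.components:
            raise ValueError("mixture needs at least one component")
        for q, m in self.components:
            if q <= 0 or m < 0 or m != int(m):
                raise ValueError(f"invalid component (q={q}, m={m})")
        if abs(sum(q for q, _ in self.components) - 1.0) > 1e-12:
            raise ValueError("weights must sum to one")

    def density(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for q, m in self.components:
            out += q * stats.gamma.pdf(t, a=m + 1, scale=1.0 / self.M)
        return out

    def cdf(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for q, m in self.components:
            out += q * stats.gamma.cdf(t, a=m + 1, scale=1.0 / self.M)
        return out

    def shifted(self) -> "ErlangMixture":
        """The mixture convolved with one extra exponential-``M`` stage."""
        return ErlangMixture(
            M=self.M, components=tuple((q, m + 1) for q, m in self.components)
        )

    def mean(self) -> float:
        return sum(q * (m + 1) for q, m in self.components) / self.M


class FitWarningError(UserWarning):
    pass


def erlang_fit(target_cdf, M: float, L: int) -> ErlangMixture:
    """Erlangize a target distribution on the ``1/M`` lattice.

    ``target_cdf`` is a callable (vectorized) CDF on the nonnegative reals.
    The rule assigns shape ``m_j = j - 1`` the probability mass of the
    target on ``((j-1)/M, j/M]`` for ``j = 1..L-1`` and dumps the remaining
    tail mass on the last shape.  As ``M, L -> infinity`` (with ``L/M``
    covering the bulk) the mixture converges weakly to the target.

    A warning is attached (via ``warnings.warn``) when the tail component
    receives more than half the mass, i.e. ``L/M`` fails to cover the bulk.
    """
    import warnings

    if L < 1:
        raise ValueError("need at least one component")
    grid = np.arange(L + 1) / M
    F = np.asarray(target_cdf(grid), dtype=float)
    F = np.clip(F, 0.0, 1.0)
    q = np.diff(F[: L])  # masses of ((j-1)/M, j/M] for j=1..L-1
    qs = list(q)
    qs.append(1.0 - F[L - 1])  # tail mass on the last shape
    comps = [(float(w), j) for j, w in enumerate(qs) if w > 1e-15]
    total = sum(w for w, _ in comps)
    comps = [(w / total, m) for w, m in comps]
    mix = ErlangMixture(M=M, components=tuple(comps))
    if qs[-1] > 0.5:
        warnings.warn(
            f"tail component carries {qs[-1]:.2f} of the mass; increase L or "
            "decrease 1/M to cover the target's bulk",
            FitWarningError,
            stacklevel=2,
        )
    return mix


def ks_distance(mix: ErlangMixture, target_cdf, t_max: float | None = None,
                n: int = 2001) -> float:
    """Kolmogorov–Smirnov distance between the mixture and a target CDF.

    An upper bound for the Lévy–Prokhorov metric, hence a convenient
    surrogate for weak-convergence diagnostics.
    """
    if t_max is None:
        t_max = 3.0 * (max(m for _, m in mix.components) + 1) / mix.M + 1.0
    t = np.linspace(0.0, t_max, n)
    return float(np.abs(mix.cdf(t) - np.asarray(target_cdf(t))).max())


def w1_distance(mix: ErlangMixture, target_cdf, t_max: float | None = None,
                n: int = 4001) -> float:
    """Wasserstein-1 distance (integral of |CDF difference|), diagnostic."""
    if t_max is None:
        t_max = 3.0 * (max(m for _, m in mix.components) + 1) / mix.M + 1.0
    t = np.linspace(0.0, t_max, n)
    return float(np.trapezoid(np.abs(mix.cdf(t) - np.asarray(target_cdf(t))), t))


def realize_chain(
    mix: ErlangMixture, start: str = "zeta", end: str = "omega"
) -> CompartmentNetwork:
    """Realize a mixture as a branching-chain reaction network.

    The start node jumps into chain ``j`` at rate ``q_j M`` (a shape-0
    component is a direct edge to the end node); each chain has ``m_j``
    internal nodes traversed at rate ``M`` and feeds the common end node at
    rate ``M``.  Under a unit impulse at the start node the flux into the
    end node equals the mixture density exactly.  The partition is
    ``{start + chains} | {end}``.
    """
    M = mix.M
    states = [start]
    chain_nodes: list[list[str]] = []
    for j, (_, m) in enumerate(mix.components):
        nodes = [f"x{n}_{j}" for n in range(1, m + 1)]
        chain_nodes.append(nodes)
        states.extend(nodes)
    states.append(end)
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    A = np.zeros((n, n))

    def add(src: str, dst: str, rate: float) -> None:
        A[idx[dst], idx[src]] += rate

    for j, (q, m) in enumerate(mix.components):
        nodes = chain_nodes[j]
        if m == 0:
            add(start, end, q * M)
            continue
        add(start, nodes[0], q * M)
        for a, b in zip(nodes[:-1], nodes[1:]):
            add(a, b, M)
        add(nodes[-1], end, M)

    np.fill_diagonal(A, -A.sum(axis=0))
    rm = validate_rate_matrix(A, states=states)
    partition = Partition(
        names=("chain", "sink"), members=(tuple(states[:-1]), (end,))
    )
    return build_compartment_network(rm, partition)


def chain_flux(net: CompartmentNetwork, grid, start: str = "zeta") -> np.ndarray:
    """Flux into the sink compartment under a unit impulse at ``start``.

    For a network built by :func:`realize_chain` this reproduces the
    mixture density on the grid (up to matrix-exponential round-off).
    """
    from .kernels import scalar_kernels

    fam = scalar_kernels(net, grid, entrances={"chain": start})
    return fam.Phi[("chain", "sink")]


def realize_network(
    p: dict[tuple[str, str], float],
    mixes: dict[tuple[str, str], ErlangMixture],
) -> CompartmentNetwork:
    """Assemble a conservative network realizing prescribed kernel masses.

    ``p[(alpha, beta)]`` are nonnegative pair weights; for every compartment
    the outgoing weights must sum to one (or all be zero, making it a sink).
    Each pair with ``p > 0`` contributes a branch node fed from the entrance
    ``i_alpha`` at rate ``M_{ab} p_{ab}`` and a chain complex ending at the
    entrance ``i_beta``.  The resulting scalar kernels integrate exactly to
    ``p_{alpha beta}``; their shape is the pair's mixture density convolved
    with the initial exponential stage (one extra shape unit).
    """
    comps = sorted({a for a, _ in p} | {b for _, b in p})
    out_sum = {a: sum(v for (x, _), v in p.items() if x == a) for a in comps}
    for a, s in out_sum.items():
        if not (abs(s - 1.0) <= 1e-9 or abs(s) <= 1e-9):
            raise ValueError(
                f"outgoing weights of {a!r} sum to {s:g}; must be 1 (or all 0)"
            )
    for a in comps:
        Ms = {mixes[(x, b)].M for (x, b), w in p.items() if x == a and w > 0}
        if len(Ms) > 1:
            raise ValueError(
                f"mixtures leaving {a!r} must share the stage rate M "
                f"(got {sorted(Ms)}); otherwise the branch probabilities at "
                "the entrance node would distort the pair masses"
            )

    states: list[str] = []
    members: dict[str, list[str]] = {a: [f"i_{a}"] for a in comps}
    edges: list[tuple[str, str, float]] = []
    for (a, b), w in p.items():
        if w <= 0:
            continue
        mix = mixes[(a, b)]
        M = mix.M
        zeta = f"z_{a}_{b}"
        members[a].append(zeta)
        edges.append((f"i_{a}", zeta, M * w))
        for j, (q, m) in enumerate(mix.components):
            nodes = [f"x{n}_{j}_{a}_{b}" for n in range(1, m + 1)]
            members[a].extend(nodes)
            path = [zeta, *nodes, f"i_{b}"]
            rates = [q * M] + [M] * (len(path) - 2)
            for (s, d), r in zip(zip(path[:-1], path[1:]), rates):
                edges.append((s, d, r))

    for a in comps:
        states.extend(members[a])
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    A = np.zeros((n, n))
    for s, d, r in edges:
        A[idx[d], idx[s]] += r
    np.fill_diagonal(A, -A.sum(axis=0))
    rm = validate_rate_matrix(A, states=states)
    partition = Partition(
        names=tuple(comps), members=tuple(tuple(members[a]) for a in comps)
    )
    return build_compartment_network(rm, partition)
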