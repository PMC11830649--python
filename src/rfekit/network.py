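"""Conservative linear reaction networks and their compartment decompositions.

A network of first-order (unimolecular) reactions on a finite state set
``Omega`` is encoded by a generator matrix ``A`` with the convention

    A[i, j] = lambda_{j -> i}   (rate of the jump j -> i, stored at row i,
                                 column j),

so that concentrations evolve as ``dn/dt = A n`` without transposition.
Off-diagonal entries are nonnegative and every column sums to zero
(conservativity): the diagonal entry ``A[i, i]`` equals minus the total exit
rate of state ``i``.

A :class:`Partition` groups the states into named compartments.  The
:class:`CompartmentNetwork` carries the block decomposition of ``A`` induced
by the partition: cross blocks ``A_{alpha beta}``, internal conservative
blocks ``E_{alpha alpha}`` and diagonal loss matrices ``C_alpha`` with
``A_{alpha alpha} = E_{alpha alpha} - C_alpha``, together with the directed
edge set and the entrance points of every compartment (states that receive
jumps from outside their compartment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import networkx as nx


class NetworkValidationError(ValueError):
    """Raised when a rate matrix or partition fails structural validation."""


def _default_labels(n: int) -> list[str]:
    return [f"s{i}" for i in range(n)]


@dataclass(frozen=True)
class RateMatrix:
    """A validated conservative generator matrix.

    Attributes
    ----------
    states:
        Ordered unique state labels.
    A:
        Dense ``(n, n)`` array, ``A[i, j] = lambda_{j->i}``.  Columns sum to
        zero exactly (the diagonal is recomputed from the off-diagonals
        during validation).
    """

    states: tuple[str, ...]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A.setflags(write=False)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self.states.index(state)

    def rate(self, src: str, dst: str) -> float:
        """Jump rate ``lambda_{src -> dst}``."""
        return float(self.A[self.index(dst), self.index(src)])


def validate_rate_matrix(
    A,
    states: Sequence[str] | None = None,
    tol: float | None = None,
) -> RateMatrix:
    """Validate a dense rate table and normalize its diagonal.

    Parameters
    ----------
    A:
        Square array-like; entry ``A[i][j]`` is the rate of the jump
        ``j -> i``.
    states:
        Optional labels; auto-generated (``s0, s1, ...``) when omitted.
    tol:
        Absolute tolerance for negative off-diagonals and nonzero column
        sums.  Defaults to ``1e-9 * max|A|`` (float accumulation over the
        column length).

    The diagonal of the returned matrix is recomputed from the off-diagonal
    entries, so columns sum to zero exactly.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise NetworkValidationError(f"rate matrix must be square, got shape {A.shape}")
    n = A.shape[0]
    if states is None:
        states = _default_labels(n)
    states = tuple(str(s) for s in states)
    if len(states) != n:
        raise NetworkValidationError(f"{len(states)} labels for a {n}-state matrix")
    if len(set(states)) != n:
        raise NetworkValidationError("state labels must be unique")
    if not np.all(np.isfinite(A)):
        raise NetworkValidationError("rate matrix contains non-finite entries")

    scale = max(np.abs(A).max(), 1.0)
    if tol is None:
        tol = 1e-9 * scale

    off = A.copy()
    np.fill_diagonal(off, 0.0)
    neg = off < -tol
    if neg.any():
        i, j = (int(v) for v in np.argwhere(neg)[0])
        raise NetworkValidationError(
            f"negative off-diagonal rate {A[i, j]:g} for jump {states[j]} -> {states[i]}"
        )
    off[off < 0] = 0.0

    colsum = A.sum(axis=0)
    bad = np.abs(colsum) > tol * max(1.0, n)
    if bad.any():
        j = int(np.flatnonzero(bad)[0])
        raise NetworkValidationError(
            f"column sum nonzero at {states[j]} (sum = {colsum[j]:g})"
        )

    out = off
    np.fill_diagonal(out, 0.0)
    np.fill_diagonal(out, -out.sum(axis=0))
    return RateMatrix(states=states, A=out)


@dataclass(frozen=True)
class Partition:
    """Ordered named partition of the state set into compartments."""

    names: tuple[str, ...]
    members: tuple[tuple[str, ...], ...]

    @classmethod
    def from_dict(cls, compartments: Mapping[str, Sequence[str]]) -> "Partition":
        names = tuple(compartments)
        members = tuple(tuple(v) for v in compartments.values())
        return cls(names=names, members=members)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise NetworkValidationError("compartment names must be unique")
        seen: set[str] = set()
        for name, mem in zip(self.names, self.members):
            if not mem:
                raise NetworkValidationError(f"compartment {name!r} is empty")
            dup = seen.intersection(mem)
            if dup:
                raise NetworkValidationError(
                    f"states {sorted(dup)} appear in more than one compartment"
                )
            seen.update(mem)

    def states(self) -> tuple[str, ...]:
        return tuple(s for mem in self.members for s in mem)

    def compartment_of(self, state: str) -> str:
        for name, mem in zip(self.names, self.members):
            if state in mem:
                return name
        raise KeyError(state)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.members[self.names.index(name)]


@dataclass(frozen=True)
class CompartmentNetwork:
    """A rate matrix together with a partition and its block decomposition."""

    rate_matrix: RateMatrix
    partition: Partition
    blocks: dict[tuple[str, str], np.ndarray] = field(repr=False)
    E: dict[str, np.ndarray] = field(repr=False)
    C: dict[str, np.ndarray] = field(repr=False)
    edges: frozenset[tuple[str, str]]
    entrance_points: dict[str, tuple[str, ...]]

    @property
    def states(self) -> tuple[str, ...]:
        return self.rate_matrix.states

    @property
    def compartments(self) -> tuple[str, ...]:
        return self.partition.names

    def state_indices(self, name: str) -> np.ndarray:
        states = self.rate_matrix.states
        return np.array([states.index(s) for s in self.partition[name]])

    def block(self, alpha: str, beta: str) -> np.ndarray:
        """Sub-table ``A_{alpha beta}`` (rows in alpha, columns in beta)."""
        return self.blocks[(alpha, beta)]

    def single_entrance(self) -> dict[str, str | None]:
        """Entrance point per compartment, requiring at most one each.

        Raises :class:`NetworkValidationError` naming the violators when a
        compartment has several entrance points.
        """
        bad = [a for a, pts in self.entrance_points.items() if len(pts) > 1]
        if bad:
            raise NetworkValidationError(
                f"compartments with multiple entrance points: {bad}"
            )
        return {
            a: (pts[0] if pts else None) for a, pts in self.entrance_points.items()
        }

    def compartment_digraph(self) -> nx.DiGraph:
        """Directed graph on compartments (edge alpha->beta iff a jump exists)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.compartments)
        part = self.partition
        for (i, j) in self.edges:
            a, b = part.compartment_of(i), part.compartment_of(j)
            if a != b:
                g.add_edge(a, b)
        return g

    def state_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.states)
        g.add_edges_from(self.edges)
        return g


def build_compartment_network(
    rate_matrix: RateMatrix, partition: Partition
) -> CompartmentNetwork:
    """Decompose a validated rate matrix along a partition.

    Populates the cross blocks ``A_{alpha beta}``, the internal conservative
    blocks ``E_{alpha alpha}`` (columns sum to zero), the diagonal loss
    matrices ``C_alpha`` (``(C_alpha)_{ii}`` is the total rate of jumps from
    ``i`` out of its compartment) and the entrance points.  Reassembling the
    blocks reproduces the input matrix exactly.
    """
    if set(partition.states()) != set(rate_matrix.states):
        missing = set(rate_matrix.states) - set(partition.states())
        extra = set(partition.states()) - set(rate_matrix.states)
        raise NetworkValidationError(
            f"partition does not match states (missing={sorted(missing)}, "
            f"unknown={sorted(extra)})"
        )
    A = rate_matrix.A
    states = rate_matrix.states
    idx = {name: [states.index(s) for s in partition[name]] for name in partition.names}

    blocks: dict[tuple[str, str], np.ndarray] = {}
    E: dict[str, np.ndarray] = {}
    C: dict[str, np.ndarray] = {}
    for a in partition.names:
        ia = idx[a]
        for b in partition.names:
            blocks[(a, b)] = A[np.ix_(ia, idx[b])].copy()
        Aaa = blocks[(a, a)]
        # (C_alpha)_{ii} = total rate i -> outside = -(column sum of the block)
        c_diag = -Aaa.sum(axis=0)
        Ca = np.diag(c_diag)
        Ea = Aaa + Ca
        E[a] = Ea
        C[a] = Ca

    edges = frozenset(
        (states[j], states[i])
        for i in range(len(states))
        for j in range(len(states))
        if i != j and A[i, j] > 0
    )
    part_of = {s: partition.compartment_of(s) for s in states}
    entrance: dict[str, tuple[str, ...]] = {}
    for a in partition.names:
        pts = []
        for s in partition[a]:
            if any(dst == s and part_of[src] != a for (src, dst) in edges):
                pts.append(s)
        entrance[a] = tuple(pts)

    return CompartmentNetwork(
        rate_matrix=rate_matrix,
        partition=partition,
        blocks=blocks,
        E=E,
        C=C,
        edges=edges,
        entrance_points=entrance,
    )


@dataclass(frozen=True)
class EquilibriumReport:
    """Result of a detailed-balance check.

    ``status`` is ``"ok"`` or ``"non-unique equilibrium"`` (reducible
    generator with a multi-dimensional null space).  When a unique strictly
    positive equilibrium exists, ``mu`` holds it normalized to a probability
    vector and ``max_violation`` the largest ``|A_ij mu_j - A_ji mu_i|``.
    """

    has_detailed_balance: bool
    mu: np.ndarray | None
    max_violation: float
    status: str = "ok"


def check_detailed_balance(
    rate_matrix: RateMatrix, tol: float = 1e-8
) -> EquilibriumReport:
    """Test whether ``A`` is reversible w.r.t. its equilibrium.

    Computes the null space of ``A``; if it is one-dimensional with a
    strictly positive vector ``mu`` (normalized to sum 1), reports the
    maximal pairwise flux imbalance ``|A_ij mu_j - A_ji mu_i|``.  Detailed
    balance holds iff that violation is below ``tol`` relative to the rate
    scale and ``mu`` is strictly positive.  A multi-dimensional null space
    yields the status ``"non-unique equilibrium"`` rather than an exception.
    """
    from scipy.linalg import null_space

    A = rate_matrix.A
    scale = max(np.abs(A).max(), 1.0)
    ns = null_space(A, rcond=1e-10)
    if ns.shape[1] != 1:
        return EquilibriumReport(
            has_detailed_balance=False,
            mu=None,
            max_violation=np.inf,
            status="non-unique equilibrium",
        )
    mu = ns[:, 0]
    if mu.sum() < 0:
        mu = -mu
    if np.any(mu <= 0):
        # equilibrium has zero/negative mass on some state
        return EquilibriumReport(
            has_detailed_balance=False,
            mu=None,
            max_violation=np.inf,
            status="ok",
        )
    mu = mu / mu.sum()
    F = A * mu[None, :]  # F[i, j] = A_ij mu_j
    viol = float(np.abs(F - F.T).max())
    return EquilibriumReport(
        has_detailed_balance=viol <= tol * scale,
        mu=mu,
        max_violation=viol,
        status="ok",
    )


class GenerationError(RuntimeError):
    """Raised when the random generator cannot satisfy the requested options."""


def random_conservative_network(
    n_states: int,
    n_compartments: int,
    seed: int,
    *,
    single_entrance: bool = False,
    detailed_balance: bool = False,
    strongly_connected: bool = False,
    rate_scale: float = 1.0,
    extra_edge_prob: float = 0.3,
    max_retries: int = 50,
) -> CompartmentNetwork:
    """Draw a random conservative network with a compartment partition.

    The construction respects the requested structural options:

    * ``single_entrance`` — cross-compartment jumps land only on a designated
      entrance state per compartment.
    * ``detailed_balance`` — rates are built as ``lambda_{i->j} = s_{ij}/mu_i``
      with a symmetric nonnegative ``s`` and a random positive equilibrium
      ``mu`` (so every edge is bidirectional and reversibility is exact).
    * ``strongly_connected`` — the state-level digraph is strongly connected
      (hence also the compartment-level digraph).

    Options are re-verified post hoc; on failure the draw is resampled up to
    ``max_retries`` times before :class:`GenerationError` is raised.
    """
    if n_states < n_compartments or n_compartments < 1:
        raise GenerationError("need n_states >= n_compartments >= 1")

    for attempt in range(max_retries):
        rng = np.random.default_rng((seed, attempt))
        net = _draw_network(
            n_states,
            n_compartments,
            rng,
            single_entrance=single_entrance,
            detailed_balance=detailed_balance,
            strongly_connected=strongly_connected,
            rate_scale=rate_scale,
            extra_edge_prob=extra_edge_prob,
        )
        if net is None:
            continue
        if single_entrance and any(
            len(p) > 1 for p in net.entrance_points.values()
        ):
            continue
        if strongly_connected and not nx.is_strongly_connected(net.state_digraph()):
            continue
        if detailed_balance and not check_detailed_balance(
            net.rate_matrix, tol=1e-10
        ).has_detailed_balance:
            continue
        return net
    raise GenerationError(
        f"could not satisfy options after {max_retries} draws "
        f"(n_states={n_states}, n_compartments={n_compartments})"
    )


def _draw_network(
    n_states: int,
    n_compartments: int,
    rng: np.random.Generator,
    *,
    single_entrance: bool,
    detailed_balance: bool,
    strongly_connected: bool,
    rate_scale: float,
    extra_edge_prob: float,
) -> CompartmentNetwork | None:
    states = _default_labels(n_states)
    # random partition sizes, each >= 1
    cuts = np.sort(
        rng.choice(np.arange(1, n_states), size=n_compartments - 1, replace=False)
    )
    bounds = [0, *cuts.tolist(), n_states]
    members = [tuple(states[bounds[k] : bounds[k + 1]]) for k in range(n_compartments)]
    names = [f"c{k}" for k in range(n_compartments)]
    partition = Partition(names=tuple(names), members=tuple(members))
    entrance = {names[k]: members[k][0] for k in range(n_compartments)}
    idx = {s: i for i, s in enumerate(states)}

    def rand_rate() -> float:
        return float(rng.uniform(0.5, 1.5) * rate_scale)

    directed: dict[tuple[int, int], float] = {}

    def add_edge(src: str, dst: str, rate: float | None = None) -> None:
        directed[(idx[src], idx[dst])] = rate if rate is not None else rand_rate()

    if detailed_balance:
        # symmetric undirected skeleton: spanning tree within compartments,
        # entrance-to-entrance links between compartments
        pairs: set[tuple[int, int]] = set()
        for mem in members:
            for a, b in zip(mem[:-1], mem[1:]):
                pairs.add((idx[a], idx[b]))
        ring = list(range(n_compartments))
        for k in ring:
            a = entrance[names[k]]
            b = entrance[names[(k + 1) % n_compartments]]
            if a != b and n_compartments > 1:
                pairs.add(tuple(sorted((idx[a], idx[b]))))
        # optional extra internal chords
        for mem in members:
            for a in mem:
                for b in mem:
                    if idx[a] < idx[b] and rng.uniform() < extra_edge_prob:
                        pairs.add((idx[a], idx[b]))
        mu = rng.uniform(0.2, 1.0, size=n_states)
        mu = mu / mu.sum()
        A = np.zeros((n_states, n_states))
        for (i, j) in pairs:
            s = rng.uniform(0.5, 1.5) * rate_scale
            # lambda_{i->j} = s/mu_i ; A[j, i] = lambda_{i->j}
            A[j, i] = s / mu[i]
            A[i, j] = s / mu[j]
    else:
        # Hamiltonian-style ring: path through each compartment, exit from its
        # last state into the next compartment's entrance. Gives strong
        # connectivity while respecting single entrances.
        for k in range(n_compartments):
            mem = members[k]
            for a, b in zip(mem[:-1], mem[1:]):
                add_edge(a, b)
            if n_compartments > 1:
                nxt = names[(k + 1) % n_compartments]
                add_edge(mem[-1], entrance[nxt])
            elif len(mem) > 1:
                add_edge(mem[-1], mem[0])
        # extra random edges
        for s in states:
            for t in states:
                if s == t or rng.uniform() >= extra_edge_prob:
                    continue
                ca = partition.compartment_of(s)
                cb = partition.compartment_of(t)
                if ca != cb and single_entrance and t != entrance[cb]:
                    continue
                add_edge(s, t)
        A = np.zeros((n_states, n_states))
        for (i, j), rate in directed.items():
            A[j, i] = rate

    np.fill_diagonal(A, 0.0)
    np.fill_diagonal(A, -A.sum(axis=0))
    try:
        rm = validate_rate_matrix(A, states=states)
        return build_compartment_network(rm, partition)
    except NetworkValidationError:
        return None
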