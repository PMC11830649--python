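import numpy as np
import pytest

from rfekit import (
    Partition,
    TimeGrid,
    build_compartment_network,
    random_conservative_network,
    validate_rate_matrix,
)


@pytest.fixture
def two_state_net():
    """Two singleton compartments, a single jump s0 -> s1 at rate 1."""
    rm = validate_rate_matrix([[-1.0, 0.0], [1.0, 0.0]])
    part = Partition.from_dict({"one": ["s0"], "two": ["s1"]})
    return build_compartment_network(rm, part)


@pytest.fixture
def symmetric_pair_net():
    """Two singleton compartments exchanging at unit rate both ways.

    Scalar kernels are Phi = e^{-t} in both directions.
    """
    rm = validate_rate_matrix([[-1.0, 1.0], [1.0, -1.0]])
    part = Partition.from_dict({"one": ["s0"], "two": ["s1"]})
    return build_compartment_network(rm, part)


@pytest.fixture
def reversible_chain_rm():
    """Two-state reversible chain: s0 -> s1 at rate 1, s1 -> s0 at rate 2."""
    return validate_rate_matrix([[-1.0, 2.0], [1.0, -2.0]])


@pytest.fixture
def sink_inside_net():
    """Single-entrance compartment with an interior trap state.

    s0 is the entrance of compartment "main"; it feeds the exit state s1
    (which jumps to the other compartment) and the trap s2 (no way out), so
    part of the kernel mass never leaves.
    """
    # states: s0 (entrance), s1 (exit), s2 (trap), s3 (other compartment)
    A = np.zeros((4, 4))
    A[1, 0] = 1.0  # s0 -> s1
    A[2, 0] = 1.0  # s0 -> s2 (trap)
    A[3, 1] = 2.0  # s1 -> s3
    np.fill_diagonal(A, -A.sum(axis=0))
    rm = validate_rate_matrix(A)
    part = Partition.from_dict({"main": ["s0", "s1", "s2"], "out": ["s3"]})
    return build_compartment_network(rm, part)


@pytest.fixture
def irreducible_fixture():
    """Strongly connected single-entrance network (8 states, 3 compartments)."""
    return random_conservative_network(
        8, 3, 11, single_entrance=True, strongly_connected=True
    )


@pytest.fixture
def db_fixture():
    """Detailed-balance single-entrance network (5 states, 2 compartments)."""
    return random_conservative_network(
        5, 2, 7, detailed_balance=True, single_entrance=True
    )


@pytest.fixture
def grid_mid():
    return TimeGrid(t_end=10.0, n_points=1001)
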