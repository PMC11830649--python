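"""When are compartment totals Markovian?

The reduced dynamics of compartment totals are Markovian exactly when every
waiting-time kernel is a pure exponential with the compartment's total exit
rate.  This script tests an exponential family (recovering its rates) and an
Erlang-shaped kernel (rejected: the waiting time has memory).
"""

import numpy as np

from rfekit import KernelFamily, TimeGrid
from rfekit.spectral import markovianity_test

grid = TimeGrid(15.0, 1501)
t = grid.nodes

exp_family = KernelFamily.from_scalar(
    grid, ("a", "b"),
    {("a", "b"): 2.0 * np.exp(-2.0 * t), ("b", "a"): 0.5 * np.exp(-0.5 * t)},
)
rep = markovianity_test(exp_family)
print("exponential kernels -> markovian:", rep.is_markovian)
print("recovered rates:", {f"{a}->{b}": round(v, 6) for (a, b), v in rep.rates.items()})

erlang_family = KernelFamily.from_scalar(
    grid, ("a", "b"),
    {("a", "b"): t * np.exp(-t), ("b", "a"): t * np.exp(-t)},
)
rep2 = markovianity_test(erlang_family)
print("erlang kernels      -> markovian:", rep2.is_markovian,
      f"(sup-norm residual {rep2.max_residual:.3f})")
# An Erlang waiting time vanishes at zero lag, so no exponential with the
# same mass can match it: the totals remember how long ago elements entered.
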