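"""Round-trip serialization of networks, kernels and solutions.

Formats:

* **Network JSON** — ``{"states": [...], "edges": [{"from": i, "to": j,
  "rate": x}, ...], "compartments": {name: [states...]}}``.  The edge list
  stores jump rates ``lambda_{i->j}`` explicitly, so the column-oriented
  matrix convention can never be misread.
* **Kernel CSV** — long format ``(t, from_compartment, to_compartment,
  row_state, col_state, value)``; scalar kernels leave the state columns
  empty.
* **Solution CSV** — ``(t, compartment, N, B_total, D_total)``.

Floats are serialized with 17 significant digits, which round-trips IEEE
doubles exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import KernelFamily, TimeGrid
from .network import (
    CompartmentNetwork,
    Partition,
    build_compartment_network,
    validate_rate_matrix,
)
from .renewal import RenewalSolution

_FLOAT_FMT = "%.17g"


def network_to_json(net: CompartmentNetwork) -> dict:
    states = list(net.states)
    idx = {s: i for i, s in enumerate(states)}
    A = net.rate_matrix.A
    edges = [
        {"from": src, "to": dst, "rate": float(A[idx[dst], idx[src]])}
        for (src, dst) in sorted(net.edges)
    ]
    comps = {a: list(net.partition[a]) for a in net.compartments}
    return {"states": states, "edges": edges, "compartments": comps}


def network_from_json(doc: dict) -> CompartmentNetwork:
    states = [str(s) for s in doc["states"]]
    n = len(states)
    idx = {s: i for i, s in enumerate(states)}
    A = np.zeros((n, n))
    for e in doc["edges"]:
        A[idx[str(e["to"])], idx[str(e["from"])]] += float(e["rate"])
    np.fill_diagonal(A, -A.sum(axis=0))
    rm = validate_rate_matrix(A, states=states)
    part = Partition.from_dict(doc["compartments"])
    return build_compartment_network(rm, part)


def write_network(net: CompartmentNetwork, path: str | Path) -> None:
    Path(path).write_text(json.dumps(network_to_json(net), indent=1))


def read_network(path: str | Path) -> CompartmentNetwork:
    return network_from_json(json.loads(Path(path).read_text()))


def kernels_to_frame(fam: KernelFamily) -> pd.DataFrame:
    rows = []
    t = fam.grid.nodes
    if fam.net is not None:
        part = fam.net.partition
    for (src, dst), g in fam.G.items():
        rs = fam.net.partition[dst] if fam.net else range(g.shape[1])
        cs = fam.net.partition[src] if fam.net else range(g.shape[2])
        for i, r in enumerate(rs):
            for j, c in enumerate(cs):
                rows.append(
                    pd.DataFrame(
                        {
                            "t": t,
                            "from_compartment": src,
                            "to_compartment": dst,
                            "row_state": str(r),
                            "col_state": str(c),
                            "value": g[:, i, j],
                        }
                    )
                )
    for (a, b), phi in fam.Phi.items():
        rows.append(
            pd.DataFrame(
                {
                    "t": t,
                    "from_compartment": a,
                    "to_compartment": b,
                    "row_state": "",
                    "col_state": "",
                    "value": phi,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["t", "from_compartment", "to_compartment", "row_state",
                     "col_state", "value"]
        )
    return pd.concat(rows, ignore_index=True)


def write_kernels(fam: KernelFamily, path: str | Path) -> None:
    kernels_to_frame(fam).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_scalar_kernels(path: str | Path) -> KernelFamily:
    """Read scalar kernels back from the long CSV format."""
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    df = df[(df["row_state"] == "") & (df["col_state"] == "")]
    if df.empty:
        raise ValueError("no scalar kernels in file")
    t = np.array(sorted(df["t"].unique()))
    grid = TimeGrid(t_end=float(t[-1]), n_points=len(t))
    comps = sorted(set(df["from_compartment"]) | set(df["to_compartment"]))
    Phi = {}
    for (a, b), sub in df.groupby(["from_compartment", "to_compartment"]):
        sub = sub.sort_values("t")
        Phi[(a, b)] = sub["value"].to_numpy()
    return KernelFamily.from_scalar(grid, comps, Phi)


def solution_to_frame(sol: RenewalSolution) -> pd.DataFrame:
    t = sol.grid.nodes
    rows = []
    for a in sol.compartments:
        if a in sol.B:
            b_tot, d_tot = sol.B[a], sol.D[a]
        else:
            b_tot = sol.S[a].sum(axis=1)
            d_tot = sol.J[a].sum(axis=1)
        rows.append(
            pd.DataFrame(
                {"t": t, "compartment": a, "N": sol.N[a], "B_total": b_tot,
                 "D_total": d_tot}
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_solution(sol: RenewalSolution, path: str | Path) -> None:
    solution_to_frame(sol).to_csv(path, index=False, float_format=_FLOAT_FMT)
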