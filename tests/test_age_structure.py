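import numpy as np
import pytest
from scipy.linalg import expm

from rfekit import (
    KernelFamily,
    TimeGrid,
    random_conservative_network,
    solve_rfe,
)
from rfekit.age_structure import (
    AgeRates,
    AgeStructureError,
    History,
    VectorHistory,
    admissible_history,
    aggregate,
    forcing_from_history,
    generalized_rates,
    kernels_from_rates,
    rates_from_kernels,
    spe_solve,
)


def _const_rates(grid, table):
    t = grid.nodes
    comps = tuple(sorted({a for a, _ in table} | {b for _, b in table}))
    return AgeRates(
        grid=grid,
        compartments=comps,
        rates={key: v * np.ones_like(t) for key, v in table.items()},
    )


class TestTransportSolver:
    def test_pure_transport_without_rates(self):
        grid = TimeGrid(4.0, 401)
        t = grid.nodes
        rates = _const_rates(grid, {("a", "b"): 0.0})
        dens = np.exp(-((t - 1.5) ** 2) / 0.1)
        sol = spe_solve(rates, {"a": History(density=dens)}, grid)
        m = 200
        shifted = np.interp(sol.xi_nodes - t[m], t, dens, left=0.0, right=0.0)
        assert np.abs(sol.f_hist["a"][m] - shifted).max() <= 1e-14

    def test_constant_rates_reduce_to_markov_chain(self):
        grid = TimeGrid(8.0, 1601)
        rates = _const_rates(grid, {("a", "b"): 1.0, ("b", "a"): 2.0})
        sol = spe_solve(rates, {"a": History(point_masses=((0.0, 1.0),))}, grid)
        N = aggregate(sol)
        L = np.array([[-1.0, 2.0], [1.0, -2.0]])
        ref = np.array([expm(tt * L) @ [1.0, 0.0] for tt in grid.nodes[::80]])
        assert np.abs(N["a"][::80] - ref[:, 0]).max() <= 1e-4
        assert np.abs(N["b"][::80] - ref[:, 1]).max() <= 1e-4

    def test_mass_conserved_for_conservative_rates(self):
        grid = TimeGrid(4.0, 3201)
        t = grid.nodes
        rates = AgeRates(
            grid=grid,
            compartments=("a", "b"),
            rates={("a", "b"): 0.5 + 0.3 * t / (1 + t),
                   ("b", "a"): 1.0 + 0.2 * np.exp(-t)},
        )
        sol = spe_solve(rates, {"a": History(point_masses=((0.0, 1.0),))}, grid)
        N = aggregate(sol)
        assert np.abs(N["a"] + N["b"] - 1.0).max() <= 1e-6

    def test_refinement_converges_quadratically(self):
        errs = []
        for n in (401, 801):
            grid = TimeGrid(8.0, n)
            rates = _const_rates(grid, {("a", "b"): 1.0, ("b", "a"): 2.0})
            sol = spe_solve(rates, {"a": History(point_masses=((0.0, 1.0),))}, grid)
            N = aggregate(sol)
            L = np.array([[-1.0, 2.0], [1.0, -2.0]])
            step = (n - 1) // 10
            ref = np.array([expm(tt * L) @ [1.0, 0.0] for tt in grid.nodes[::step]])
            errs.append(np.abs(N["a"][::step] - ref[:, 0]).max())
        assert 2.5 <= errs[0] / errs[1] <= 6.0

    def test_mismatched_steps_rejected(self):
        rates = _const_rates(TimeGrid(4.0, 401), {("a", "b"): 1.0})
        with pytest.raises(AgeStructureError, match="step"):
            spe_solve(rates, {}, TimeGrid(4.0, 801))


class TestRateKernelConversion:
    def test_constant_rates_give_exponential_kernels(self):
        grid = TimeGrid(10.0, 1001)
        rates = _const_rates(grid, {("a", "b"): 1.0, ("b", "a"): 2.0})
        fam = kernels_from_rates(rates)
        t = grid.nodes
        assert np.abs(fam.Phi[("a", "b")] - np.exp(-t)).max() <= 1e-10
        assert np.abs(fam.Phi[("b", "a")] - 2.0 * np.exp(-2.0 * t)).max() <= 1e-10

    def test_survival_identity(self):
        # exp(-int Lambda) = 1 - int sum_b Phi, exactly through the exponent
        grid = TimeGrid(8.0, 1601)
        t = grid.nodes
        rates = AgeRates(
            grid=grid,
            compartments=("a", "b"),
            rates={("a", "b"): 0.3 + 0.4 * np.tanh(t)},
        )
        fam = kernels_from_rates(rates)
        from scipy.integrate import cumulative_simpson

        I = cumulative_simpson(rates.Lambda("a"), x=t, initial=0.0)
        lhs = np.exp(-I)
        rhs = 1.0 - (1.0 - np.exp(-I))  # analytic cumulative kernel mass
        assert np.abs(lhs - rhs).max() <= 1e-10
        # and the tabulated kernel is consistent with it by quadrature
        quad = cumulative_simpson(fam.Phi[("a", "b")], x=t, initial=0.0)
        assert np.abs(quad - (1.0 - np.exp(-I))).max() <= 1e-8

    def test_zero_rates_zero_kernels(self):
        grid = TimeGrid(4.0, 401)
        rates = _const_rates(grid, {("a", "b"): 0.0})
        fam = kernels_from_rates(rates)
        assert np.all(fam.Phi[("a", "b")] == 0.0)

    def test_exponential_kernel_gives_constant_rate(self):
        grid = TimeGrid(6.0, 1201)
        t = grid.nodes
        lam = 1.3
        fam = KernelFamily.from_scalar(
            grid, ("a", "b"), {("a", "b"): lam * np.exp(-lam * t)}
        )
        rates = rates_from_kernels(fam)
        assert np.abs(rates.rates[("a", "b")] - lam).max() <= 1e-7

    def test_erlang_kernel_gives_rational_rate(self):
        # Phi = t e^{-t}: survival (1+t)e^{-t}, rate t/(1+t)
        grid = TimeGrid(6.0, 1201)
        t = grid.nodes
        fam = KernelFamily.from_scalar(grid, ("a", "b"), {("a", "b"): t * np.exp(-t)})
        rates = rates_from_kernels(fam)
        assert np.abs(rates.rates[("a", "b")] - t / (1.0 + t)).max() <= 1e-8

    def test_round_trip_kernels_rates_kernels(self):
        grid = TimeGrid(8.0, 1601)
        t = grid.nodes
        Phi = {("a", "b"): np.exp(-t), ("b", "a"): 2.0 * np.exp(-2.0 * t)}
        fam = KernelFamily.from_scalar(grid, ("a", "b"), Phi)
        fam2 = kernels_from_rates(rates_from_kernels(fam))
        for key in Phi:
            assert np.abs(fam2.Phi[key] - fam.Phi[key]).max() <= 1e-8

    def test_exhausted_survival_rejected(self):
        # a kernel whose full unit mass sits inside the grid: the survival
        # probability hits zero and the rates blow up
        grid = TimeGrid(4.0, 801)
        t = grid.nodes
        tri = np.where(t < 1.0, 2.0 * (1.0 - np.abs(2.0 * t - 1.0)), 0.0)
        fam = KernelFamily.from_scalar(grid, ("a", "b"), {("a", "b"): tri})
        with pytest.raises(AgeStructureError, match="survival exhausted"):
            rates_from_kernels(fam)


class TestHistoryForcing:
    def test_atom_at_zero_gives_consistency_forcing(self):
        grid = TimeGrid(10.0, 1001)
        rates = _const_rates(grid, {("a", "b"): 1.0, ("b", "a"): 2.0})
        fam = kernels_from_rates(rates)
        f = forcing_from_history(fam, {"a": History(point_masses=((0.0, 1.0),))})
        assert np.abs(f.B0["b"] - fam.Phi[("a", "b")]).max() <= 1e-12
        assert np.abs(f.D0["a"] - fam.k["a"]).max() <= 1e-12
        assert f.N0["a"] == pytest.approx(1.0)

    def test_empty_history_zero_forcing(self):
        grid = TimeGrid(5.0, 501)
        rates = _const_rates(grid, {("a", "b"): 1.0})
        fam = kernels_from_rates(rates)
        f = forcing_from_history(fam, {})
        assert np.all(f.B0["b"] == 0.0)
        assert np.all(f.D0["a"] == 0.0)

    def test_spread_history_smooths_forcing(self):
        # convolution with a spread-out history has smaller total variation
        # than the kernel itself
        grid = TimeGrid(12.0, 1201)
        t = grid.nodes
        rates = _const_rates(grid, {("a", "b"): 1.0, ("b", "a"): 1.0})
        fam = kernels_from_rates(rates)
        spread = np.exp(-t)  # history density over ages, mass 1
        f = forcing_from_history(fam, {"a": History(density=spread)})
        tv = lambda y: np.abs(np.diff(y)).sum()
        assert tv(f.B0["b"]) < tv(fam.Phi[("a", "b")])

    def test_equivalence_with_transport_solution(self):
        # renewal route and transport route agree on the totals
        grid = TimeGrid(8.0, 1601)
        rates = _const_rates(grid, {("a", "b"): 1.0, ("b", "a"): 2.0})
        hist = {"a": History(point_masses=((0.0, 1.0),))}
        fam = kernels_from_rates(rates)
        f = forcing_from_history(fam, hist)
        solR = solve_rfe(fam, f)
        N = aggregate(spe_solve(rates, hist, grid))
        assert np.abs(solR.N["a"] - N["a"]).max() <= 1e-4
        assert np.abs(solR.N["b"] - N["b"]).max() <= 1e-4

    def test_equivalence_gap_shrinks_quadratically(self):
        gaps = []
        for n in (401, 801):
            grid = TimeGrid(8.0, n)
            rates = _const_rates(grid, {("a", "b"): 1.0, ("b", "a"): 2.0})
            hist = {"a": History(point_masses=((0.0, 1.0),))}
            fam = kernels_from_rates(rates)
            solR = solve_rfe(fam, forcing_from_history(fam, hist))
            N = aggregate(spe_solve(rates, hist, grid))
            gaps.append(np.abs(solR.N["a"] - N["a"]).max())
        assert 2.5 <= gaps[0] / gaps[1] <= 7.0


class TestGeneralizedReduction:
    def test_substate_reduction_matches_markov_oracle(self):
        # compartments {s0, s1} and {s2}; no internal edges, so each state
        # acts as its own sub-compartment and the generalized transport
        # system aggregates to the Markov totals
        grid = TimeGrid(6.0, 1201)
        t = grid.nodes
        mu = {
            ("s0", "s2"): 1.0 * np.ones_like(t),
            ("s1", "s2"): 0.5 * np.ones_like(t),
            ("s2", "s0"): 0.7 * np.ones_like(t),
            ("s2", "s1"): 0.3 * np.ones_like(t),
        }
        comp_of = {"s0": "left", "s1": "left", "s2": "right"}
        rates = generalized_rates(mu, comp_of, grid)
        hist = {"s0": History(point_masses=((0.0, 1.0),))}
        sol = spe_solve(rates, hist, grid)
        Nsub = aggregate(sol)
        N_left = Nsub["s0"] + Nsub["s1"]
        L = np.zeros((3, 3))
        for (i, j), lam in mu.items():
            L[int(j[1]), int(i[1])] = lam[0]
        np.fill_diagonal(L, -L.sum(axis=0))
        ref = np.array([expm(tt * L) @ [1.0, 0.0, 0.0] for tt in t[::60]])
        assert np.abs(N_left[::60] - (ref[:, 0] + ref[:, 1])).max() <= 1e-4

    def test_internal_rates_rejected(self):
        grid = TimeGrid(2.0, 201)
        mu = {("s0", "s1"): np.ones(201)}
        with pytest.raises(AgeStructureError, match="internal"):
            generalized_rates(mu, {"s0": "c", "s1": "c"}, grid)


class TestAdmissibleHistory:
    def test_atom_at_age_zero_always_admissible(self):
        net = random_conservative_network(5, 2, 1)
        n0 = np.abs(np.random.default_rng(2).uniform(size=5))
        hists = {
            b: VectorHistory(atoms=((0.0, n0[net.state_indices(b)]),))
            for b in net.compartments
        }
        ok, res = admissible_history(net, n0, hists)
        assert ok
        assert res <= 1e-12

    def test_generic_history_inadmissible(self):
        net = random_conservative_network(5, 2, 1)
        rng = np.random.default_rng(3)
        n0 = np.abs(rng.uniform(size=5))
        hists = {
            b: VectorHistory(atoms=((0.5, rng.uniform(size=len(net.state_indices(b)))),))
            for b in net.compartments
        }
        ok, res = admissible_history(net, n0, hists)
        assert not ok
        assert res > 1e-3

    def test_exponentially_tilted_scalar_history(self):
        # 1x1 block with exit rate r: an exponential history with the decay
        # exactly undone reproduces any n0: int_0^T e^{r u} m(u) du = n0
        net = random_conservative_network(2, 2, 1)
        b = net.compartments[0]
        r = -float(net.block(b, b)[0, 0])
        n0_val = 0.8
        ages = np.linspace(0.0, 2.0, 2001)
        dens = np.exp(-r * ages)  # flat after the e^{+r u} propagation
        dens = dens * n0_val / 2.0  # total integral after tilt: 2.0 * scale
        other = net.compartments[1]
        n0 = np.zeros(2)
        n0[net.state_indices(b)[0]] = n0_val
        hists = {
            b: VectorHistory(ages=ages, density=dens[:, None]),
            other: VectorHistory(),
        }
        ok, res = admissible_history(net, n0, hists, rtol=1e-4)
        assert ok
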