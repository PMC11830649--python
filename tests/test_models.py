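import numpy as np
import pytest

from rfekit import TimeGrid, check_detailed_balance, validate_rate_matrix
from rfekit.models import (
    AdaptationKernel,
    HopfieldParams,
    SignalFunction,
    adaptation_output,
    adaptation_response,
    c1ffl_limit_response,
    c1ffl_response,
    hopfield_network,
    hopfield_response,
    hopfield_total_production,
    linear_polymerization,
    mean_production_time,
    nonlinear_polymerization,
    production_ratio,
)


class TestHopfield:
    def test_network_structure(self):
        net = hopfield_network(HopfieldParams.scaling_preset())
        assert net.compartments == ("complex", "product")
        # empty and P are absorbing
        A = net.rate_matrix.A
        for sink in ("empty", "P"):
            j = net.states.index(sink)
            assert A[:, j].max() == 0.0

    def test_impulse_response_mass_without_degradation(self):
        # with mu = 0 every substrate molecule eventually makes product
        p = HopfieldParams.scaling_preset()
        total = hopfield_total_production(p, mu=0.0)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_response_decays_and_is_nonnegative(self):
        p = HopfieldParams.scaling_preset(eps=0.01, s=0.5)
        grid = TimeGrid(2000.0, 4001)
        phi = hopfield_response(p, grid)
        assert phi.min() >= 0.0
        assert phi[-1] < phi[np.argmax(phi)] * 0.1

    def test_zero_catalysis_zero_response(self):
        p = HopfieldParams(lam=0.0)
        phi = hopfield_response(p, TimeGrid(10.0, 101))
        assert np.all(phi == 0.0)

    def test_identical_substrates_ratio_one(self):
        p = HopfieldParams(alpha=0.1, beta=0.01, lam=1e-3, mu=0.05, Q=100.0,
                           e_E1=2.0, e_E2=40.0, e_E1_bar=2.0)
        assert production_ratio(p) == pytest.approx(1.0, rel=1e-10)

    def test_ratio_bounded_below_by_squared_discrimination(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = HopfieldParams(
                alpha=10.0 ** rng.uniform(-3, -1),
                beta=10.0 ** rng.uniform(-5, -2),
                lam=10.0 ** rng.uniform(-5, -3),
                mu=10.0 ** rng.uniform(-3, -1),
                Q=10.0 ** rng.uniform(1, 5),
                e_E1=rng.uniform(1.5, 4.0),
                e_E2=10.0 ** rng.uniform(1, 3),
                e_E1_bar=None,
            )
            p = HopfieldParams(**{**p.__dict__, "e_E1_bar": p.e_E1 * rng.uniform(2.0, 8.0)})
            r = production_ratio(p)
            assert r >= p.theta**2 * (1.0 - 1e-12)

    def test_ratio_approaches_squared_discrimination_in_scaling_limit(self):
        gaps = []
        for eps in (1e-2, 1e-3, 1e-4):
            p = HopfieldParams.scaling_preset(eps=eps, s=0.5)
            r = production_ratio(p)
            gaps.append(r / p.theta**2 - 1.0)
        assert all(g > 0 for g in gaps)
        assert gaps[2] < gaps[1] < gaps[0]
        assert gaps[2] < 0.01

    def test_time_unit_invariance_of_ratio(self):
        # rescaling every rate (time unit change, k -> 1) leaves the
        # discrimination ratio unchanged
        p = HopfieldParams(k=2.0, alpha=0.02, beta=2e-4, lam=4e-4, mu=0.02,
                           Q=1e4, e_E1=2.0, e_E2=400.0, e_E1_bar=8.0)
        q = HopfieldParams(k=1.0, alpha=0.01, beta=1e-4, lam=2e-4, mu=0.01,
                           Q=1e4, e_E1=2.0, e_E2=400.0, e_E1_bar=8.0)
        assert production_ratio(p) == pytest.approx(production_ratio(q), rel=1e-10)

    def test_mean_production_time_moment_identity(self):
        # T = int t Phi dt when int Phi = 1: check against quadrature of
        # the impulse response (independent route)
        from rfekit.models import _core_generator

        p = HopfieldParams(alpha=0.1, beta=0.05, lam=0.2, mu=0.0, Q=50.0,
                           e_E1=3.0, e_E2=30.0)
        T = mean_production_time(p)
        slowest = float(np.min(-np.linalg.eigvals(_core_generator(p, mu=0.0)).real))
        grid = TimeGrid(40.0 / slowest, 80001)
        phi = hopfield_response(p, grid)
        from scipy.integrate import simpson

        T_quad = simpson(grid.nodes * phi, x=grid.nodes)
        assert T == pytest.approx(T_quad, rel=1e-5)

    def test_speed_ratio_under_separated_scales(self):
        # T / Tbar ~ theta^2 once the dominant production channel is
        # C -> S -> S* with the direct C -> S* route negligible:
        # beta e^{E1} << alpha << e^{E1}, lam << beta eta e^{E1},
        # alpha/Q << beta e^{E1}, e^{E1} >> 1
        p = HopfieldParams(k=1.0, alpha=1e-2, beta=1e-6, lam=1e-6, mu=0.0,
                           Q=1e8, e_E1=50.0, e_E2=5000.0, e_E1_bar=200.0)
        T = mean_production_time(p, cross_check_tol=1e-3)
        Tbar = mean_production_time(p.barred(), cross_check_tol=1e-3)
        assert T / Tbar == pytest.approx(p.theta**2, rel=0.15)


class TestAdaptation:
    def test_printed_coefficients_for_a2_b3(self):
        k = adaptation_response(2.0, 3.0)
        assert (k.lam_plus, k.lam_minus) == (-1.0, -2.0)
        assert (k.C_plus, k.C_minus) == (-3.0, 6.0)
        assert k(0.0) == pytest.approx(3.0)

    def test_kernel_starts_at_b(self):
        for a, b in ((1.0, 3.0), (0.5, 2.0), (3.0, 4.0)):
            k = adaptation_response(a, b)
            assert k(0.0) == pytest.approx(b, rel=1e-12)

    def test_zero_total_integral(self):
        rng = np.random.default_rng(1)
        from scipy.integrate import simpson

        for _ in range(5):
            b = rng.uniform(1.0, 5.0)
            a = rng.uniform(0.3, 0.9) * b * b / 4.0
            k = adaptation_response(a, b)
            assert abs(k.integral) <= 1e-10
            t = np.linspace(0.0, 40.0 / -k.lam_plus, 400001)
            assert abs(simpson(k(t), x=t)) <= 1e-10

    def test_oscillatory_regime_rejected(self):
        with pytest.raises(ValueError, match="b\\^2 > 4a"):
            adaptation_response(4.0, 2.0)

    def test_constant_signal_returns_to_setpoint(self):
        k = adaptation_response(2.0, 3.0)
        X = adaptation_output(k, SignalFunction.constant(7.0), TimeGrid(25.0, 2501))
        assert X[0] == pytest.approx(1.0)
        assert X.max() > 1.1  # transient excursion
        assert abs(X[-1] - 1.0) <= 1e-4  # perfect adaptation


@pytest.fixture(scope="module")
def front_result():
    grid = TimeGrid(60.0, 3001)
    t = grid.nodes
    psi = t * np.exp(-t)  # Erlang-2, mean step time 2
    return linear_polymerization(psi, L_max=22, grid=grid)


class TestLinearPolymerization:

    def test_mean_step_time(self, front_result):
        assert front_result.mean_step == pytest.approx(2.0, rel=1e-6)

    def test_sizes_plateau_at_mean(self, front_result):
        # n_ell(t) -> mu for t >> ell * mu
        assert front_result.n[4, -1] == pytest.approx(2.0, rel=1e-3)
        assert front_result.n[9, -1] == pytest.approx(2.0, rel=1e-3)

    def test_front_positions_advance_linearly(self, front_result):
        ft = front_result.front_times
        ells = np.arange(1, len(ft) + 1)
        ok = ~np.isnan(ft)
        slope = np.polyfit(ells[ok][5:], ft[ok][5:], 1)[0]
        assert slope == pytest.approx(2.0, rel=0.05)

    def test_front_speed_near_reciprocal_mean(self, front_result):
        assert front_result.front_speed == pytest.approx(0.5, rel=0.05)

    def test_narrow_kernel_gives_sharp_front(self):
        grid = TimeGrid(30.0, 3001)
        t = grid.nodes
        # narrow Gamma kernel, mean 1, sd 0.1
        from scipy import stats

        psi = stats.gamma.pdf(t, a=100, scale=0.01)
        res = linear_polymerization(psi, L_max=15, grid=grid)
        assert res.front_times[9] == pytest.approx(10.0, abs=0.5)

    def test_nonunit_mass_rejected(self):
        grid = TimeGrid(10.0, 101)
        with pytest.raises(ValueError, match="integrate to 1"):
            linear_polymerization(np.ones(101), 5, grid)


class TestC1FFL:
    def test_ode_and_kernel_routes_agree(self):
        grid = TimeGrid(3.0, 301)
        res = c1ffl_response(5.0, 1.0, 5.0, SignalFunction.step_on(0.0), grid)
        assert np.abs(res.Z_ode - res.Z_kernel).max() <= 1e-4

    def test_agreement_improves_under_refinement(self):
        errs = []
        for n in (151, 301):
            grid = TimeGrid(3.0, n)
            res = c1ffl_response(5.0, 1.0, 5.0, SignalFunction.step_on(0.0), grid)
            errs.append(np.abs(res.Z_ode - res.Z_kernel).max())
        assert errs[1] < errs[0]

    def test_zero_signal_zero_output(self):
        grid = TimeGrid(2.0, 101)
        res = c1ffl_response(5.0, 1.0, 5.0, SignalFunction.constant(0.0), grid)
        assert np.all(res.Z_ode == 0.0)
        assert np.all(res.Z_kernel == 0.0)

    def test_limit_model_step_on_saturates(self):
        grid = TimeGrid(10.0, 1001)
        xi = c1ffl_limit_response(SignalFunction.step_on(0.0), grid)
        t = grid.nodes
        assert np.abs(xi - (1.0 - np.exp(-t))).max() <= 1e-6
        assert xi[-1] == pytest.approx(1.0, abs=1e-4)

    def test_limit_model_step_off_drops_instantly(self):
        grid = TimeGrid(10.0, 1001)
        t_bar = 2.0
        xi = c1ffl_limit_response(SignalFunction.step_off(t_bar), grid)
        after = grid.nodes > t_bar
        assert np.all(xi[after] == 0.0)
        before = grid.nodes <= t_bar
        assert xi[before].max() > 0.9  # response was on before removal


class TestNonlinearPolymerization:
    def test_mass_accounting_tracks_source(self):
        grid = TimeGrid(8.0, 801)
        t = grid.nodes
        psi = 4.0 * t * np.exp(-2.0 * t)
        res = nonlinear_polymerization(
            psi, SignalFunction.constant(0.5), L_max=8, grid=grid
        )
        assert res.mass_residual <= 1e-4
        assert res.boundary_flux <= 1e-3  # truncation hardly reached

    def test_zero_data_stays_zero(self):
        grid = TimeGrid(4.0, 401)
        t = grid.nodes
        psi = 4.0 * t * np.exp(-2.0 * t)
        res = nonlinear_polymerization(
            psi, SignalFunction.constant(0.0), L_max=5, grid=grid
        )
        assert np.all(res.n == 0.0)
        assert np.all(res.w == 0.0)

    def test_delta_like_kernel_recovers_markovian_growth(self):
        # a very narrow maturation kernel makes attachment effectively
        # instantaneous: compare with the ODE chain where w is slaved
        from scipy import stats
        from scipy.integrate import solve_ivp

        grid = TimeGrid(6.0, 1201)
        t = grid.nodes
        psi = stats.gamma.pdf(t, a=400, scale=0.0001)  # mean 0.04, tiny sd
        L = 6
        res = nonlinear_polymerization(psi, SignalFunction.constant(0.5), L, grid)

        def rhs(_, y):
            n = np.concatenate([[0.0], y])  # index by size, n[1]..n[L]
            dn = np.zeros(L + 1)
            n1 = n[1]
            for l in range(2, L + 1):
                attach = n1 * n[l] if l < L else 0.0
                shed_in = n[l + 1] if l + 1 <= L else 0.0
                dn[l] = -attach + shed_in - n[l] + n1 * n[l - 1]
            attach_sum = sum(n1 * n[l] for l in range(2, L))
            shed_sum = sum(n[l + 1] for l in range(2, L) )
            dn[1] = 2.0 * n[2] - attach_sum - 2.0 * n1 * n1 + shed_sum + 0.5
            return dn[1:]

        sol = solve_ivp(rhs, (0.0, 6.0), np.zeros(L), t_eval=t, rtol=1e-8,
                        atol=1e-10)
        assert np.abs(res.n1 - sol.y[0]).max() <= 0.05
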