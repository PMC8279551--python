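import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pelkit.constants import KB, PLANCK
from pelkit.ktn import KineticTransitionNetwork, Minimum, TransitionState
from pelkit.synthetic import (
    FunnelParams,
    FunnelSpec,
    analytic_two_state,
    generate_ktn,
    two_state_network,
)
from pelkit.thermo import (
    DomainError,
    delta_f,
    free_energies,
    heat_capacity,
    heat_capacity_numerical,
    ln_z_ts,
    populations,
    z_min,
    z_ts,
)


def _net(*minima):
    net = KineticTransitionNetwork()
    for m in minima:
        net.add_minimum_record(m)
    return net


class TestBasinPartitionFunction:
    def test_unit_value_at_matched_frequency(self):
        # V=0, n_iso=1, kappa=1, nu = k_B T / h  ->  Z = 1
        T = 300.0
        nu = KB * T / PLANCK
        m = Minimum(V=0.0, nu_bar=nu, kappa=1)
        assert z_min(m, T) == pytest.approx(1.0)

    def test_linear_in_isomer_count(self):
        m1 = Minimum(V=1.0, nu_bar=1e13, kappa=5, n_iso=1)
        m2 = Minimum(V=1.0, nu_bar=1e13, kappa=5, n_iso=2)
        assert z_min(m2, 300.0) == pytest.approx(2.0 * z_min(m1, 300.0))

    def test_boltzmann_ratio_at_unit_kbt(self):
        # kB T = 1 kcal/mol at T = 1/KB; dV = 1 -> ratio e^-1
        T = 1.0 / KB
        a = Minimum(V=0.0, nu_bar=1e13, kappa=5)
        b = Minimum(V=1.0, nu_bar=1e13, kappa=5)
        assert z_min(b, T) / z_min(a, T) == pytest.approx(math.exp(-1.0))

    def test_nonpositive_temperature_rejected(self):
        m = Minimum(V=0.0, nu_bar=1e13, kappa=3)
        with pytest.raises(DomainError):
            z_min(m, 0.0)

    def test_ts_partition_function_excludes_imaginary_mode(self):
        t = TransitionState(V=2.0, nu_bar_real=1e13, min_a=0, min_b=0)
        # kappa = 1: empty real-mode product -> Z = n exp(-V/kbt)
        T = 350.0
        assert z_ts(t, 1, T) == pytest.approx(math.exp(-2.0 / (KB * T)))
        # shared kernel: matches a fictitious minimum with kappa-1 modes
        m = Minimum(V=2.0, nu_bar=1e13, kappa=4)
        assert z_ts(t, 5, T) == pytest.approx(z_min(m, T))

    def test_ts_free_energy_increases_with_v(self):
        T = 300.0
        f = [
            -KB * T * ln_z_ts(
                TransitionState(V=v, nu_bar_real=1e13, min_a=0, min_b=0), 5, T
            )
            for v in (1.0, 2.0, 3.0)
        ]
        assert f[0] < f[1] < f[2]


class TestPopulations:
    def test_single_minimum(self):
        net = _net(Minimum(V=-3.0, nu_bar=1e13, kappa=5))
        assert populations(net, 200.0) == {0: pytest.approx(1.0)}

    def test_two_identical_minima_split_evenly(self):
        net = _net(*(Minimum(V=1.0, nu_bar=1e13, kappa=5) for _ in range(2)))
        p = populations(net, 250.0)
        assert p[0] == pytest.approx(0.5)
        assert p[1] == pytest.approx(0.5)

    def test_unit_kbt_gap_gives_logistic_populations(self):
        T = 1.0 / KB
        net = _net(
            Minimum(V=0.0, nu_bar=1e13, kappa=5),
            Minimum(V=1.0, nu_bar=1e13, kappa=5),
        )
        p = populations(net, T)
        assert p[0] == pytest.approx(0.7310585786300049)
        assert p[1] == pytest.approx(0.2689414213699951)

    def test_stable_for_huge_gaps_at_low_temperature(self):
        # a ~13 kcal/mol gap at 10 K would overflow naive exponentials
        net = _net(
            Minimum(V=0.0, nu_bar=1e13, kappa=51),
            Minimum(V=13.0, nu_bar=1e13, kappa=51),
        )
        p = populations(net, 10.0)
        assert p[0] == pytest.approx(1.0)
        assert p[1] >= 0.0
        f = free_energies(net, 10.0)
        assert np.isfinite(list(f.values())).all()

    @settings(deadline=None, max_examples=30)
    @given(
        vs=st.lists(st.floats(-5, 25), min_size=1, max_size=15),
        t=st.floats(5.0, 1000.0),
    )
    def test_normalization_property(self, vs, t):
        net = _net(*(Minimum(V=v, nu_bar=1e13, kappa=7) for v in vs))
        assert sum(populations(net, t).values()) == pytest.approx(1.0, abs=1e-12)


class TestDeltaF:
    def test_identical_singleton_groups_zero(self):
        net = _net(
            Minimum(V=0.7, nu_bar=1e13, kappa=5),
            Minimum(V=0.7, nu_bar=1e13, kappa=5),
        )
        assert delta_f(net, {0}, {1}, 300.0) == pytest.approx(0.0)

    def test_antisymmetry(self):
        net = generate_ktn(FunnelSpec(funnels=[FunnelParams(8)], rng_seed=2))
        a = set(list(net.minima)[:3])
        b = set(list(net.minima)[3:6])
        assert delta_f(net, a, b, 300.0) == -delta_f(net, b, a, 300.0)

    def test_low_temperature_limit_is_potential_gap(self):
        net = _net(
            Minimum(V=0.0, nu_bar=2e13, kappa=5),
            Minimum(V=1.3, nu_bar=0.5e13, kappa=5),
        )
        assert delta_f(net, {0}, {1}, 0.5) == pytest.approx(1.3, abs=1e-2)

    def test_entropic_gap_formula_for_frequency_ratio(self):
        # equal V, frequency ratio r, equal kappa: dF = kappa kB T ln r
        r, kappa, T = 1.7, 9, 320.0
        net = _net(
            Minimum(V=2.0, nu_bar=1e13, kappa=kappa),
            Minimum(V=2.0, nu_bar=1e13 * r, kappa=kappa),
        )
        assert delta_f(net, {0}, {1}, T) == pytest.approx(
            kappa * KB * T * math.log(r)
        )

    def test_rejects_overlapping_or_empty_groups(self):
        net = _net(Minimum(V=0.0, nu_bar=1e13, kappa=5))
        with pytest.raises(ValueError):
            delta_f(net, {0}, {0}, 300.0)
        with pytest.raises(ValueError):
            delta_f(net, set(), {0}, 300.0)


class TestHeatCapacity:
    def test_single_minimum_is_classical_equipartition(self):
        kappa = 12
        net = _net(Minimum(V=0.0, nu_bar=1e13, kappa=kappa))
        res = heat_capacity(net, np.arange(50.0, 500.0, 50.0))
        assert np.allclose(res.Cv, kappa * KB)

    def test_two_state_anomaly_peaks_near_x_2p40(self):
        # degenerate frequencies, gap dV: excess Cv = kB x^2 e^x/(1+e^x)^2
        # maximized at x = dV / kB T ~= 2.3994 (two-state oracle)
        dv = 1.0
        oracle = analytic_two_state(dv, 1.0, 5)
        t_star = oracle.cv_peak_temperature()
        assert dv / (KB * t_star) == pytest.approx(2.3994, abs=1e-3)
        net = _net(
            Minimum(V=0.0, nu_bar=1e13, kappa=5),
            Minimum(V=dv, nu_bar=1e13, kappa=5),
        )
        grid = np.arange(50.0, 500.0, 1.0)
        res = heat_capacity(net, grid)
        assert len(res.peaks_T) == 1
        assert res.peaks_T[0] == pytest.approx(t_star, abs=1.0)
        # and the excess over equipartition matches the closed form
        i = np.argmin(np.abs(grid - t_star))
        assert res.Cv[i] - 5 * KB == pytest.approx(
            oracle.cv_excess(grid[i]), rel=1e-9
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_numerical_lnz_derivative(self, seed):
        net = generate_ktn(
            FunnelSpec(
                funnels=[FunnelParams(10), FunnelParams(5, offset=2.0)],
                rng_seed=seed,
                kappa=30,
            )
        )
        for T in (80.0, 298.0):
            cv = heat_capacity(net, np.array([T - 1, T, T + 1])).Cv[1]
            assert cv == pytest.approx(heat_capacity_numerical(net, T), rel=1e-6)

    def test_grid_validation(self):
        net = _net(Minimum(V=0.0, nu_bar=1e13, kappa=3))
        with pytest.raises(ValueError):
            heat_capacity(net, np.array([100.0, 50.0, 200.0]))
        with pytest.raises(ValueError):
            heat_capacity(net, np.array([100.0, 200.0]))

    def test_high_temperature_populations_follow_frequency_entropy(self):
        # T -> inf with equal kappa: p_i proportional to n_i / nu_bar^kappa
        net = _net(
            Minimum(V=0.0, nu_bar=1e13, kappa=4, n_iso=1),
            Minimum(V=5.0, nu_bar=0.5e13, kappa=4, n_iso=2),
        )
        p = populations(net, 1e7)
        expect = np.array([1.0, 2.0 * 2.0**4])
        expect /= expect.sum()
        assert p[0] == pytest.approx(expect[0], rel=1e-3)
        assert p[1] == pytest.approx(expect[1], rel=1e-3)
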