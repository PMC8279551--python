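import math

import numpy as np
import pytest

from pelkit.constants import KB
from pelkit.kinetics import (
    RateNetwork,
    mfpt_linear_solve,
    phenomenological_rates,
    rate_scan,
    tst_rate,
)
from pelkit.ktn import IntegrityError, KineticTransitionNetwork, Minimum, TransitionState
from pelkit.synthetic import FunnelParams, FunnelSpec, analytic_two_state, generate_ktn, two_state_network
from pelkit.thermo import populations


def _chain(energies, barriers, kappa=10, nu=1e13):
    net = KineticTransitionNetwork()
    for v in energies:
        net.add_minimum_record(Minimum(V=v, nu_bar=nu, kappa=kappa))
    for i, b in enumerate(barriers):
        v_ts = max(energies[i], energies[i + 1]) + b
        net.add_ts_record(
            TransitionState(V=v_ts, nu_bar_real=nu, min_a=i, min_b=i + 1)
        )
    return net


class TestElementaryRates:
    def test_prefactor_only_limit(self):
        m = Minimum(V=0.0, nu_bar=1e12, kappa=1)
        t = TransitionState(V=0.0, nu_bar_real=1e13, min_a=0, min_b=1)
        # kappa=1: rate = nu_bar^1 / nu_ts^0 = 1e12 regardless of nu_ts
        assert tst_rate(m, t, 300.0) == pytest.approx(1e12)

    def test_arrhenius_factor(self):
        T = 250.0
        m = Minimum(V=0.0, nu_bar=1e13, kappa=5)
        t1 = TransitionState(V=2.0, nu_bar_real=1e13, min_a=0, min_b=1)
        t2 = TransitionState(V=4.0, nu_bar_real=1e13, min_a=0, min_b=1)
        ratio = tst_rate(m, t2, T) / tst_rate(m, t1, T)
        assert ratio == pytest.approx(math.exp(-2.0 / (KB * T)))

    def test_symmetric_double_well_rates_equal(self):
        net = _chain([0.0, 0.0], [3.0])
        rn = RateNetwork.from_network(net, 300.0)
        assert rn.rates[0][1] == pytest.approx(rn.rates[1][0])

    def test_two_routes_agree(self):
        m = Minimum(V=-1.0, nu_bar=3.3e13, kappa=17, n_iso=2)
        t = TransitionState(V=4.2, nu_bar_real=2.8e13, min_a=0, min_b=1, n_iso=3)
        for T in (120.0, 298.0, 700.0):
            assert tst_rate(m, t, T, route="frequency") == pytest.approx(
                tst_rate(m, t, T, route="partition"), rel=1e-12
            )

    def test_saddle_below_minimum_rejected(self):
        m = Minimum(V=5.0, nu_bar=1e13, kappa=5)
        t = TransitionState(V=4.0, nu_bar_real=1e13, min_a=0, min_b=1)
        with pytest.raises(IntegrityError):
            tst_rate(m, t, 300.0)

    def test_detailed_balance_per_edge(self):
        net = generate_ktn(FunnelSpec(funnels=[FunnelParams(8)], rng_seed=7, kappa=15))
        T = 298.0
        rn = RateNetwork.from_network(net, T)
        p = populations(net, T)
        for i, out in rn.rates.items():
            for j, kij in out.items():
                assert kij * p[i] == pytest.approx(rn.rates[j][i] * p[j], rel=1e-10)

    def test_branching_probabilities_normalized(self):
        net = generate_ktn(FunnelSpec(funnels=[FunnelParams(8)], rng_seed=7, kappa=15))
        rn = RateNetwork.from_network(net, 298.0)
        for i in net.minima:
            assert sum(rn.branching[i].values()) == pytest.approx(1.0)


class TestGraphTransformation:
    def test_two_state_equals_summed_tst(self):
        oracle = analytic_two_state(1.0, 1.3, 8)
        net = two_state_network(oracle)
        # add a parallel saddle: rates must sum
        net.add_ts_record(
            TransitionState(V=4.0, nu_bar_real=1e13, min_a=0, min_b=1)
        )
        T = 298.0
        expect = sum(
            tst_rate(net.minima[0], t, T) for t in net.transition_states.values()
        )
        r = phenomenological_rates(net, {0}, {1}, T)
        assert r.k_AB == pytest.approx(expect, rel=1e-12)

    def test_linear_three_state_chain_matches_linear_solve(self):
        net = _chain([0.0, 1.0, 0.5], [2.0, 1.5])
        T = 298.0
        r = phenomenological_rates(net, {0}, {2}, T)
        assert r.mfpt_AB == pytest.approx(mfpt_linear_solve(net, {0}, {2}, T), rel=1e-8)
        assert r.mfpt_BA == pytest.approx(mfpt_linear_solve(net, {2}, {0}, T), rel=1e-8)

    @pytest.mark.parametrize("seed", range(50))
    def test_random_networks_match_linear_solve(self, seed):
        net = generate_ktn(
            FunnelSpec(
                funnels=[FunnelParams(10), FunnelParams(5, offset=1.0)],
                rng_seed=seed,
                kappa=20,
            )
        )
        ids = sorted(net.minima)
        A, B = {ids[0]}, {ids[-1], ids[-2]}
        T = 298.0
        r = phenomenological_rates(net, A, B, T)
        assert r.mfpt_AB == pytest.approx(mfpt_linear_solve(net, A, B, T), rel=1e-6)
        assert r.mfpt_BA == pytest.approx(mfpt_linear_solve(net, B, A, T), rel=1e-6)

    def test_global_detailed_balance(self):
        net = generate_ktn(
            FunnelSpec(funnels=[FunnelParams(9), FunnelParams(4, offset=1.5)], rng_seed=11, kappa=25)
        )
        ids = sorted(net.minima)
        A = set(ids[:4])
        B = set(ids[-3:])
        T = 320.0
        r = phenomenological_rates(net, A, B, T)
        p = populations(net, T)
        pa, pb = sum(p[a] for a in A), sum(p[b] for b in B)
        assert r.k_AB * pa == pytest.approx(r.k_BA * pb, rel=1e-8)

    def test_elimination_order_independence(self):
        net = generate_ktn(FunnelSpec(funnels=[FunnelParams(12)], rng_seed=3, kappa=20))
        ids = sorted(net.minima)
        A, B = {ids[0]}, {ids[-1]}
        base = phenomenological_rates(net, A, B, 298.0)
        rng = np.random.default_rng(0)
        inter = [i for i in ids if i not in A | B]
        for _ in range(5):
            order = list(inter)
            rng.shuffle(order)
            r = phenomenological_rates(net, A, B, 298.0, elimination_order=order)
            assert r.k_AB == pytest.approx(base.k_AB, rel=1e-9)
            assert r.mfpt_AB == pytest.approx(base.mfpt_AB, rel=1e-9)

    def test_self_loop_saddles_shorten_waits_but_not_passage_times(self):
        # degenerate rearrangements add unobservable self-transitions: the
        # per-visit waiting time shrinks, but revisits compensate exactly,
        # so first-passage observables are invariant
        net = _chain([0.0, 1.0], [2.0])
        r_plain = phenomenological_rates(net, {0}, {1}, 298.0)
        rn_plain = RateNetwork.from_network(net, 298.0)
        net.add_ts_record(
            TransitionState(V=1.0, nu_bar_real=1e13, min_a=0, min_b=0)
        )
        rn_loop = RateNetwork.from_network(net, 298.0)
        assert rn_loop.tau[0] < rn_plain.tau[0]
        assert rn_loop.self_loop_rate[0] > 0
        r_loop = phenomenological_rates(net, {0}, {1}, 298.0)
        assert r_loop.mfpt_AB == pytest.approx(r_plain.mfpt_AB, rel=1e-10)
        assert r_loop.k_AB == pytest.approx(r_plain.k_AB, rel=1e-10)

    def test_disconnected_macrostates_raise(self):
        net = KineticTransitionNetwork()
        for v in (0.0, 1.0):
            net.add_minimum_record(Minimum(V=v, nu_bar=1e13, kappa=5))
        from pelkit.kinetics import NoPathError

        with pytest.raises(NoPathError):
            phenomenological_rates(net, {0}, {1}, 298.0)


class TestRateScan:
    def test_two_state_arrhenius_line(self):
        # ln k vs 1/T is a straight line with slope -dV/kB
        net = _chain([0.0, 0.0], [3.0])
        grid = np.linspace(200.0, 400.0, 9)
        df = rate_scan(net, {0}, {1}, grid)
        x = 1.0 / grid
        slope = np.polyfit(x, np.log(df.k_AB.to_numpy()), 1)[0]
        assert slope == pytest.approx(-3.0 / KB, rel=1e-10)
        assert df.monotone.all()

    def test_microsecond_scale_for_seven_and_half_kcal_barrier(self):
        # a ~7.5 kcal/mol barrier with ~1e13 1/s prefactors relaxes on the
        # microsecond scale near room temperature
        net = _chain([0.0, 1.6], [7.5 - 1.6])  # saddle 7.5 above the lower well
        r = phenomenological_rates(net, {0}, {1}, 298.0)
        assert 1e-8 < r.mfpt_AB < 1e-4

    def test_uniform_frequency_scaling_leaves_branching_unchanged(self):
        net = _chain([0.0, 0.8, 0.3], [2.0, 1.1])
        rn1 = RateNetwork.from_network(net, 298.0)
        scaled = KineticTransitionNetwork()
        for i in sorted(net.minima):
            m = net.minima[i]
            scaled.add_minimum_record(
                Minimum(V=m.V, nu_bar=2 * m.nu_bar, kappa=m.kappa)
            )
        for j in sorted(net.transition_states):
            t = net.transition_states[j]
            scaled.add_ts_record(
                TransitionState(
                    V=t.V, nu_bar_real=2 * t.nu_bar_real, min_a=t.min_a, min_b=t.min_b
                )
            )
        rn2 = RateNetwork.from_network(scaled, 298.0)
        for i in net.minima:
            for j in rn1.branching[i]:
                assert rn1.branching[i][j] == pytest.approx(
                    rn2.branching[i][j], rel=1e-12
                )
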