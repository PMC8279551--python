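"""Synthetic transition networks and closed-form oracles.

Generates random funneled kinetic transition networks whose statistical
structure mirrors what the landscape analysis assumes: clusters of harmonic
basins with controlled energy offsets, frequency ratios, and barrier
heights, optionally organized into several funnels separated by a high
inter-funnel barrier (the cis/trans-like topology of capped dipeptides).
Every generated network is a pure function of (spec, seed), and closed-form
two-state oracles are provided for validating the thermodynamics and
kinetics modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .constants import KB
from .ktn import KineticTransitionNetwork, Minimum, TransitionState


class GenerationError(RuntimeError):
    pass


@dataclass
class FunnelParams:
    """One funnel: ``n_minima`` basins above a common ``offset`` (kcal/mol)."""

    n_minima: int
    offset: float = 0.0
    energy_spread: tuple[float, float] = (0.0, 5.0)  # uniform, kcal/mol
    barrier_range: tuple[float, float] = (0.5, 8.0)  # log-uniform, kcal/mol
    extra_edge_prob: float = 0.3


@dataclass
class FunnelSpec:
    """Specification of a random funneled network.

    Frequencies are drawn as nu_bar = nu0 * exp(N(0, sigma_ln_nu)); every
    transition-state energy exceeds both endpoint minima by a drawn barrier,
    and distinct funnels are joined only through saddles lying
    ``inter_funnel_barrier`` above the higher of the two funnel bottoms.
    """

    funnels: list[FunnelParams] = field(
        default_factory=lambda: [FunnelParams(n_minima=10)]
    )
    inter_funnel_barrier: float = 13.0
    kappa: int = 51
    nu0: float = 1e13
    sigma_ln_nu: float = 0.1
    n_iso: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        if self.inter_funnel_barrier <= 0:
            raise GenerationError("inter-funnel barrier must be positive")
        for f in self.funnels:
            if f.n_minima < 1:
                raise GenerationError("each funnel needs at least one minimum")
            if f.barrier_range[0] <= 0:
                raise GenerationError("barriers must be positive")


def generate_ktn(spec: FunnelSpec) -> KineticTransitionNetwork:
    """Generate a connected, seeded random funneled network."""
    rng = np.random.default_rng(spec.rng_seed)
    net = KineticTransitionNetwork()

    def draw_nu() -> float:
        return spec.nu0 * math.exp(rng.normal(0.0, spec.sigma_ln_nu))

    funnel_ids: list[list[int]] = []
    for f in spec.funnels:
        ids = []
        for i in range(f.n_minima):
            if i == 0:
                v = f.offset
            else:
                v = f.offset + rng.uniform(*f.energy_spread)
            mid = net.add_minimum_record(
                Minimum(V=v, nu_bar=draw_nu(), kappa=spec.kappa, n_iso=spec.n_iso)
            )
            ids.append(mid)
        # random tree (connect each new minimum to a previous one), then a
        # few extra edges for parallel pathways
        lo, hi = f.barrier_range
        for i in range(1, len(ids)):
            j = int(rng.integers(0, i))
            _add_ts(net, spec, rng, ids[i], ids[j], math.exp(rng.uniform(math.log(lo), math.log(hi))))
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if rng.random() < f.extra_edge_prob / max(len(ids) - 1, 1):
                    _add_ts(net, spec, rng, ids[i], ids[j], math.exp(rng.uniform(math.log(lo), math.log(hi))))
        funnel_ids.append(ids)

    # join consecutive funnels through their bottoms
    for fa, fb in zip(funnel_ids, funnel_ids[1:]):
        a, b = fa[0], fb[0]
        bottom = max(net.minima[a].V, net.minima[b].V)
        v_ts = bottom + spec.inter_funnel_barrier
        net.add_ts_record(
            TransitionState(V=v_ts, nu_bar_real=draw_nu(), min_a=a, min_b=b, n_iso=spec.n_iso)
        )

    if len(net.connected_components()) != 1:
        raise GenerationError("generated network is not connected")
    return net


def _add_ts(net, spec, rng, a, b, barrier):
    if barrier <= 0:
        raise GenerationError("drew a non-positive barrier")
    v_ts = max(net.minima[a].V, net.minima[b].V) + barrier
    net.add_ts_record(
        TransitionState(
            V=v_ts,
            nu_bar_real=spec.nu0 * math.exp(rng.normal(0.0, spec.sigma_ln_nu)),
            min_a=a,
            min_b=b,
            n_iso=spec.n_iso,
        )
    )


# ---------------------------------------------------------------------------
# closed-form two-state oracle
# ---------------------------------------------------------------------------


@dataclass
class TwoStateOracle:
    """Closed-form thermodynamics/kinetics of two harmonic basins.

    State 1 lies ``delta_v`` above state 0; ``freq_ratio`` is
    nu_bar_0 / nu_bar_1, so state 1 is entropically favored when
    freq_ratio > 1.  All expressions follow from the classical harmonic
    basin partition function with equal kappa.
    """

    delta_v: float
    freq_ratio: float
    kappa: int

    def __post_init__(self):
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")
        if self.freq_ratio <= 0:
            raise ValueError("freq_ratio must be positive")

    def delta_f(self, T: float) -> float:
        """F_1 - F_0 = delta_v - kappa k_B T ln(freq_ratio)."""
        return self.delta_v - self.kappa * KB * T * math.log(self.freq_ratio)

    def populations(self, T: float) -> tuple[float, float]:
        x = self.delta_f(T) / (KB * T)
        p1 = 1.0 / (1.0 + math.exp(x))
        return 1.0 - p1, p1

    def cv_excess(self, T: float) -> float:
        """Two-state heat-capacity anomaly (configurational part).

        Cv_excess = delta_v^2 p0 p1 / (k_B T^2); for freq_ratio = 1 this is
        the textbook form k_B x^2 e^x / (1+e^x)^2 with x = delta_v / k_B T,
        peaking at x ~= 2.40.
        """
        p0, p1 = self.populations(T)
        return self.delta_v**2 * p0 * p1 / (KB * T * T)

    def cv_peak_temperature(self, bracket=(1.0, 2000.0)) -> float:
        res = minimize_scalar(
            lambda t: -self.cv_excess(t), bounds=bracket, method="bounded",
            options={"xatol": 1e-8},
        )
        return float(res.x)

    def rates(self, T: float, prefactor: float = 1e12, barrier: float | None = None):
        """Forward/backward rates over a saddle ``barrier`` above state 0.

        State 0 has the higher frequencies (nu_0 = r nu_1), so its escape
        prefactor carries the r^kappa factor; detailed balance
        k01 p0 = k10 p1 then holds by construction.
        """
        dv = barrier if barrier is not None else max(self.delta_v, 0.0) + 1.0
        k01 = prefactor * self.freq_ratio**self.kappa * math.exp(-dv / (KB * T))
        k10 = prefactor * math.exp(-(dv - self.delta_v) / (KB * T))
        return k01, k10


def analytic_two_state(delta_v: float, freq_ratio: float, kappa: int) -> TwoStateOracle:
    return TwoStateOracle(delta_v=delta_v, freq_ratio=freq_ratio, kappa=kappa)


def two_state_network(oracle: TwoStateOracle, barrier: float = 3.0, nu0: float = 1e13
                      ) -> KineticTransitionNetwork:
    """Materialize a two-state oracle as a 2-minimum, 1-TS network."""
    net = KineticTransitionNetwork()
    a = net.add_minimum_record(
        Minimum(V=0.0, nu_bar=nu0 * oracle.freq_ratio, kappa=oracle.kappa)
    )
    b = net.add_minimum_record(Minimum(V=oracle.delta_v, nu_bar=nu0, kappa=oracle.kappa))
    net.add_ts_record(
        TransitionState(
            V=max(0.0, oracle.delta_v) + barrier, nu_bar_real=nu0, min_a=a, min_b=b
        )
    )
    return net


def parameter_recovery_suite(
    seed_count: int = 20,
    n_minima: int = 12,
    temperatures=(100.0, 298.0, 500.0),
) -> dict:
    """Generate random networks and compare both analysis routes per seed.

    For each seed: closed-form heat capacity vs numerical differentiation of
    ln Z, and graph-transformation MFPTs vs the dense master-equation linear
    solve, plus the T -> 0 limit of the free-energy gap against the planted
    potential-energy gap.  Returns a report of maximum relative errors.
    """
    from .kinetics import mfpt_linear_solve, phenomenological_rates
    from .thermo import delta_f, heat_capacity, heat_capacity_numerical

    if seed_count < 1:
        raise ValueError("seed_count must be >= 1")
    report = {
        "seeds": seed_count,
        "max_rel_err_cv": 0.0,
        "max_rel_err_mfpt": 0.0,
        "max_abs_err_df_t0": 0.0,
    }
    for seed in range(seed_count):
        spec = FunnelSpec(
            funnels=[FunnelParams(n_minima=n_minima), FunnelParams(n_minima=max(n_minima // 2, 1), offset=1.5)],
            rng_seed=seed,
            kappa=30,
        )
        net = generate_ktn(spec)
        for T in temperatures:
            grid = np.array([T - 1.0, T, T + 1.0])
            cv = heat_capacity(net, grid).Cv[1]
            cv_fd = heat_capacity_numerical(net, T)
            report["max_rel_err_cv"] = max(
                report["max_rel_err_cv"], abs(cv - cv_fd) / abs(cv_fd)
            )
        ids = sorted(net.minima)
        gm = net.global_minimum().id
        other = max(ids, key=lambda i: net.minima[i].V)
        if gm != other:
            T = 298.0
            r = phenomenological_rates(net, {gm}, {other}, T)
            ref = mfpt_linear_solve(net, {gm}, {other}, T)
            report["max_rel_err_mfpt"] = max(
                report["max_rel_err_mfpt"], abs(r.mfpt_AB - ref) / ref
            )
            planted = net.minima[other].V - net.minima[gm].V
            df0 = delta_f(net, {gm}, {other}, 1e-7)
            report["max_abs_err_df_t0"] = max(
                report["max_abs_err_df_t0"], abs(df0 - planted)
            )
    return report
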