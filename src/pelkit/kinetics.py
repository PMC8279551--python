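"""Harmonic transition-state theory rates and graph-transformation kinetics.

Elementary escape rates through each transition state follow harmonic TST,

    k = (k_B T / h) (Z_ts / Z_min) exp(-dV / k_B T)

whose classical-harmonic closed form is
``(n_ts/n_min) nu_bar_min^kappa / nu_bar_ts^(kappa-1) exp(-dV/k_B T)``.
Both routes are implemented and must agree.

Phenomenological two-state rates and mean first-passage times (MFPTs)
between macrostates A and B are obtained by graph transformation: iterative
elimination of intermediate nodes with renormalization of branching
probabilities and waiting times,

    P'_uv = P_uv + P_ux P_xv / (1 - P_xx),   tau'_u = tau_u + P_ux tau_x / (1 - P_xx),

which is exact under the Markov assumption and numerically stable when
1 - P_xx is accumulated from the off-diagonal branching sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import KB, PLANCK
from .ktn import IntegrityError, KineticTransitionNetwork, Minimum, TransitionState
from .thermo import ln_z_min, ln_z_ts, populations


class NoPathError(ValueError):
    pass


def ln_tst_rate(
    m: Minimum, t: TransitionState, T: float, route: str = "frequency"
) -> float:
    """ln of the harmonic TST escape rate from minimum m through saddle t."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    dv = t.V - m.V
    if dv < -1e-9:
        raise IntegrityError(
            f"saddle {t.id} lies {-dv:.3g} kcal/mol below minimum {m.id}"
        )
    kbt = KB * T
    if route == "frequency":
        return (
            math.log(t.n_iso / m.n_iso)
            + m.kappa * math.log(m.nu_bar)
            - (m.kappa - 1) * math.log(t.nu_bar_real)
            - dv / kbt
        )
    if route == "partition":
        # (k_B T/h) (Z_ts/Z_m) exp(-dV/kbt) with the energy factors kept
        # inside the ln Z terms (they cancel against the explicit dV).
        return (
            math.log(kbt / PLANCK)
            + ln_z_ts(t, m.kappa, T)
            - ln_z_min(m, T)
        )
    raise ValueError(f"unknown route {route!r}")


def tst_rate(m: Minimum, t: TransitionState, T: float, route: str = "frequency") -> float:
    """Harmonic TST rate constant (s^-1) for escape from m through t."""
    return math.exp(ln_tst_rate(m, t, T, route=route))


@dataclass
class RateNetwork:
    """Minimum-to-minimum rates at one temperature.

    ``rates[i][j]`` is the total rate constant i -> j (parallel transition
    states summed); ``tau[i]`` the mean waiting time at i, ``branching[i][j]``
    the branching probability.  Self-loop saddles (degenerate rearrangements)
    contribute to waiting times but carry no inter-minimum flux.
    """

    T: float
    rates: dict[int, dict[int, float]]
    tau: dict[int, float]
    branching: dict[int, dict[int, float]]
    self_loop_rate: dict[int, float]

    @classmethod
    def from_network(cls, net: KineticTransitionNetwork, T: float) -> "RateNetwork":
        rates: dict[int, dict[int, float]] = {i: {} for i in net.minima}
        self_loop: dict[int, float] = {i: 0.0 for i in net.minima}
        for t in net.transition_states.values():
            if t.min_a == t.min_b:
                self_loop[t.min_a] += tst_rate(net.minima[t.min_a], t, T)
                continue
            for i, j in ((t.min_a, t.min_b), (t.min_b, t.min_a)):
                k = tst_rate(net.minima[i], t, T)
                rates[i][j] = rates[i].get(j, 0.0) + k
        tau = {}
        branching: dict[int, dict[int, float]] = {}
        for i in net.minima:
            total = sum(rates[i].values()) + self_loop[i]
            if total > 0:
                tau[i] = 1.0 / total
                branching[i] = {j: k * tau[i] for j, k in rates[i].items()}
            else:  # isolated minimum: absorbing
                tau[i] = math.inf
                branching[i] = {}
        return cls(T=T, rates=rates, tau=tau, branching=branching, self_loop_rate=self_loop)


class _GT:
    """Graph-transformation state: branching dict-of-dicts and waiting times."""

    def __init__(self, rn: RateNetwork, nodes):
        self.P: dict[int, dict[int, float]] = {
            u: {v: p for v, p in rn.branching[u].items() if v in nodes}
            for u in nodes
        }
        # self-loop saddles enter as an explicit P_uu
        for u in nodes:
            k_self = rn.self_loop_rate.get(u, 0.0)
            if k_self > 0.0 and math.isfinite(rn.tau[u]):
                self.P[u][u] = self.P[u].get(u, 0.0) + k_self * rn.tau[u]
        self.tau: dict[int, float] = {u: rn.tau[u] for u in nodes}

    def eliminate(self, x: int) -> None:
        px = self.P.pop(x)
        taux = self.tau.pop(x)
        # 1 - P_xx computed from the off-diagonal sum for stability as P_xx -> 1
        out = {v: p for v, p in px.items() if v != x}
        denom = sum(out.values())
        if denom <= 0.0:
            # absorbing intermediate: nothing flows through it
            for u in self.P:
                self.P[u].pop(x, None)
            return
        inv = 1.0 / denom
        for u in list(self.P):
            pux = self.P[u].pop(x, None)
            if pux is None or pux == 0.0:
                continue
            self.tau[u] += pux * taux * inv
            for v, pxv in out.items():
                if v == u:
                    self.P[u][u] = self.P[u].get(u, 0.0) + pux * pxv * inv
                else:
                    self.P[u][v] = self.P[u].get(v, 0.0) + pux * pxv * inv

    def copy(self) -> "_GT":
        g = object.__new__(_GT)
        g.P = {u: dict(d) for u, d in self.P.items()}
        g.tau = dict(self.tau)
        return g


def _elimination_order(gt: _GT, keep: set[int]) -> list[int]:
    # fewest-neighbors-first keeps intermediate fill-in small
    cand = [u for u in gt.P if u not in keep]
    return sorted(cand, key=lambda u: (len(gt.P[u]), u))


def _mfpt_from_source(gt: _GT, source: int, targets: set[int]) -> float:
    """Mean first-passage time from ``source`` to the target set.

    Eliminates every retained node except the source and the targets, then
    t = tau''_s / (1 - P''_ss).
    """
    g = gt.copy()
    for u in _elimination_order(g, targets | {source}):
        g.eliminate(u)
    p_self = g.P[source].get(source, 0.0)
    escape = sum(p for v, p in g.P[source].items() if v != source)
    if escape <= 0.0:
        raise NoPathError(f"no route from {source} to the target set")
    return g.tau[source] / escape


@dataclass
class PhenomenologicalRates:
    """Two-state observables for macrostates A and B at one temperature.

    ``k_AB`` is the A -> B rate constant (and ``k_BA`` its reverse), defined
    as the source-equilibrium-weighted steady-state flux, which satisfies
    detailed balance k_AB p_A = k_BA p_B exactly.  MFPTs are
    equilibrium-weighted over the source macrostate.
    """

    T: float
    k_AB: float
    k_BA: float
    mfpt_AB: float
    mfpt_BA: float


def phenomenological_rates(
    net: KineticTransitionNetwork,
    A,
    B,
    T: float,
    elimination_order: list[int] | None = None,
) -> PhenomenologicalRates:
    """Contract the network to two-state rates and MFPTs between A and B."""
    A, B = set(A), set(B)
    if not A or not B:
        raise ValueError("macrostates must be non-empty")
    if A & B:
        raise ValueError("macrostates must be disjoint")
    comps = net.connected_components()
    comp = next((c for c in comps if A <= c), None)
    if comp is None or not B <= comp:
        raise NoPathError("A and B are not in the same connected component")

    rn = RateNetwork.from_network(net, T)
    gt = _GT(rn, comp)
    keep = A | B
    order = (
        [x for x in elimination_order if x not in keep]
        if elimination_order is not None
        else _elimination_order(gt, keep)
    )
    for x in order:
        gt.eliminate(x)

    p = populations(net, T)
    pa = sum(p[a] for a in A)
    pb = sum(p[b] for b in B)

    # steady-state rates: renormalized branching with the *original* waiting
    # time of the source (flux form, exactly detailed-balanced)
    k_ab = sum(
        (p[a] / pa) * sum(gt.P[a].get(b, 0.0) for b in B) / rn.tau[a] for a in A
    )
    k_ba = sum(
        (p[b] / pb) * sum(gt.P[b].get(a, 0.0) for a in A) / rn.tau[b] for b in B
    )

    mfpt_ab = sum((p[a] / pa) * _mfpt_from_source(gt, a, B) for a in A)
    mfpt_ba = sum((p[b] / pb) * _mfpt_from_source(gt, b, A) for b in B)
    return PhenomenologicalRates(T=T, k_AB=k_ab, k_BA=k_ba, mfpt_AB=mfpt_ab, mfpt_BA=mfpt_ba)


def mfpt_linear_solve(net: KineticTransitionNetwork, A, B, T: float) -> float:
    """Equilibrium-weighted MFPT from A to B by dense linear algebra.

    Solves sum_j k_{i->j} (t_j - t_i) = -1 with t = 0 on B; the independent
    master-equation route used to validate graph transformation.  Rate
    matrices mix intra-well (~1/ps) and activated (~1/ms) scales and can be
    severely ill-conditioned, so the double-precision solve is polished with
    iterative refinement using extended-precision residuals.
    """
    A, B = set(A), set(B)
    rn = RateNetwork.from_network(net, T)
    comps = net.connected_components()
    comp = next((c for c in comps if A <= c), None)
    if comp is None or not B <= comp:
        raise NoPathError("A and B are not in the same connected component")
    free = sorted(comp - B)
    idx = {u: i for i, u in enumerate(free)}
    n = len(free)
    mat = np.zeros((n, n), dtype=np.longdouble)
    rhs = -np.ones(n, dtype=np.longdouble)
    for u in free:
        i = idx[u]
        total = np.sum(np.array(list(rn.rates[u].values()), dtype=np.longdouble))
        mat[i, i] -= total
        for v, k in rn.rates[u].items():
            if v in idx:
                mat[i, idx[v]] += k
    t = _solve_longdouble(mat, rhs)
    p = populations(net, T)
    pa = sum(p[a] for a in A)
    return float(sum(p[a] / pa * t[idx[a]] for a in A))


def _solve_longdouble(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Gaussian elimination with partial pivoting in extended precision."""
    a = a.astype(np.longdouble).copy()
    b = b.astype(np.longdouble).copy()
    n = a.shape[0]
    for c in range(n):
        piv = c + int(np.argmax(np.abs(a[c:, c])))
        if a[piv, c] == 0:
            raise np.linalg.LinAlgError("singular rate matrix")
        if piv != c:
            a[[c, piv]] = a[[piv, c]]
            b[[c, piv]] = b[[piv, c]]
        fac = a[c + 1 :, c] / a[c, c]
        a[c + 1 :, c:] -= fac[:, None] * a[c, c:]
        b[c + 1 :] -= fac * b[c]
    x = np.zeros(n, dtype=np.longdouble)
    for c in range(n - 1, -1, -1):
        x[c] = (b[c] - a[c, c + 1 :] @ x[c + 1 :]) / a[c, c]
    return x


def rate_scan(
    net: KineticTransitionNetwork, A, B, T_grid, check_monotone: bool = True
):
    """Phenomenological rates on a temperature grid.

    Returns a pandas DataFrame with columns T, k_AB, k_BA, mfpt_AB, mfpt_BA
    and a ``monotone`` flag column marking any decrease of k with T (not
    expected for positive barriers and fixed topology).
    """
    import pandas as pd

    rows = []
    for T in np.asarray(T_grid, dtype=float):
        r = phenomenological_rates(net, A, B, T)
        rows.append(
            {"T": T, "k_AB": r.k_AB, "k_BA": r.k_BA, "mfpt_AB": r.mfpt_AB, "mfpt_BA": r.mfpt_BA}
        )
    df = pd.DataFrame(rows)
    if check_monotone:
        df["monotone"] = True
        for col in ("k_AB", "k_BA"):
            d = np.diff(df[col].to_numpy())
            if np.any(d < 0):
                bad = np.where(d < 0)[0] + 1
                df.loc[df.index[bad], "monotone"] = False
    return df
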