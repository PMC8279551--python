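"""Transition-state location and discrete-path construction.

Candidate saddles between two minima come from a doubly-nudged elastic band
(DNEB): a chain of images relaxed under the true gradient perpendicular to
the path tangent plus the spring gradient along it, retaining a fraction of
the perpendicular spring component for stability.  Candidates (interior
energy maxima along the relaxed band) are converged with hybrid
eigenvector-following: an uphill step along the lowest Hessian eigenvector
combined with Newton minimization in the orthogonal subspace, accepted as a
transition state only if exactly one negative Hessian eigenvalue remains
(the Murrell-Laidler criterion).  Approximate steepest-descent paths started
parallel and antiparallel to the reaction vector identify the two connected
minima.  A Dijkstra-driven missing-connection loop assembles complete
discrete paths, and refinement schemes (shortcut, shortcut-barrier, untrap)
grow the database toward kinetically relevant pathways.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import networkx as nx

from .constants import KB
from .ktn import (
    DiscretePath,
    KineticTransitionNetwork,
    Minimum,
    TransitionState,
    add_minimum,
    add_transition_state,
    best_rmsd,
)
from .potentials import PotentialSurface
from .sampling import (
    ConvergenceError,
    frequencies_from_eigenvalues,
    local_minimize,
    vibrational_analysis,
)


class ClassificationError(RuntimeError):
    """Saddle search converged to a point with no negative eigenvalue."""


class HigherOrderSaddleError(RuntimeError):
    """Saddle search converged to a point with more than one negative eigenvalue."""


class UnconnectedError(RuntimeError):
    def __init__(self, msg, net=None):
        super().__init__(msg)
        self.net = net


class NoPathError(ValueError):
    pass


@dataclass
class BandConfig:
    n_images: int = 11  # interior images
    k_spring: float = 100.0  # kcal mol^-1 A^-2
    dneb_fraction: float = 0.1
    max_iter: int = 1000
    rms_tol: float = 1e-3
    step: float = 0.02
    budget: int = 30  # connection attempts for connect_pair

    def __post_init__(self):
        if self.n_images < 3:
            raise ValueError("need at least 3 images")


def _band_gradient(surface, band, k_spring, dneb_fraction):
    """DNEB gradient on the interior images of a band (endpoints fixed)."""
    n = len(band)
    grads = np.zeros_like(band)
    energies = np.array([surface.energy(x) for x in band])
    for i in range(1, n - 1):
        g = surface.gradient(band[i])
        dp = band[i + 1] - band[i]
        dm = band[i] - band[i - 1]
        # energy-weighted upwind tangent (Henkelman & Jonsson)
        e0, e1, e2 = energies[i - 1], energies[i], energies[i + 1]
        if e2 > e1 > e0:
            tan = dp
        elif e2 < e1 < e0:
            tan = dm
        else:
            dmax = max(abs(e2 - e1), abs(e0 - e1))
            dmin = min(abs(e2 - e1), abs(e0 - e1))
            tan = dp * dmax + dm * dmin if e2 > e0 else dp * dmin + dm * dmax
        nrm = np.linalg.norm(tan)
        tan = tan / nrm if nrm > 0 else tan
        g_perp = g - (g @ tan) * tan
        # spring gradient: parallel part from image spacing, plus the
        # double-nudged residue of its perpendicular part
        g_spr = -k_spring * (np.linalg.norm(dp) - np.linalg.norm(dm)) * tan
        g_spr_full = -k_spring * (dp - dm)
        g_spr_perp = g_spr_full - (g_spr_full @ tan) * tan
        gp_nrm = np.linalg.norm(g_perp)
        if gp_nrm > 0:
            ghat = g_perp / gp_nrm
            g_star = g_spr_perp - (g_spr_perp @ ghat) * ghat
        else:
            g_star = g_spr_perp
        grads[i] = g_perp + g_spr + dneb_fraction * g_star
    return grads, energies


def dneb_candidates(
    surface: PotentialSurface,
    min_a,
    min_b,
    cfg: BandConfig | None = None,
) -> tuple[list[np.ndarray], bool]:
    """Transition-state candidates from a relaxed doubly-nudged elastic band.

    Endpoints (Minimum objects or coordinate arrays) stay fixed; returns the
    interior images that are local energy maxima along the band, ordered by
    position, and a flag that is True when band relaxation converged.
    """
    cfg = cfg or BandConfig()
    xa = np.asarray(min_a.coords if isinstance(min_a, Minimum) else min_a, float).ravel()
    xb = np.asarray(min_b.coords if isinstance(min_b, Minimum) else min_b, float).ravel()
    n = cfg.n_images + 2
    w = np.linspace(0.0, 1.0, n)[:, None]
    band = (1 - w) * xa[None, :] + w * xb[None, :]
    if np.allclose(xa, xb):
        # degenerate loop: perturb interior images so relaxation can proceed
        rng = np.random.default_rng(0)
        band[1:-1] += rng.normal(scale=1e-3, size=band[1:-1].shape)

    # quenched-velocity (FIRE-like) relaxation; NEB forces are non-conservative
    v = np.zeros_like(band)
    dt = cfg.step
    converged = False
    for _ in range(cfg.max_iter):
        grads, energies = _band_gradient(surface, band, cfg.k_spring, cfg.dneb_fraction)
        rms = float(np.sqrt(np.mean(grads[1:-1] ** 2)))
        if rms < cfg.rms_tol:
            converged = True
            break
        f = -grads
        power = float(np.sum(v * f))
        if power > 0:
            fn = np.linalg.norm(f)
            vn = np.linalg.norm(v)
            if fn > 0:
                v = 0.9 * v + 0.1 * (vn * f / fn)
        else:
            v[:] = 0.0
        v += dt * f
        step = dt * v
        nrm = np.linalg.norm(step, axis=1, keepdims=True)
        big = nrm > 0.1
        if np.any(big):
            step = np.where(big, step * 0.1 / np.maximum(nrm, 1e-30), step)
        band += step

    _, energies = _band_gradient(surface, band, cfg.k_spring, cfg.dneb_fraction)
    cands = [
        band[i].copy()
        for i in range(1, n - 1)
        if energies[i] > energies[i - 1] and energies[i] > energies[i + 1]
    ]
    if not cands and not np.allclose(xa, xb):
        i = 1 + int(np.argmax(energies[1:-1]))
        if energies[i] > max(energies[0], energies[-1]):
            cands = [band[i].copy()]
    return cands, converged


def _projected_eigh(surface, x):
    h = surface.hessian(x)
    basis = surface.zero_mode_basis(x)
    if basis is not None and basis.size:
        # shift rigid modes far up the spectrum so they never get followed
        shift = max(1.0, float(np.abs(h).max()))
        h = h + (10.0 * shift) * (basis @ basis.T)
    return np.linalg.eigh(h)


def ef_refine(
    surface: PotentialSurface,
    x0,
    rms_tol: float = 1e-6,
    trust_radius: float = 0.2,
    max_iter: int = 500,
    neg_tol: float = 1e-6,
) -> tuple[np.ndarray, TransitionState]:
    """Converge a saddle candidate with hybrid eigenvector-following.

    Steps uphill along the lowest Hessian eigenvector while taking Newton
    steps in the orthogonal subspace, bounded by a trust radius.  Raises
    ClassificationError (converged to a minimum) or HigherOrderSaddleError
    (more than one negative eigenvalue) per the Murrell-Laidler criterion.
    Returns the converged coordinates and a TransitionState record (endpoint
    ids unset) with nu_bar over the real modes.
    """
    x = np.asarray(x0, dtype=float).ravel().copy()
    for _ in range(max_iter):
        g = surface.gradient(x)
        rms = float(np.sqrt(np.mean(g * g)))
        if rms <= rms_tol:
            break
        evals, vecs = _projected_eigh(surface, x)
        gl = vecs.T @ g
        lam = evals.copy()
        # follow the softest mode uphill: flip the sign of its curvature
        s = 0
        floor = max(1e-8, 1e-10 * np.abs(lam).max())
        denom = np.where(np.abs(lam) < floor, floor, np.abs(lam))
        # Newton in the orthogonal subspace; along the followed mode the
        # curvature sign is reversed, which for |lam| denominators is always
        # a +g/|lam| step (uphill when lam > 0, Newton when lam < 0)
        step = -gl / denom
        step[s] = +gl[s] / denom[s]
        dx = vecs @ step
        nrm = np.linalg.norm(dx)
        if nrm > trust_radius:
            dx *= trust_radius / nrm
        x = x + dx
    else:
        raise ConvergenceError(
            f"eigenvector-following did not reach RMS {rms_tol:g}",
            x=x,
            V=surface.energy(x),
            rms=rms,
        )

    kappa, evals = vibrational_analysis(surface, x)
    n_neg = int(np.sum(evals < -neg_tol))
    if n_neg == 0:
        raise ClassificationError("converged to a stationary point with no negative eigenvalue")
    if n_neg > 1:
        raise HigherOrderSaddleError(f"{n_neg} negative eigenvalues: higher-order saddle")
    pos = evals[evals > neg_tol]
    if pos.size:
        nus = frequencies_from_eigenvalues(pos)
        nu_bar_real = float(np.exp(np.mean(np.log(nus))))
    else:  # 1-DOF system: empty real-mode product
        nu_bar_real = 1.0
    ts = TransitionState(
        V=float(surface.energy(x)),
        nu_bar_real=nu_bar_real,
        min_a=-1,
        min_b=-1,
        coords=x.copy(),
    )
    return x, ts


def lowest_mode(surface: PotentialSurface, x) -> np.ndarray:
    evals, vecs = _projected_eigh(surface, np.asarray(x, dtype=float).ravel())
    return vecs[:, 0]


def descend_from_ts(
    surface: PotentialSurface,
    ts_coords,
    displacement: float = 0.05,
    rms_tol: float = 1e-6,
) -> tuple:
    """Minima on either side of a saddle via perturbed minimization.

    Displaces +-displacement along the normalized eigenvector of the unique
    negative eigenvalue, then minimizes each side (approximate
    steepest-descent connection).  Returns two MinimizationResult objects.
    """
    x = np.asarray(ts_coords, dtype=float).ravel()
    mode = lowest_mode(surface, x)
    sides = []
    for sign, label in ((+1.0, "forward"), (-1.0, "backward")):
        try:
            sides.append(
                local_minimize(surface, x + sign * displacement * mode,
                               rms_tol=rms_tol, characterize=True)
            )
        except ConvergenceError as exc:
            raise ConvergenceError(
                f"{label} descent from saddle failed: {exc}", exc.x, exc.V, exc.rms
            ) from exc
    return sides[0], sides[1]


# ---------------------------------------------------------------------------
# discrete paths on the network
# ---------------------------------------------------------------------------


def shortest_path(
    net: KineticTransitionNetwork,
    id_a: int,
    id_b: int,
    weight: str = "ts_energy",
    T: float = 298.0,
) -> DiscretePath:
    """Minimal-weight discrete path between two minima.

    Weights: "ts_energy" (sum of saddle energies above the global minimum,
    so parallel saddles resolve to the lower one), "step_count", or
    "rate_based" (edge weight -ln P of the branching probability at T).
    """
    g = net.graph()
    if id_a not in g or id_b not in g:
        raise KeyError("unknown minimum id")
    v_ref = net.global_minimum().V
    if weight == "rate_based":
        from .kinetics import RateNetwork

        rn = RateNetwork.from_network(net, T)

    def edge_w(u, v, key):
        t = net.transition_states[key]
        if weight == "ts_energy":
            return t.V - v_ref
        if weight == "step_count":
            return 1.0
        if weight == "rate_based":
            p = rn.branching[u].get(v, 0.0)
            # parallel saddles share the summed branching probability; the
            # per-edge weight still orders them by energy via a tiny tiebreak
            if p <= 0:
                return math.inf
            return -math.log(p) + 1e-12 * (t.V - v_ref)
        raise ValueError(f"unknown weight {weight!r}")

    try:
        nodes = nx.dijkstra_path(
            g, id_a, id_b, weight=lambda u, v, d: min(edge_w(u, v, k) for k in d)
        )
    except nx.NetworkXNoPath as exc:
        raise NoPathError(f"minima {id_a} and {id_b} are not connected") from exc

    ts_ids = []
    for u, v in zip(nodes, nodes[1:]):
        keys = [k for k in g[u][v]]
        ts_ids.append(min(keys, key=lambda k: edge_w(u, v, k)))
    return DiscretePath(minima=nodes, transition_states=ts_ids, net=net)


def _attempt_connection(surface, net, xa_id, xb_id, cfg, e_tol, rmsd_tol):
    """One DNEB + EF + descend cycle between two minima; inserts results."""
    ma, mb = net.minima[xa_id], net.minima[xb_id]
    cands, _ = dneb_candidates(surface, ma, mb, cfg)
    added = 0
    for cand in cands:
        try:
            xts, ts = ef_refine(surface, cand)
        except (ClassificationError, HigherOrderSaddleError, ConvergenceError):
            continue
        try:
            side_a, side_b = descend_from_ts(surface, xts)
        except ConvergenceError:
            continue
        if side_a.is_minimum is False or side_b.is_minimum is False:
            continue
        ia, _ = add_minimum(net, side_a.as_minimum(), e_tol, rmsd_tol,
                            metric=surface.distance)
        ib, _ = add_minimum(net, side_b.as_minimum(), e_tol, rmsd_tol,
                            metric=surface.distance)
        ts.min_a, ts.min_b = ia, ib
        _, new = add_transition_state(net, ts, e_tol, rmsd_tol, metric=surface.distance)
        added += int(new)
    return added


def connect_pair(
    surface: PotentialSurface,
    net: KineticTransitionNetwork,
    id_a: int,
    id_b: int,
    cfg: BandConfig | None = None,
    d0: float = 1.0,
    gap_cap: float = 1e4,
    e_tol: float = 1e-3,
    rmsd_tol: float = 0.05,
) -> DiscretePath:
    """Build a discrete path between two minima, filling gaps iteratively.

    Runs Dijkstra on a mixed graph in which known transition-state edges are
    near-free and unknown minimum pairs are weighted by exp(d/d0) of their
    best-superposition distance; the widest gap on the current best mixed
    path is attacked with DNEB + eigenvector-following + descent, results
    are inserted, and the loop repeats until a pure transition-state path
    exists or the attempt budget is exhausted (UnconnectedError carrying the
    partially grown network).  The network only ever gains stationary points.
    """
    cfg = cfg or BandConfig()
    if id_a not in net.minima or id_b not in net.minima:
        raise KeyError("unknown minimum id")
    tried: set[tuple[int, int]] = set()

    for _ in range(cfg.budget):
        try:
            return shortest_path(net, id_a, id_b, weight="ts_energy")
        except NoPathError:
            pass
        g = nx.Graph()
        g.add_nodes_from(net.minima)
        for t in net.transition_states.values():
            if t.min_a != t.min_b:
                w = min(g.get_edge_data(t.min_a, t.min_b, {"weight": math.inf})["weight"], 1e-6)
                g.add_edge(t.min_a, t.min_b, weight=w, known=True)
        ids = sorted(net.minima)
        for i, u in enumerate(ids):
            for v in ids[i + 1 :]:
                if g.has_edge(u, v):
                    continue
                mu, mv = net.minima[u], net.minima[v]
                if mu.coords is None or mv.coords is None:
                    continue
                key = (u, v)
                n_sites = mu.coords.size / 3 if mu.coords.size % 3 == 0 else mu.coords.size
                d = best_rmsd(mu.coords, mv.coords) * math.sqrt(n_sites)
                w = min(math.exp(d / d0), gap_cap)
                if key in tried:
                    w *= 10.0  # de-prioritize failed gaps
                g.add_edge(u, v, weight=w, known=False)
        try:
            nodes = nx.dijkstra_path(g, id_a, id_b, weight="weight")
        except nx.NetworkXNoPath as exc:
            raise UnconnectedError("no geometric route between endpoints", net) from exc
        gaps = [
            (u, v)
            for u, v in zip(nodes, nodes[1:])
            if not g[u][v].get("known", False)
        ]
        if not gaps:
            return shortest_path(net, id_a, id_b, weight="ts_energy")
        for u, v in gaps:
            tried.add((min(u, v), max(u, v)))
            _attempt_connection(surface, net, u, v, cfg, e_tol, rmsd_tol)
    try:
        return shortest_path(net, id_a, id_b, weight="ts_energy")
    except NoPathError as exc:
        raise UnconnectedError(
            f"connection budget exhausted between {id_a} and {id_b}", net
        ) from exc


def untrap_ranking(net: KineticTransitionNetwork) -> list[tuple[int, float]]:
    """Minima ranked by (downhill barrier toward the global minimum) over
    (energy above the global minimum), highest ratio first.

    A large ratio flags artificial frustration: a minimum barely above the
    global minimum yet separated from it by a disproportionate barrier.
    """
    gm = net.global_minimum().id
    g = net.graph()
    scores = []
    for mid, m in net.minima.items():
        if mid == gm:
            continue
        dv = m.V - net.minima[gm].V
        if dv <= 0:
            continue
        try:
            path = shortest_path(net, mid, gm, weight="ts_energy")
        except NoPathError:
            continue
        barrier = path.highest_barrier()
        scores.append((mid, barrier / dv))
    scores.sort(key=lambda t: (-t[1], t[0]))
    return scores


def refine_database(
    surface: PotentialSurface,
    net: KineticTransitionNetwork,
    scheme: str,
    budget: int = 5,
    endpoints: tuple[int, int] | None = None,
    cfg: BandConfig | None = None,
    e_tol: float = 1e-3,
    rmsd_tol: float = 0.05,
) -> KineticTransitionNetwork:
    """Grow the database with one refinement scheme (in place).

    "shortcut" attempts direct connections between pairs far apart along the
    current best path between the endpoints; "shortcut_barrier" attacks the
    segment containing the highest saddle of that path; "untrap" reconnects
    the worst frustration offenders to the global minimum.  The network only
    ever gains stationary points.
    """
    if not net.minima:
        raise StateError("refinement on an empty network")
    cfg = cfg or BandConfig()
    if scheme in ("shortcut", "shortcut_barrier"):
        if endpoints is None:
            raise ValueError(f"{scheme} needs endpoint minima")
        a, b = endpoints
        for _ in range(budget):
            path = shortest_path(net, a, b, weight="ts_energy")
            if len(path) <= 1:
                break
            before = len(path)
            if scheme == "shortcut":
                # most-separated pair along the path first
                u, v = path.minima[0], path.minima[-1]
            else:
                e = [net.transition_states[t].V for t in path.transition_states]
                i = int(np.argmax(e))
                u = path.minima[max(i - 1, 0)]
                v = path.minima[min(i + 2, len(path.minima) - 1)]
            _attempt_connection(surface, net, u, v, cfg, e_tol, rmsd_tol)
            after = len(shortest_path(net, a, b, weight="ts_energy"))
            if after >= before:
                break
        return net
    if scheme == "untrap":
        for mid, _ratio in untrap_ranking(net)[:budget]:
            _attempt_connection(surface, net, mid, net.global_minimum().id, cfg, e_tol, rmsd_tol)
        return net
    raise ValueError(f"unknown scheme {scheme!r}")


class StateError(RuntimeError):
    pass
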