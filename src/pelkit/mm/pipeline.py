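"""End-to-end exploration pipeline for the built-in dipeptide surfaces.

Combines deterministic multistart minimization from the nine Ramachandran
family centers (both peptide-bond isomers, and side-chain rotamers for
serine), basin-hopping with backbone group-rotation moves, DNEB +
eigenvector-following connections between the low-lying conformer families,
and rotation-seeded saddle searches across the peptide-bond (omega)
isomerization.  The result is a labeled kinetic transition network ready for
harmonic-superposition thermodynamics and rate calculations.
"""

from __future__ import annotations

import math

import numpy as np

from ..connect import (
    BandConfig,
    ClassificationError,
    HigherOrderSaddleError,
    dneb_candidates,
    descend_from_ts,
    ef_refine,
)
from ..ktn import KineticTransitionNetwork, add_minimum, add_transition_state
from ..sampling import (
    BasinHoppingConfig,
    ConvergenceError,
    basin_hop,
    local_minimize,
    rotate_group,
)
from .engine import AmberStyleSurface
from .topology import build_conformer, build_topology

# (phi, psi) starting centers for the nine conformer families
FAMILY_CENTERS = {
    "C7eq": (-80.0, 75.0),
    "C5": (-150.0, 160.0),
    "C7ax": (75.0, -65.0),
    "PII": (-70.0, 150.0),
    "alphaR": (-60.0, -45.0),
    "alphaL": (60.0, 45.0),
    "alphaD": (60.0, -170.0),
    "alphaP": (-160.0, -60.0),
    "beta2": (-130.0, 25.0),
}


def _label(surface: AmberStyleSurface, m) -> None:
    lab = surface.classify(m.coords)
    m.family, m.isomer = lab.family, lab.isomer


def multistart_minima(
    surface: AmberStyleSurface,
    net: KineticTransitionNetwork | None = None,
    include_cis: bool = True,
    rms_tol: float = 1e-6,
) -> KineticTransitionNetwork:
    """Minimize from every family center (and rotamer/isomer combination)."""
    if net is None:
        net = KineticTransitionNetwork()
    residue = surface.topology.residue
    omegas = (180.0, 0.0) if include_cis else (180.0,)
    if residue == "SER":
        # side-chain rotamer grid: chi1 x chi2 (hydroxyl orientation)
        chis = [(c1, c2) for c1 in (-60.0, 60.0, 180.0) for c2 in (-60.0, 60.0, 180.0)]
    else:
        chis = [None]
    for phi, psi in FAMILY_CENTERS.values():
        for omega in omegas:
            for chi in chis:
                kw = {} if chi is None else {"chi1": chi[0], "chi2": chi[1]}
                x0 = build_conformer(residue, phi, psi, omega, **kw)
                try:
                    r = local_minimize(surface, x0, rms_tol=rms_tol, characterize=True)
                except ConvergenceError:
                    continue
                if r.is_minimum is False:
                    continue
                m = r.as_minimum()
                _label(surface, m)
                add_minimum(net, m, metric=surface.distance)
    return net


def basin_hop_minima(
    surface: AmberStyleSurface,
    net: KineticTransitionNetwork,
    seed: int = 0,
    n_steps: int = 50,
) -> KineticTransitionNetwork:
    """Basin-hopping with Cartesian + backbone group-rotation moves."""
    cfg = BasinHoppingConfig(
        n_steps=n_steps,
        cartesian_step=0.15,
        group_rotations=surface.topology.backbone_rotation_moves(max_angle_deg=120.0),
        rng_seed=seed,
    )
    gm = net.global_minimum()
    res = basin_hop(surface, gm.coords, cfg, net=net)
    for m in res.network.minima.values():
        if m.family is None:
            _label(surface, m)
    return res.network


def attempt_saddle(
    surface: AmberStyleSurface,
    net: KineticTransitionNetwork,
    x0: np.ndarray,
    ef_max_iter: int = 200,
) -> int | None:
    """Refine a saddle candidate; insert it with its two descent minima."""
    try:
        xts, ts = ef_refine(surface, x0, max_iter=ef_max_iter)
        side_a, side_b = descend_from_ts(surface, xts)
    except (ClassificationError, HigherOrderSaddleError, ConvergenceError):
        return None
    if side_a.is_minimum is False or side_b.is_minimum is False:
        return None
    ma, mb = side_a.as_minimum(), side_b.as_minimum()
    _label(surface, ma)
    _label(surface, mb)
    ia, _ = add_minimum(net, ma, metric=surface.distance)
    ib, _ = add_minimum(net, mb, metric=surface.distance)
    ts.min_a, ts.min_b = ia, ib
    tid, _ = add_transition_state(net, ts, metric=surface.distance)
    return tid


def lowest_in_family(net, family, isomer="trans"):
    ids = net.ids_by_family(family, isomer)
    if not ids:
        return None
    return min(ids, key=lambda i: net.minima[i].V)


def connect_family_pairs(
    surface: AmberStyleSurface,
    net: KineticTransitionNetwork,
    pairs,
    band_cfg: BandConfig | None = None,
) -> None:
    """DNEB + EF between the lowest minima of the named family pairs."""
    cfg = band_cfg or BandConfig(max_iter=300)
    for fa, fb in pairs:
        ia, ib = lowest_in_family(net, fa), lowest_in_family(net, fb)
        if ia is None or ib is None or ia == ib:
            continue
        cands, _ = dneb_candidates(surface, net.minima[ia], net.minima[ib], cfg)
        for cand in cands[:2]:
            attempt_saddle(surface, net, cand)


def add_omega_saddles(
    surface: AmberStyleSurface, net: KineticTransitionNetwork
) -> None:
    """Rotation-seeded saddle searches across the peptide-bond isomerization.

    Rotating the acetyl group by +-90 degrees about the amide C-N axis
    places the geometry near the top of the cis/trans rotation profile;
    eigenvector-following from there converges the isomerization saddles.
    """
    top = surface.topology
    axis = (top.index["RES.N"], top.index["ACE.C"])
    group = tuple(top.atoms_beyond(axis))
    for i in sorted(net.minima):
        m = net.minima[i]
        if m.isomer != "trans" or m.coords is None:
            continue
        for ang in (90.0, -90.0):
            attempt_saddle(
                surface, net, rotate_group(m.coords, group, axis, math.radians(ang))
            )


def explore_dipeptide(
    residue: str = "ALA",
    seed: int = 0,
    bh_steps: int = 40,
    include_cis: bool = True,
    connect: bool = True,
) -> tuple[AmberStyleSurface, KineticTransitionNetwork]:
    """Full pipeline: multistart + basin-hopping (+ saddles for alanine).

    Returns the surface and a labeled network.  With ``connect=True`` the
    low-lying trans families are joined by DNEB + eigenvector-following and
    the omega isomerization saddles are added from every trans minimum.
    """
    surface = AmberStyleSurface(build_topology(residue))
    net = multistart_minima(surface, include_cis=include_cis)
    if bh_steps > 0:
        net = basin_hop_minima(surface, net, seed=seed, n_steps=bh_steps)
    if connect:
        connect_family_pairs(
            surface,
            net,
            [("C5", "C7eq"), ("C7ax", "C7eq"), ("PII", "C7eq"), ("C5", "C7ax")],
        )
        if include_cis:
            add_omega_saddles(surface, net)
    return surface, net
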