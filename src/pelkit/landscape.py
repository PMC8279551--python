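"""Disconnectivity graphs and conformer classification.

A disconnectivity graph records, for a ladder of energy thresholds, which
minima are mutually reachable through transition states lying below each
threshold (superbasins).  Branches terminate at individual minima and merge
at the lowest threshold above the barrier separating them; the result is a
faithful, projection-free picture of landscape topography.  Both
potential-energy and free-energy (harmonic superposition at temperature T)
variants are supported, with optional branch coloring by a minimum label
such as the peptide-bond isomer.

Conformer classification assigns backbone dihedrals (phi, psi) to one of the
nine standard families of capped dipeptides via a configurable region table,
and the peptide-bond isomer (cis/trans) from omega.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .ktn import KineticTransitionNetwork
from .thermo import free_energies, ts_free_energy


class StateError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# superbasin analysis
# ---------------------------------------------------------------------------


def _node_energies(net: KineticTransitionNetwork, energy_mode: str, T: float | None):
    if energy_mode == "potential":
        emin = {i: m.V for i, m in net.minima.items()}
        ets = {j: t.V for j, t in net.transition_states.items()}
    elif energy_mode == "free":
        if T is None or T <= 0:
            raise ValueError("free-energy mode needs a positive temperature")
        emin = free_energies(net, T)
        ets = {j: ts_free_energy(net, j, T) for j in net.transition_states}
    else:
        raise ValueError(f"unknown energy_mode {energy_mode!r}")
    return emin, ets


def superbasins(
    net: KineticTransitionNetwork,
    E: float,
    energy_mode: str = "potential",
    T: float | None = None,
) -> list[frozenset[int]]:
    """Partition of minima below E into mutually reachable sets.

    Two minima belong to the same superbasin when they are connected through
    transition states whose (free) energy lies below E; minima at or above E
    are excluded from the partition.
    """
    emin, ets = _node_energies(net, energy_mode, T)
    parent = {i: i for i in net.minima if emin[i] < E}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for j, t in net.transition_states.items():
        if ets[j] >= E:
            continue
        a, b = t.min_a, t.min_b
        if a in parent and b in parent:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    groups: dict[int, set[int]] = {}
    for i in parent:
        groups.setdefault(find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]


@dataclass
class TreeNode:
    """A superbasin at one threshold level of a disconnectivity tree."""

    level: int
    energy: float
    members: frozenset[int]
    parent: int | None = None  # index into DisconnectivityTree.nodes
    children: list[int] = field(default_factory=list)
    color: str | None = None


@dataclass
class DisconnectivityTree:
    levels: np.ndarray  # threshold energies E_l
    nodes: list[TreeNode]
    leaves: dict[int, int]  # minimum id -> node index of its first appearance
    energy_mode: str
    delta_e: float
    color_key: str | None = None
    minimum_energies: dict[int, float] = field(default_factory=dict)
    colors: dict[int, str] = field(default_factory=dict)  # minimum id -> label

    @property
    def roots(self) -> list[int]:
        return [i for i, n in enumerate(self.nodes) if n.parent is None]

    def to_json(self) -> str:
        payload = {
            "energy_mode": self.energy_mode,
            "delta_e": self.delta_e,
            "levels": self.levels.tolist(),
            "nodes": [
                {
                    "level": n.level,
                    "energy": n.energy,
                    "members": sorted(n.members),
                    "parent": n.parent,
                    "children": n.children,
                    "color": n.color,
                }
                for n in self.nodes
            ],
            "leaves": {str(k): v for k, v in self.leaves.items()},
            "minimum_energies": {str(k): v for k, v in self.minimum_energies.items()},
        }
        return json.dumps(payload, indent=1)


def build_tree(
    net: KineticTransitionNetwork,
    delta_e: float = 1.0,
    energy_mode: str = "potential",
    T: float | None = None,
    color_by: str | None = None,
    e_ref: float | None = None,
) -> DisconnectivityTree:
    """Construct the superbasin hierarchy on regularly spaced thresholds.

    Thresholds are E_l = E_ref + l * delta_e with E_ref defaulting to the
    (free) energy of the global minimum; levels extend one step past the
    highest saddle so a single root exists for a connected network.
    """
    if delta_e <= 0:
        raise ValueError("delta_e must be positive")
    if not net.minima:
        raise StateError("cannot build a tree for an empty network")
    emin, ets = _node_energies(net, energy_mode, T)
    if e_ref is None:
        e_ref = min(emin.values())
    top = max([*ets.values(), *emin.values()], default=e_ref)
    n_levels = int(math.ceil((top - e_ref) / delta_e)) + 2
    levels = e_ref + delta_e * np.arange(1, n_levels + 1)

    colors = {}
    if color_by is not None:
        for i, m in net.minima.items():
            colors[i] = getattr(m, color_by, None)

    nodes: list[TreeNode] = []
    leaves: dict[int, int] = {}
    prev: dict[frozenset, int] = {}
    for lvl, E in enumerate(levels):
        parts = superbasins(net, E, energy_mode=energy_mode, T=T)
        cur: dict[frozenset, int] = {}
        for basin in parts:
            labels = {colors.get(i) for i in basin} if colors else set()
            node = TreeNode(
                level=lvl,
                energy=float(E),
                members=basin,
                color=labels.pop() if len(labels) == 1 else None,
            )
            nodes.append(node)
            idx = len(nodes) - 1
            cur[basin] = idx
            for i in basin:
                if i not in leaves:
                    leaves[i] = idx
        # parent links: a level-l basin's parent is the level-l+1 basin that
        # contains it; fill in when the next level is built
        if lvl > 0:
            for basin_prev, idx_prev in prev.items():
                for basin_cur, idx_cur in cur.items():
                    if basin_prev <= basin_cur:
                        nodes[idx_prev].parent = idx_cur
                        nodes[idx_cur].children.append(idx_prev)
                        break
        prev = cur
    return DisconnectivityTree(
        levels=levels,
        nodes=nodes,
        leaves=leaves,
        energy_mode=energy_mode,
        delta_e=delta_e,
        color_key=color_by,
        minimum_energies=emin,
        colors=colors,
    )


def merge_level(tree: DisconnectivityTree, id_a: int, id_b: int) -> float:
    """Lowest threshold energy at which two minima share a superbasin."""
    for node in sorted(tree.nodes, key=lambda n: n.level):
        if id_a in node.members and id_b in node.members:
            return node.energy
    raise NoMergeError(f"minima {id_a} and {id_b} never merge")


class NoMergeError(ValueError):
    pass


_PALETTE = {"trans": "#c62828", "cis": "#1565c0", None: "#444444"}


def render_svg(tree: DisconnectivityTree, path, width: float = 640.0, height: float = 480.0):
    """Render the tree as an SVG file via matplotlib.

    Leaf branches descend to each minimum's own energy; subtrees are laid
    out with the deepest funnel first.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # x-layout: recursive allocation, deepest child first
    xpos: dict[int, float] = {}

    def depth(idx: int) -> float:
        n = tree.nodes[idx]
        if not n.children:
            return min(tree.minimum_energies[i] for i in n.members)
        return min(depth(c) for c in n.children)

    def layout(idx: int, lo: float, hi: float):
        n = tree.nodes[idx]
        xpos[idx] = 0.5 * (lo + hi)
        kids = sorted(n.children, key=depth)
        if not kids:
            return
        total = sum(len(tree.nodes[c].members) for c in kids)
        x = lo
        for c in kids:
            w = (hi - lo) * len(tree.nodes[c].members) / total
            layout(c, x, x + w)
            x += w

    roots = tree.roots
    span = 1.0 / max(len(roots), 1)
    for r_i, r in enumerate(roots):
        layout(r, r_i * span, (r_i + 1) * span)

    fig, ax = plt.subplots(figsize=(width / 96.0, height / 96.0))
    for idx, n in enumerate(tree.nodes):
        color = _PALETTE.get(n.color, "#444444")
        if n.parent is not None:
            ax.plot(
                [xpos[idx], xpos[n.parent]],
                [n.energy, tree.nodes[n.parent].energy],
                color=color,
                lw=1.0,
            )
        if not n.children:  # stem down to the minimum energy
            emin = min(tree.minimum_energies[i] for i in n.members)
            ax.plot([xpos[idx], xpos[idx]], [emin, n.energy], color=color, lw=1.0)
    ax.set_xticks([])
    label = "V / kcal mol$^{-1}$" if tree.energy_mode == "potential" else "F / kcal mol$^{-1}$"
    ax.set_ylabel(label)
    for side in ("top", "right", "bottom"):
        ax.spines[side].set_visible(False)
    fig.savefig(str(path), format="svg", bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# conformer classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConformerLabel:
    family: str
    isomer: str  # "cis" | "trans"
    rotamer: str | None = None


def wrap_angle(a: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    return -((-a + 180.0) % 360.0) + 180.0


def dihedral(p0, p1, p2, p3) -> float:
    """Dihedral angle in degrees, IUPAC sign convention, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2hat = b2 / np.linalg.norm(b2)
    ang = math.degrees(math.atan2(float(np.cross(n1, n2) @ b2hat), float(n1 @ n2)))
    return wrap_angle(ang)


# Default (phi, psi) region table for the nine backbone conformer families of
# capped dipeptides.  Rectangles approximate the conventional Ramachandran
# segregation; the exact published boundaries are not reproduced here, so the
# table is fully user-configurable.  First matching rectangle wins.
DEFAULT_REGIONS: list[tuple[str, float, float, float, float]] = [
    #  family   phi_min phi_max  psi_min psi_max
    ("C5", -180.0, -100.0, 100.0, 180.0),
    ("PII", -100.0, -35.0, 100.0, 180.0),
    ("C7eq", -180.0, -35.0, 20.0, 100.0),  # inverse gamma turn (C7 ring)
    ("beta2", -180.0, -100.0, -10.0, 20.0),
    ("alphaR", -100.0, -35.0, -70.0, 20.0),
    ("alphaP", -180.0, -35.0, -180.0, -70.0),  # alpha-prime
    ("alphaR", -180.0, -100.0, -70.0, -10.0),
    ("C7ax", 35.0, 130.0, -140.0, 0.0),  # gamma turn (C7 ring)
    ("alphaL", 35.0, 130.0, 0.0, 100.0),
    ("alphaD", 35.0, 130.0, 100.0, 180.0),
    ("alphaD", 35.0, 130.0, -180.0, -140.0),
]


def classify_angles(
    phi: float,
    psi: float,
    omega: float,
    region_table=None,
) -> ConformerLabel:
    """Assign a conformer family from (phi, psi) and the isomer from omega.

    Angles wrap periodically; cis iff |omega| < 90 deg (boundary -> trans);
    (phi, psi) outside every region yields family "unassigned".
    """
    regions = DEFAULT_REGIONS if region_table is None else region_table
    phi, psi, omega = wrap_angle(phi), wrap_angle(psi), wrap_angle(omega)
    family = "unassigned"
    for name, p0, p1, s0, s1 in regions:
        if p0 <= phi < p1 and s0 <= psi < s1:
            family = name
            break
        # psi = 180 belongs to regions closed at the top boundary
        if p0 <= phi < p1 and s1 == 180.0 and psi == 180.0:
            family = name
            break
    isomer = "cis" if abs(omega) < 90.0 else "trans"
    return ConformerLabel(family=family, isomer=isomer)


def classify_conformer(coords, atom_map: dict, region_table=None) -> ConformerLabel:
    """Classify a conformation from Cartesian coordinates.

    ``atom_map`` holds the dihedral quadruples (atom indices) under keys
    "phi", "psi" and "omega".
    """
    xyz = np.asarray(coords, dtype=float).reshape(-1, 3)

    def ang(key):
        i, j, k, l = atom_map[key]
        return dihedral(xyz[i], xyz[j], xyz[k], xyz[l])

    return classify_angles(ang("phi"), ang("psi"), ang("omega"), region_table)


def load_region_table(path) -> list[tuple[str, float, float, float, float]]:
    """Read a region table: family phi_min phi_max psi_min psi_max per line."""
    table = []
    with open(str(path)) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            table.append((parts[0], *(float(v) for v in parts[1:5])))
    return table
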