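"""Capped-dipeptide topologies and internal-coordinate conformer building.

Supported systems are the acetyl- and amide-capped single residues
Ac-Ala-NH2 and Ac-Ser-NH2 (residue templates ACE / ALA / SER / NHE).  The
topology carries atom names, types, charges and the bond graph, from which
angles, proper torsions, impropers and nonbonded exclusion lists are
derived.  Conformers are constructed from an internal-coordinate template
(NeRF chain construction) with the backbone torsions phi, psi, omega and the
side-chain torsions as free dials, so any Ramachandran region can be used as
a deterministic starting point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import ffparams


class ParameterError(ValueError):
    pass


@dataclass
class TemplateAtom:
    name: str
    type: str
    charge: float


# Residue templates: atoms, intra-residue bonds (by name), and the names of
# the atoms that link to the previous/next residue.
_RESIDUES = {
    "ACE": {
        "atoms": [
            TemplateAtom("CH3", "CT", -0.3662),
            TemplateAtom("HH31", "HC", 0.1123),
            TemplateAtom("HH32", "HC", 0.1123),
            TemplateAtom("HH33", "HC", 0.1123),
            TemplateAtom("C", "C", 0.5972),
            TemplateAtom("O", "O", -0.5679),
        ],
        "bonds": [("CH3", "HH31"), ("CH3", "HH32"), ("CH3", "HH33"), ("CH3", "C"), ("C", "O")],
        "head": None,
        "tail": "C",
    },
    "ALA": {
        "atoms": [
            TemplateAtom("N", "N", -0.4157),
            TemplateAtom("H", "H", 0.2719),
            TemplateAtom("CA", "CX", 0.0337),
            TemplateAtom("HA", "H1", 0.0823),
            TemplateAtom("CB", "CT", -0.1825),
            TemplateAtom("HB1", "HC", 0.0603),
            TemplateAtom("HB2", "HC", 0.0603),
            TemplateAtom("HB3", "HC", 0.0603),
            TemplateAtom("C", "C", 0.5973),
            TemplateAtom("O", "O", -0.5679),
        ],
        "bonds": [
            ("N", "H"), ("N", "CA"), ("CA", "HA"), ("CA", "CB"),
            ("CB", "HB1"), ("CB", "HB2"), ("CB", "HB3"), ("CA", "C"), ("C", "O"),
        ],
        "head": "N",
        "tail": "C",
    },
    "SER": {
        "atoms": [
            TemplateAtom("N", "N", -0.4157),
            TemplateAtom("H", "H", 0.2719),
            TemplateAtom("CA", "CX", -0.0249),
            TemplateAtom("HA", "H1", 0.0843),
            TemplateAtom("CB", "2C", 0.2117),
            TemplateAtom("HB2", "H1", 0.0352),
            TemplateAtom("HB3", "H1", 0.0352),
            TemplateAtom("OG", "OH", -0.6546),
            TemplateAtom("HG", "HO", 0.4275),
            TemplateAtom("C", "C", 0.5973),
            TemplateAtom("O", "O", -0.5679),
        ],
        "bonds": [
            ("N", "H"), ("N", "CA"), ("CA", "HA"), ("CA", "CB"),
            ("CB", "HB2"), ("CB", "HB3"), ("CB", "OG"), ("OG", "HG"),
            ("CA", "C"), ("C", "O"),
        ],
        "head": "N",
        "tail": "C",
    },
    "NHE": {
        "atoms": [
            TemplateAtom("N", "N", -0.4630),
            TemplateAtom("HN1", "H", 0.2315),
            TemplateAtom("HN2", "H", 0.2315),
        ],
        "bonds": [("N", "HN1"), ("N", "HN2")],
        "head": "N",
        "tail": None,
    },
}

SUPPORTED_RESIDUES = ("ALA", "SER")


@dataclass
class Topology:
    """Atom list, bond graph and derived interaction lists."""

    residue: str
    atom_names: list[str]
    atom_types: list[str]
    charges: np.ndarray
    masses: np.ndarray
    elements: list[str]
    bonds: list[tuple[int, int]]
    angles: list[tuple[int, int, int]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int]] = field(default_factory=list)
    impropers: list[tuple[int, int, int, int]] = field(default_factory=list)
    pairs_14: list[tuple[int, int]] = field(default_factory=list)
    pairs_nb: list[tuple[int, int]] = field(default_factory=list)
    index: dict[str, int] = field(default_factory=dict)  # "resname.atom" -> idx

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def atoms_beyond(self, axis: tuple[int, int]) -> list[int]:
        """Atoms on the far side of bond axis (i, j): reachable from j
        without crossing i (j itself excluded)."""
        i, j = axis
        seen = {i, j}
        stack = [j]
        out = []
        while stack:
            u = stack.pop()
            for v in self.neighbors(u):
                if v not in seen:
                    seen.add(v)
                    out.append(v)
                    stack.append(v)
        return sorted(out)

    @property
    def atom_map(self) -> dict[str, tuple[int, int, int, int]]:
        """Dihedral quadruples for phi, psi, omega (and chi1 where present)."""
        ix = self.index
        out = {
            "phi": (ix["ACE.C"], ix["RES.N"], ix["RES.CA"], ix["RES.C"]),
            "psi": (ix["RES.N"], ix["RES.CA"], ix["RES.C"], ix["NHE.N"]),
            "omega": (ix["ACE.CH3"], ix["ACE.C"], ix["RES.N"], ix["RES.CA"]),
        }
        if self.residue == "SER":
            out["chi1"] = (ix["RES.N"], ix["RES.CA"], ix["RES.CB"], ix["RES.OG"])
        return out

    def backbone_rotation_moves(self, max_angle_deg: float = 60.0):
        """Group-rotation basin-hopping moves about the soft torsions."""
        from ..sampling import GroupRotationMove

        ix = self.index
        axes = [
            (ix["RES.N"], ix["RES.CA"]),   # phi
            (ix["RES.CA"], ix["RES.C"]),   # psi
            (ix["RES.N"], ix["ACE.C"]),    # omega (rotates the acetyl cap)
        ]
        if self.residue == "SER":
            axes.append((ix["RES.CA"], ix["RES.CB"]))  # chi1
        moves = []
        for ax in axes:
            moves.append(
                GroupRotationMove(
                    atoms=tuple(self.atoms_beyond(ax)),
                    axis=ax,
                    max_angle_deg=max_angle_deg,
                    probability=0.5,
                )
            )
        return moves


def build_topology(residue: str = "ALA") -> Topology:
    """Assemble the ACE-<residue>-NH2 topology with derived term lists."""
    residue = residue.upper()
    if residue not in SUPPORTED_RESIDUES:
        raise ParameterError(
            f"unsupported residue {residue!r}; supported: {SUPPORTED_RESIDUES}"
        )
    seq = ["ACE", residue, "NHE"]
    names, types, charges, index = [], [], [], {}
    bonds: list[tuple[int, int]] = []
    prev_tail = None
    for res in seq:
        tpl = _RESIDUES[res]
        offset = len(names)
        local = {}
        for a in tpl["atoms"]:
            local[a.name] = len(names)
            key = ("RES" if res == residue else res) + "." + a.name
            index[key] = len(names)
            names.append(a.name)
            types.append(a.type)
            charges.append(a.charge)
        for a, b in tpl["bonds"]:
            bonds.append((local[a], local[b]))
        if tpl["head"] is not None and prev_tail is not None:
            bonds.append((prev_tail, local[tpl["head"]]))
        if tpl["tail"] is not None:
            prev_tail = local[tpl["tail"]]
        del offset

    masses = np.array([ffparams.MASSES[t] for t in types])
    elements = [ffparams.ELEMENTS[t] for t in types]
    top = Topology(
        residue=residue,
        atom_names=names,
        atom_types=types,
        charges=np.array(charges),
        masses=masses,
        elements=elements,
        bonds=bonds,
        index=index,
    )
    _derive_terms(top)
    return top


def _derive_terms(top: Topology) -> None:
    n = top.n_atoms
    adj = [set() for _ in range(n)]
    for a, b in top.bonds:
        adj[a].add(b)
        adj[b].add(a)

    angles = []
    for j in range(n):
        nb = sorted(adj[j])
        for ii in range(len(nb)):
            for kk in range(ii + 1, len(nb)):
                angles.append((nb[ii], j, nb[kk]))
    top.angles = angles

    dihedrals = []
    for j, k in top.bonds:
        for i in sorted(adj[j] - {k}):
            for l in sorted(adj[k] - {j}):
                if i != l:
                    dihedrals.append((i, j, k, l))
    top.dihedrals = dihedrals

    # impropers at sp2 centers (carbonyl C, amide N); central atom third
    impropers = []
    for c in range(n):
        t = top.atom_types[c]
        nb = sorted(adj[c])
        if len(nb) != 3:
            continue
        if t == "C":
            ox = [i for i in nb if top.atom_types[i] == "O"]
            if ox:
                rest = [i for i in nb if i != ox[0]]
                impropers.append((rest[0], rest[1], c, ox[0]))
        elif t == "N":
            hy = [i for i in nb if top.atom_types[i].startswith("H")]
            if hy:
                h = hy[-1]
                rest = [i for i in nb if i != h]
                impropers.append((rest[0], rest[1], c, h))
    top.impropers = impropers

    # exclusions: 1-2 and 1-3 fully excluded, 1-4 scaled
    excl = {frozenset(b) for b in top.bonds}
    for i, j, k in angles:
        excl.add(frozenset((i, k)))
    p14 = set()
    for i, j, k, l in dihedrals:
        key = frozenset((i, l))
        if key not in excl:
            p14.add(key)
    pairs_nb = []
    for i in range(n):
        for j in range(i + 1, n):
            key = frozenset((i, j))
            if key in excl or key in p14:
                continue
            pairs_nb.append((i, j))
    top.pairs_14 = sorted(tuple(sorted(p)) for p in p14)
    top.pairs_nb = pairs_nb


# ---------------------------------------------------------------------------
# internal-coordinate conformer construction
# ---------------------------------------------------------------------------


def _place(pos_a, pos_b, pos_c, r, theta_deg, phi_deg):
    """NeRF placement: new atom bonded to a, angle with b, torsion with c."""
    theta = math.radians(theta_deg)
    phi = math.radians(phi_deg)
    ba = pos_a - pos_b
    cb = pos_b - pos_c
    ba /= np.linalg.norm(ba)
    n = np.cross(cb, ba)
    nn = np.linalg.norm(n)
    if nn < 1e-10:  # collinear references: pick any perpendicular
        probe = np.array([1.0, 0.0, 0.0])
        if abs(ba @ probe) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        n = np.cross(ba, probe)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, ba)
    d = (
        -r * math.cos(theta) * ba
        + r * math.sin(theta) * math.cos(phi) * m
        + r * math.sin(theta) * math.sin(phi) * n
    )
    return pos_a + d


def _zmatrix(residue: str, phi, psi, omega, chi1, chi2):
    """Internal-coordinate template: (atom, ref_a, ref_b, ref_c, r, theta, tors)."""
    # shared ACE + backbone skeleton; indices follow build_topology order
    if residue == "ALA":
        ca, c2 = 8, 14
        side = [
            (10, 8, 6, 4, 1.526, 109.7, phi - 120.0),  # CB (L configuration)
            (11, 10, 8, 6, 1.090, 109.5, 60.0),
            (12, 10, 8, 6, 1.090, 109.5, 180.0),
            (13, 10, 8, 6, 1.090, 109.5, -60.0),
        ]
        nterm = 16
    else:  # SER
        ca, c2 = 8, 15
        side = [
            (10, 8, 6, 4, 1.526, 109.7, phi - 120.0),  # CB (L configuration)
            (11, 10, 8, 6, 1.090, 109.5, chi1 + 120.0),  # HB2
            (12, 10, 8, 6, 1.090, 109.5, chi1 - 120.0),  # HB3
            (13, 10, 8, 6, 1.410, 109.5, chi1),  # OG
            (14, 13, 10, 8, 0.960, 108.5, chi2),  # HG
        ]
        nterm = 17
    entries = [
        # ACE: CH3 (0) at origin, C (4) and N (6) seed the frame
        (5, 4, 0, 6, 1.229, 120.4, 180.0),  # O opposite N
        (1, 0, 4, 6, 1.090, 109.5, 60.0),
        (2, 0, 4, 6, 1.090, 109.5, 180.0),
        (3, 0, 4, 6, 1.090, 109.5, -60.0),
        (8, 6, 4, 0, 1.449, 121.9, omega),  # CA: omega torsion
        (7, 6, 4, 0, 1.010, 120.0, omega + 180.0),  # amide H opposite CA
        (c2, ca, 6, 4, 1.522, 110.1, phi),  # carbonyl C: phi torsion
        (9, ca, 6, 4, 1.090, 109.5, phi + 120.0),  # HA
        *side,
        (nterm, c2, ca, 6, 1.335, 116.6, psi),  # NHE N: psi torsion
        (c2 + 1, c2, ca, nterm, 1.229, 120.4, 180.0),  # carbonyl O opposite N
        (nterm + 1, nterm, c2, ca, 1.010, 120.0, 0.0),  # HN1 (cis to O side)
        (nterm + 2, nterm, c2, ca, 1.010, 120.0, 180.0),  # HN2
    ]
    return entries


def build_conformer(
    residue: str = "ALA",
    phi: float = -80.0,
    psi: float = 75.0,
    omega: float = 180.0,
    chi1: float = -60.0,
    chi2: float = 180.0,
) -> np.ndarray:
    """Cartesian coordinates (flat, Angstrom) for a requested conformer.

    Backbone torsions follow the standard definitions: phi = C(-1)-N-CA-C,
    psi = N-CA-C-N(+1), omega = CH3-C-N-CA (trans = 180).  The geometry is a
    reasonable covalent skeleton intended as a minimization start, not a
    stationary point.
    """
    residue = residue.upper()
    if residue not in SUPPORTED_RESIDUES:
        raise ParameterError(f"unsupported residue {residue!r}")
    n_atoms = 19 if residue == "ALA" else 20
    xyz = np.zeros((n_atoms, 3))
    # seed frame: CH3 at origin, ACE C along x, amide N in the xy-plane
    xyz[0] = (0.0, 0.0, 0.0)
    xyz[4] = (1.522, 0.0, 0.0)
    th = math.radians(116.6)
    xyz[6] = xyz[4] + 1.335 * np.array([-math.cos(th), math.sin(th), 0.0])
    for atom, a, b, c, r, theta, tors in _zmatrix(residue, phi, psi, omega, chi1, chi2):
        xyz[atom] = _place(xyz[a], xyz[b], xyz[c], r, theta, tors)
    return xyz.ravel()
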