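"""Vacuum molecular-mechanics potential surface for capped dipeptides.

``AmberStyleSurface`` evaluates the standard fixed-charge force-field energy
(bonds, angles, cosine torsions and impropers, Lennard-Jones and Coulomb
with 1-4 scaling, no cutoffs) with analytic gradients, in kcal/mol and
Angstrom.  The surface carries atomic masses and the six rigid-body zero
modes, so normal-mode analysis downstream yields kappa = 3N - 6 vibrational
frequencies in s^-1.

``make_surface`` is the engine adapter: the built-in engine handles the
supported capped residues; an external OpenMM backend can be requested and
fails with a CapabilityError explaining how to enable it when the engine is
not installed.
"""

from __future__ import annotations

import math

import numpy as np

from ..constants import COULOMB as _COULOMB
from ..potentials import ParameterError, PotentialSurface
from . import ffparams
from .topology import Topology, build_conformer, build_topology


class CapabilityError(RuntimeError):
    """An optional external engine is not available."""


class AmberStyleSurface(PotentialSurface):
    n_zero_modes = 6

    def __init__(self, topology: Topology):
        self.topology = topology
        self.ndof = 3 * topology.n_atoms
        self.masses = topology.masses
        t = topology

        self._bond_idx = np.array(t.bonds, dtype=int).reshape(-1, 2)
        bp = [ffparams.bond_params(t.atom_types[i], t.atom_types[j]) for i, j in t.bonds]
        self._bond_k = np.array([p[0] for p in bp])
        self._bond_r0 = np.array([p[1] for p in bp])

        self._ang_idx = np.array(t.angles, dtype=int).reshape(-1, 3)
        ap = [
            ffparams.angle_params(t.atom_types[i], t.atom_types[j], t.atom_types[k])
            for i, j, k in t.angles
        ]
        self._ang_k = np.array([p[0] for p in ap])
        self._ang_t0 = np.radians([p[1] for p in ap])

        tor_idx, tor_h, tor_g, tor_n = [], [], [], []
        for quad in t.dihedrals:
            terms = ffparams.dihedral_params(*(t.atom_types[q] for q in quad))
            for h, g, n in terms:
                if h == 0.0:
                    continue
                tor_idx.append(quad)
                tor_h.append(h)
                tor_g.append(math.radians(g))
                tor_n.append(n)
        for quad in t.impropers:
            terms = ffparams.improper_params(t.atom_types[quad[2]], t.atom_types[quad[3]])
            for h, g, n in terms:
                tor_idx.append(quad)
                tor_h.append(h)
                tor_g.append(math.radians(g))
                tor_n.append(n)
        self._tor_idx = np.array(tor_idx, dtype=int).reshape(-1, 4)
        self._tor_h = np.array(tor_h)
        self._tor_g = np.array(tor_g)
        self._tor_n = np.array(tor_n, dtype=float)

        def nb_arrays(pairs, scale_ee, scale_lj):
            idx = np.array(pairs, dtype=int).reshape(-1, 2)
            qq = scale_ee * t.charges[idx[:, 0]] * t.charges[idx[:, 1]] * _COULOMB
            eps, rmin = [], []
            for i, j in idx:
                ri, ei = ffparams.LENNARD_JONES[t.atom_types[i]]
                rj, ej = ffparams.LENNARD_JONES[t.atom_types[j]]
                eps.append(scale_lj * math.sqrt(ei * ej))
                rmin.append(ri + rj)
            return idx, qq, np.array(eps), np.array(rmin)

        i14, q14, e14, r14 = nb_arrays(t.pairs_14, ffparams.SCALE_EE_14, ffparams.SCALE_LJ_14)
        inb, qnb, enb, rnb = nb_arrays(t.pairs_nb, 1.0, 1.0)
        self._nb_idx = np.vstack([i14, inb])
        self._nb_qq = np.concatenate([q14, qnb])
        self._nb_eps = np.concatenate([e14, enb])
        self._nb_rmin = np.concatenate([r14, rnb])

    # -- energy & analytic gradient ----------------------------------------

    def energy(self, x):
        return self.energy_gradient(x)[0]

    def gradient(self, x):
        return self.energy_gradient(x)[1]

    def energy_gradient(self, x):
        xyz = np.asarray(x, dtype=float).reshape(-1, 3)
        f = np.zeros_like(xyz)
        v = 0.0

        # bonds
        bi, bj = self._bond_idx[:, 0], self._bond_idx[:, 1]
        d = xyz[bi] - xyz[bj]
        r = np.linalg.norm(d, axis=1)
        dr = r - self._bond_r0
        v += float(np.sum(self._bond_k * dr * dr))
        coef = (2.0 * self._bond_k * dr / r)[:, None] * d
        np.add.at(f, bi, coef)
        np.add.at(f, bj, -coef)

        # angles
        ai, aj, ak = self._ang_idx[:, 0], self._ang_idx[:, 1], self._ang_idx[:, 2]
        u = xyz[ai] - xyz[aj]
        w = xyz[ak] - xyz[aj]
        nu = np.linalg.norm(u, axis=1)
        nw = np.linalg.norm(w, axis=1)
        cos_t = np.einsum("ij,ij->i", u, w) / (nu * nw)
        cos_t = np.clip(cos_t, -1.0, 1.0)
        theta = np.arccos(cos_t)
        dth = theta - self._ang_t0
        v += float(np.sum(self._ang_k * dth * dth))
        sin_t = np.sqrt(np.clip(1.0 - cos_t * cos_t, 1e-12, None))
        uhat = u / nu[:, None]
        what = w / nw[:, None]
        dth_di = (cos_t[:, None] * uhat - what) / (nu * sin_t)[:, None]
        dth_dk = (cos_t[:, None] * what - uhat) / (nw * sin_t)[:, None]
        coef = (2.0 * self._ang_k * dth)[:, None]
        np.add.at(f, ai, coef * dth_di)
        np.add.at(f, ak, coef * dth_dk)
        np.add.at(f, aj, -coef * (dth_di + dth_dk))

        # torsions (propers + impropers share the cosine form)
        if len(self._tor_idx):
            ti, tj, tk, tl = (self._tor_idx[:, c] for c in range(4))
            b1 = xyz[tj] - xyz[ti]
            b2 = xyz[tk] - xyz[tj]
            b3 = xyz[tl] - xyz[tk]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.linalg.norm(b2, axis=1)
            ang = np.arctan2(
                np.einsum("ij,ij->i", np.cross(n1, n2), b2 / nb2[:, None]),
                np.einsum("ij,ij->i", n1, n2),
            )
            arg = self._tor_n * ang - self._tor_g
            v += float(np.sum(self._tor_h * (1.0 + np.cos(arg))))
            dv_dphi = -self._tor_h * self._tor_n * np.sin(arg)
            n1sq = np.einsum("ij,ij->i", n1, n1)
            n2sq = np.einsum("ij,ij->i", n2, n2)
            dphi_di = -(nb2 / n1sq)[:, None] * n1
            dphi_dl = (nb2 / n2sq)[:, None] * n2
            s12 = (np.einsum("ij,ij->i", b1, b2) / (nb2 * nb2))[:, None]
            s32 = (np.einsum("ij,ij->i", b3, b2) / (nb2 * nb2))[:, None]
            dphi_dj = -(1.0 + s12) * dphi_di + s32 * dphi_dl
            dphi_dk = s12 * dphi_di - (1.0 + s32) * dphi_dl
            c = dv_dphi[:, None]
            np.add.at(f, ti, c * dphi_di)
            np.add.at(f, tj, c * dphi_dj)
            np.add.at(f, tk, c * dphi_dk)
            np.add.at(f, tl, c * dphi_dl)

        # nonbonded
        ni, nj = self._nb_idx[:, 0], self._nb_idx[:, 1]
        d = xyz[ni] - xyz[nj]
        r2 = np.einsum("ij,ij->i", d, d)
        r = np.sqrt(r2)
        inv = 1.0 / r
        x6 = (self._nb_rmin * inv) ** 6
        v += float(np.sum(self._nb_eps * (x6 * x6 - 2.0 * x6) + self._nb_qq * inv))
        dv_dr = self._nb_eps * (-12.0 * x6 * x6 + 12.0 * x6) * inv - self._nb_qq * inv * inv
        coef = (dv_dr * inv)[:, None] * d
        np.add.at(f, ni, coef)
        np.add.at(f, nj, -coef)

        return v, f.ravel()

    # -- masses & rigid-body modes ------------------------------------------

    def dof_masses(self, x):
        return np.repeat(self.masses, 3)

    def zero_mode_basis(self, x, mass_weighted: bool = False):
        xyz = np.asarray(x, dtype=float).reshape(-1, 3)
        n = xyz.shape[0]
        w = np.sqrt(self.masses) if mass_weighted else np.ones(n)
        com = (xyz * (w * w)[:, None]).sum(axis=0) / float((w * w).sum())
        rel = xyz - com
        modes = []
        for ax in range(3):
            m = np.zeros((n, 3))
            m[:, ax] = w
            modes.append(m.ravel())
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = 1.0
            m = np.cross(rel, e) * w[:, None]
            modes.append(m.ravel())
        basis = np.array(modes).T
        q, rr = np.linalg.qr(basis)
        keep = np.abs(np.diag(rr)) > 1e-8
        return q[:, keep]

    def distance(self, a, b):
        """Heavy-atom best-superposition RMSD.

        Methyl and amide rotations permute hydrogens among equivalent sites,
        producing permutation-inversion isomers of identical energy; judging
        duplicates on the heavy-atom skeleton identifies those with their
        canonical conformer.
        """
        from ..ktn import best_rmsd

        heavy = [i for i, el in enumerate(self.topology.elements) if el != "H"]
        a3 = np.asarray(a, dtype=float).reshape(-1, 3)[heavy]
        b3 = np.asarray(b, dtype=float).reshape(-1, 3)[heavy]
        return best_rmsd(a3, b3)

    # -- convenience ---------------------------------------------------------

    @property
    def atom_map(self):
        return self.topology.atom_map

    def conformer(self, phi, psi, omega=180.0, **kw):
        return build_conformer(self.topology.residue, phi, psi, omega, **kw)

    def classify(self, x, region_table=None):
        from ..landscape import classify_conformer

        return classify_conformer(x, self.topology.atom_map, region_table)

    def to_xyz(self, x, comment: str = "") -> str:
        xyz = np.asarray(x, dtype=float).reshape(-1, 3)
        lines = [str(xyz.shape[0]), comment]
        for el, row in zip(self.topology.elements, xyz):
            lines.append(f"{el} {row[0]:.8f} {row[1]:.8f} {row[2]:.8f}")
        return "\n".join(lines) + "\n"


def _parse_spec(topology_spec):
    if topology_spec is None:
        return "ALA"
    if isinstance(topology_spec, str):
        return topology_spec.upper()
    if isinstance(topology_spec, dict):
        res = str(topology_spec.get("residue", "ALA")).upper()
        caps = topology_spec.get("caps", ("ACE", "NH2"))
        caps = tuple(str(c).upper() for c in caps)
        if caps not in (("ACE", "NH2"), ("ACE", "NHE")):
            raise ParameterError(f"unsupported caps {caps}; only acetyl/amide caps")
        return res
    raise ParameterError(f"cannot interpret topology spec {topology_spec!r}")


def make_surface(topology_spec=None, backend: str = "builtin"):
    """Engine adapter: return a PotentialSurface for a capped dipeptide."""
    residue = _parse_spec(topology_spec)
    if backend in ("builtin", "auto"):
        return AmberStyleSurface(build_topology(residue))
    if backend == "openmm":
        try:
            import openmm  # noqa: F401
        except ImportError as exc:
            raise CapabilityError(
                "the OpenMM backend needs the external engine: install the "
                "'openmm' package (e.g. via conda-forge) with the desired "
                "protein force field, then request backend='openmm' again"
            ) from exc
        raise CapabilityError(
            "OpenMM is importable but no system builder is bundled for it; "
            "construct the System externally and wrap its context in a "
            "PotentialSurface (energy/gradient in kcal/mol and Angstrom)"
        )
    raise ParameterError(f"unknown backend {backend!r}")
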