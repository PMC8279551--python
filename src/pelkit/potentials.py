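"""Pluggable potential energy surfaces.

All surfaces expose ``energy(x)``, ``gradient(x)`` and ``hessian(x)`` on flat
coordinate vectors.  Analytic benchmark surfaces with planted stationary
points are provided for testing every stage of the landscape pipeline
without a molecular-mechanics engine; the torsional dipeptide mimic emulates
the nine-family backbone landscape of a capped dipeptide, including a high
cis/trans barrier along the peptide-bond torsion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class ParameterError(ValueError):
    pass


class PotentialSurface:
    """Base class: subclasses implement ``energy`` and ``gradient``.

    ``hessian`` defaults to central finite differences of the gradient with
    step 1e-4 (coordinate units).  ``n_zero_modes`` is the number of exact
    zero modes (rigid-body motions) a downstream eigenvalue analysis should
    ignore; ``masses`` (per degree of freedom, amu) default to unity.
    """

    ndof: int
    n_zero_modes: int = 0
    hessian_step: float = 1e-4

    def energy(self, x: np.ndarray) -> float:
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        return self.energy(x), self.gradient(x)

    def hessian(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        h = self.hessian_step
        n = x.size
        out = np.empty((n, n))
        for i in range(n):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            out[i] = (self.gradient(xp) - self.gradient(xm)) / (2 * h)
        return 0.5 * (out + out.T)

    def dof_masses(self, x: np.ndarray) -> np.ndarray:
        return np.ones(np.asarray(x).size)

    def zero_mode_basis(
        self, x: np.ndarray, mass_weighted: bool = False
    ) -> np.ndarray | None:
        """Orthonormal basis (columns) of exact zero modes at x, or None.

        ``mass_weighted=True`` returns the basis in mass-weighted
        coordinates (for normal-mode analysis); otherwise plain Cartesian
        (for geometry optimization).
        """
        return None

    def canonicalize(self, x: np.ndarray) -> np.ndarray:
        """Map coordinates to a canonical representative (e.g. periodic wrap)."""
        return np.asarray(x, dtype=float)

    def distance(self, a: np.ndarray, b: np.ndarray) -> float:
        """Configuration distance used for duplicate detection (RMSD-like)."""
        from .ktn import best_rmsd

        return best_rmsd(a, b)

    def numerical_gradient(self, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        g = np.empty(x.size)
        for i in range(x.size):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            g[i] = (self.energy(xp) - self.energy(xm)) / (2 * h)
        return g


class DoubleWell1D(PotentialSurface):
    """V(x) = a (x^2 - 1)^2: minima at x = +-1 (V=0), saddle at 0 (V=a)."""

    ndof = 1

    def __init__(self, a: float = 1.0) -> None:
        if a <= 0:
            raise ParameterError("a must be positive")
        self.a = a

    def energy(self, x):
        x = np.asarray(x, dtype=float).ravel()[0]
        return self.a * (x * x - 1.0) ** 2

    def gradient(self, x):
        x = np.asarray(x, dtype=float).ravel()[0]
        return np.array([4.0 * self.a * x * (x * x - 1.0)])

    def hessian(self, x):
        x = np.asarray(x, dtype=float).ravel()[0]
        return np.array([[4.0 * self.a * (3.0 * x * x - 1.0)]])

    @property
    def planted_minima(self):
        return [np.array([-1.0]), np.array([1.0])]

    @property
    def planted_saddles(self):
        return [np.array([0.0])]


def double_well_1d(a: float = 1.0) -> DoubleWell1D:
    return DoubleWell1D(a)


@dataclass
class GaussianTerm:
    """A single Gaussian well (amplitude < 0) or barrier (amplitude > 0).

    Contributes ``A * exp(-(x-c)^T W (x-c))`` with W symmetric positive
    definite.
    """

    amplitude: float
    center: np.ndarray
    width: np.ndarray  # positive-definite matrix W

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        w = np.asarray(self.width, dtype=float)
        if w.ndim == 1:
            w = np.diag(w)
        if not np.allclose(w, w.T):
            raise ParameterError("width matrix must be symmetric")
        if np.linalg.eigvalsh(w).min() <= 0:
            raise ParameterError("width matrix must be positive definite")
        self.width = w


class GaussianSumSurface(PotentialSurface):
    """Sum of anisotropic Gaussian wells/barriers; analytic gradient."""

    def __init__(self, terms: list[GaussianTerm], harmonic_confinement: float = 0.0):
        if not terms:
            raise ParameterError("need at least one Gaussian term")
        self.terms = terms
        self.k_conf = harmonic_confinement
        self.ndof = terms[0].center.size
        for t in terms:
            if t.center.size != self.ndof:
                raise ParameterError("inconsistent term dimensions")

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        v = 0.5 * self.k_conf * float(x @ x)
        for t in self.terms:
            d = x - t.center
            v += t.amplitude * math.exp(-float(d @ t.width @ d))
        return v

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        g = self.k_conf * x
        for t in self.terms:
            d = x - t.center
            e = t.amplitude * math.exp(-float(d @ t.width @ d))
            g = g - 2.0 * e * (t.width @ d)
        return g


def gaussian_sum_surface(terms, harmonic_confinement: float = 0.0) -> GaussianSumSurface:
    return GaussianSumSurface(list(terms), harmonic_confinement)


def three_well_chain() -> GaussianSumSurface:
    """2D benchmark: three collinear wells; saddles only between neighbors.

    Planted topology: minima near x = -2.2, 0, 2.2 on the y=0 axis, with a
    saddle between each adjacent pair, mild confinement so the surface is
    bounded below.
    """
    w = GaussianTerm
    terms = [
        w(-3.0, [-2.2, 0.0], np.diag([1.1, 0.9])),
        w(-2.6, [0.0, 0.0], np.diag([1.0, 1.0])),
        w(-3.0, [2.2, 0.0], np.diag([1.1, 0.9])),
    ]
    return GaussianSumSurface(terms, harmonic_confinement=0.08)


class TorsionalDipeptideMimic(PotentialSurface):
    """Periodic 3-torsion surface (phi, psi, omega), coordinates in degrees.

    Each requested well center contributes a von-Mises-style well
    ``-depth * exp(sum_i conc_i (cos Delta_i - 1))``; an additional ridge
    term ``(omega_barrier/2) * (1 - cos 2*omega)`` separates the cis
    (omega ~ 0) and trans (omega ~ 180 deg) isomers, vanishing at both so
    wells planted at omega in {0, 180} stay put.  A weak cosine background
    tilted toward the first well center removes flat regions between wells,
    so every spurious stationary point there has a direction of negative
    curvature and local minimization always drains into a planted well.
    """

    ndof = 3

    def __init__(
        self,
        well_centers,
        depths,
        omega_barrier: float = 13.0,
        concentration: float = 4.0,
        background: float = 0.5,
    ):
        centers = [np.asarray(c, dtype=float) for c in well_centers]
        if len(centers) != len(list(depths)):
            raise ParameterError("need one depth per well center")
        for i, a in enumerate(centers):
            for b in centers[i + 1 :]:
                if np.allclose(np.cos(np.radians(a)), np.cos(np.radians(b))) and np.allclose(
                    np.sin(np.radians(a)), np.sin(np.radians(b))
                ):
                    raise ParameterError("duplicate well centers")
        self.centers = centers
        self.depths = [float(d) for d in depths]
        if any(d <= 0 for d in self.depths):
            raise ParameterError("depths must be positive")
        self.omega_barrier = float(omega_barrier)
        self.conc = np.full(3, concentration, dtype=float)
        self.background = float(background)

    def _well(self, x, c):
        d = np.radians(x - c)
        return math.exp(float(np.sum(self.conc * (np.cos(d) - 1.0))))

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        v = 0.0
        for c, depth in zip(self.centers, self.depths):
            v -= depth * self._well(x, c)
        v += 0.5 * self.omega_barrier * (1.0 - math.cos(2.0 * math.radians(x[2])))
        d0 = np.radians(x - self.centers[0])
        v += self.background * float(np.sum(1.0 - np.cos(d0)))
        return v

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        g = np.zeros(3)
        deg = math.pi / 180.0
        for c, depth in zip(self.centers, self.depths):
            d = np.radians(x - c)
            g += depth * self._well(x, c) * self.conc * np.sin(d) * deg
        g[2] += self.omega_barrier * math.sin(2.0 * math.radians(x[2])) * deg
        g += self.background * np.sin(np.radians(x - self.centers[0])) * deg
        return g

    def canonicalize(self, x):
        return self.wrap(x)

    def distance(self, a, b):
        d = self.wrap(np.asarray(a, float) - np.asarray(b, float))
        return float(np.sqrt(np.mean(d * d)))

    @property
    def planted_minima(self):
        return [c.copy() for c in self.centers]

    @staticmethod
    def wrap(x):
        """Wrap angles to (-180, 180]."""
        x = np.asarray(x, dtype=float)
        return -np.mod(-x + 180.0, 360.0) + 180.0


def torsional_dipeptide_mimic(
    well_centers,
    depths,
    omega_barrier: float = 13.0,
    concentration: float = 4.0,
    background: float = 0.5,
) -> TorsionalDipeptideMimic:
    return TorsionalDipeptideMimic(
        well_centers, depths, omega_barrier, concentration, background
    )


def dipeptide_mimic_ala() -> TorsionalDipeptideMimic:
    """Four trans wells mirroring the capped-alanine conformer families.

    Depth differences reproduce the characteristic ordering
    C7eq < C5 < PII < C7ax of the trans funnel; no cis ridge, so the four
    planted wells are the only minima.
    """
    centers = [
        (-80.0, 75.0, 180.0),   # C7eq
        (-150.0, 160.0, 180.0),  # C5
        (-70.0, 150.0, 180.0),   # PII
        (75.0, -65.0, 180.0),    # C7ax
    ]
    base = 6.0
    depths = [base, base - 0.3, base - 1.1, base - 1.6]
    return TorsionalDipeptideMimic(centers, depths, omega_barrier=0.0)


def two_funnel_mimic(omega_barrier: float = 13.0) -> TorsionalDipeptideMimic:
    """Trans funnel plus a cis funnel across the omega ridge."""
    centers = [
        (-80.0, 75.0, 180.0),
        (-150.0, 160.0, 180.0),
        (-60.0, -45.0, 0.0),
        (60.0, 45.0, 0.0),
    ]
    depths = [6.0, 5.7, 4.0, 3.6]
    return TorsionalDipeptideMimic(centers, depths, omega_barrier=omega_barrier)


def check_gradient(surface: PotentialSurface, x, rtol: float = 1e-5, h: float = 1e-6) -> float:
    """Max relative deviation between analytic and central-difference gradient."""
    g = surface.gradient(np.asarray(x, dtype=float))
    gn = surface.numerical_gradient(np.asarray(x, dtype=float), h=h)
    scale = max(float(np.linalg.norm(gn)), 1.0)
    return float(np.linalg.norm(g - gn) / scale)


def mm_engine_adapter(topology_spec=None, backend: str = "builtin", **kwargs):
    """Construct a molecular-mechanics surface for a capped dipeptide.

    ``topology_spec`` is a residue name (``"ALA"`` or ``"SER"``) or a mapping
    with keys ``residue`` and optional ``caps`` (only acetyl/amide caps are
    supported).  ``backend="builtin"`` uses the in-repo vacuum engine;
    ``backend="openmm"`` requires the external OpenMM engine.
    """
    from .mm import engine as _engine

    return _engine.make_surface(topology_spec, backend=backend, **kwargs)
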