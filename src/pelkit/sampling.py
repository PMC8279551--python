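"""Basin-hopping global optimization and tight local minimization.

Basin-hopping transforms the landscape into interpenetrating catchment
basins: each step perturbs the current coordinates (random Cartesian
displacement and/or rigid rotation of a group of atoms about a bond axis),
minimizes, and accepts or rejects the *minimized* energy with a Metropolis
criterion.  The transformation preserves the global minimum and the relative
ordering of minima while removing downhill barriers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .constants import EIGENVALUE_TO_OMEGA_SQ, KB, TWO_PI
from .ktn import KineticTransitionNetwork, Minimum, add_minimum
from .potentials import PotentialSurface


class ConvergenceError(RuntimeError):
    """Minimization failed; carries the best point found."""

    def __init__(self, msg: str, x: np.ndarray, V: float, rms: float):
        super().__init__(msg)
        self.x = x
        self.V = V
        self.rms = rms


@dataclass
class MinimizationResult:
    x: np.ndarray
    V: float
    rms_grad: float
    n_iter: int
    is_minimum: bool | None = None
    kappa: int | None = None
    nu_bar: float | None = None
    frequencies: np.ndarray | None = None

    def as_minimum(self, n_iso: int = 1) -> Minimum:
        if self.kappa is None or self.nu_bar is None:
            raise ValueError("minimization was run without characterize=True")
        return Minimum(
            V=self.V,
            nu_bar=self.nu_bar,
            kappa=self.kappa,
            n_iso=n_iso,
            coords=self.x.copy(),
        )


def _rms(g: np.ndarray) -> float:
    return float(np.sqrt(np.mean(g * g)))


def vibrational_analysis(
    surface: PotentialSurface, x: np.ndarray, zero_tol: float = 1e-5
) -> tuple[int, np.ndarray]:
    """Normal-mode eigenvalues at x after mass weighting and projection.

    Mass-weights the Hessian, projects out the surface's declared rigid-body
    zero modes, and returns ``(kappa, eigenvalues)`` where the eigenvalues
    are in kcal mol^-1 A^-2 amu^-1 and kappa = ndof - n_zero_modes.
    Negative eigenvalues are returned as negative (imaginary modes).
    """
    x = np.asarray(x, dtype=float)
    h = surface.hessian(x)
    m = surface.dof_masses(x)
    inv_sqrt_m = 1.0 / np.sqrt(m)
    hw = h * inv_sqrt_m[:, None] * inv_sqrt_m[None, :]
    basis = surface.zero_mode_basis(x, mass_weighted=True)
    if basis is not None and basis.size:
        # project the mass-weighted rigid modes out of the Hessian
        p = np.eye(x.size) - basis @ basis.T
        hw = p @ hw @ p
    evals = np.linalg.eigvalsh(hw)
    nzero = surface.n_zero_modes
    if nzero:
        # drop the nzero eigenvalues of smallest magnitude (the projected
        # rigid modes sit numerically at ~0)
        idx = np.argsort(np.abs(evals))
        keep = np.sort(idx[nzero:])
        evals = evals[keep]
    kappa = x.size - nzero
    return kappa, np.sort(evals)


def frequencies_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Convert positive normal-mode eigenvalues to frequencies in s^-1."""
    evals = np.asarray(evals, dtype=float)
    if np.any(evals <= 0):
        raise ValueError("non-positive eigenvalue passed to frequency conversion")
    return np.sqrt(evals * EIGENVALUE_TO_OMEGA_SQ) / TWO_PI


def local_minimize(
    surface: PotentialSurface,
    x0,
    rms_tol: float = 1e-6,
    max_iter: int = 20000,
    characterize: bool = False,
    polish_iter: int = 200,
) -> MinimizationResult:
    """Minimize to RMS gradient <= rms_tol (limited-memory quasi-Newton).

    Runs L-BFGS and, if the target RMS is tighter than L-BFGS achieves,
    polishes with modified-Newton steps (eigenvalue-shifted, so it is robust
    to slightly indefinite Hessians away from the solution and to exact
    rigid-body zero modes, which are ignored).  With ``characterize=True``
    the result carries kappa and the geometric-mean frequency from the
    projected mass-weighted Hessian; a point whose real frequencies are not
    all positive is flagged ``is_minimum=False``.
    """
    x0 = np.asarray(x0, dtype=float).ravel()
    if not np.isfinite(surface.energy(x0)):
        raise ValueError("non-finite energy at the starting point")

    res = _scipy_minimize(
        lambda x: surface.energy(x),
        x0,
        jac=lambda x: surface.gradient(x),
        method="L-BFGS-B",
        options={
            "maxiter": max_iter,
            "ftol": 1e-16,
            "gtol": rms_tol * 1e-2,
            "maxcor": 20,
        },
    )
    x = np.asarray(res.x, dtype=float)
    g = surface.gradient(x)
    n_iter = int(res.nit)

    # Newton polish to reach tight RMS-gradient targets
    it = 0
    while _rms(g) > rms_tol and it < polish_iter:
        h = surface.hessian(x)
        evals, vecs = np.linalg.eigh(h)
        gl = vecs.T @ g
        lam = np.abs(evals)
        floor = max(1e-10, 1e-8 * lam.max())
        step = np.zeros_like(gl)
        nz = lam > floor
        step[nz] = -gl[nz] / lam[nz]
        dx = vecs @ step
        norm = np.linalg.norm(dx)
        if norm > 0.5:
            dx *= 0.5 / norm
        xn = x + dx
        if surface.energy(xn) > surface.energy(x) + 1e-12 and norm > 1e-9:
            dx *= 0.1
            xn = x + dx
        x = xn
        g = surface.gradient(x)
        it += 1
    n_iter += it

    rms = _rms(g)
    if rms > rms_tol:
        raise ConvergenceError(
            f"RMS gradient {rms:.3e} above tolerance {rms_tol:.3e} "
            f"after {n_iter} iterations",
            x=x,
            V=surface.energy(x),
            rms=rms,
        )

    out = MinimizationResult(x=x, V=float(surface.energy(x)), rms_grad=rms, n_iter=n_iter)
    if characterize:
        kappa, evals = vibrational_analysis(surface, x)
        out.kappa = kappa
        out.is_minimum = bool(np.all(evals > 0))
        if out.is_minimum:
            nus = frequencies_from_eigenvalues(evals)
            out.frequencies = nus
            out.nu_bar = float(np.exp(np.mean(np.log(nus))))
    return out


@dataclass
class GroupRotationMove:
    """Rigid rotation of ``atoms`` about the axis through atom pair ``axis``.

    Angles are drawn uniformly from (-max_angle_deg, max_angle_deg); the move
    is attempted with probability ``probability`` at each basin-hopping step.
    """

    atoms: tuple[int, ...]
    axis: tuple[int, int]
    max_angle_deg: float = 60.0
    probability: float = 1.0


@dataclass
class BasinHoppingConfig:
    n_steps: int = 100
    temperature: float = 1.0 / KB  # Metropolis temperature, K (k_B T = 1 kcal/mol)
    cartesian_step: float = 0.4  # Angstrom (or coordinate units)
    group_rotations: list[GroupRotationMove] = field(default_factory=list)
    rng_seed: int = 0
    rms_tol: float = 1e-6
    e_tol: float = 1e-3
    rmsd_tol: float = 0.05
    max_retries: int = 3
    characterize: bool = True

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.temperature <= 0 or self.cartesian_step <= 0:
            raise ValueError("temperature and step size must be positive")


def rotate_group(
    x: np.ndarray, atoms, axis: tuple[int, int], angle_rad: float
) -> np.ndarray:
    """Rotate the listed atoms about the axis through two atom positions."""
    from scipy.spatial.transform import Rotation

    xyz = np.asarray(x, dtype=float).reshape(-1, 3).copy()
    i, j = axis
    origin = xyz[i]
    direction = xyz[j] - xyz[i]
    nrm = np.linalg.norm(direction)
    if nrm < 1e-12:
        return xyz.ravel()
    rot = Rotation.from_rotvec(angle_rad * direction / nrm)
    idx = list(atoms)
    xyz[idx] = rot.apply(xyz[idx] - origin) + origin
    return xyz.ravel()


@dataclass
class BasinHoppingResult:
    network: KineticTransitionNetwork
    accepted: int
    attempted: int
    trajectory: list[int] = field(default_factory=list)  # id visited per step

    @property
    def acceptance_fraction(self) -> float:
        return self.accepted / max(self.attempted, 1)

    @property
    def minima(self) -> list[Minimum]:
        return [self.network.minima[i] for i in sorted(self.network.minima)]


def basin_hop(
    surface: PotentialSurface,
    x0,
    config: BasinHoppingConfig,
    net: KineticTransitionNetwork | None = None,
) -> BasinHoppingResult:
    """Run basin-hopping from x0; deterministic for a fixed seed.

    New minima are deduplicated into the (possibly supplied) network via
    energy and best-superposition-RMSD thresholds.  Minima whose projected
    Hessian is not positive definite are discarded.
    """
    rng = np.random.default_rng(config.rng_seed)
    if net is None:
        net = KineticTransitionNetwork()

    def _minimize_retry(xstart):
        last = None
        for attempt in range(config.max_retries + 1):
            try:
                return local_minimize(
                    surface,
                    xstart,
                    rms_tol=config.rms_tol,
                    characterize=config.characterize,
                )
            except ConvergenceError as exc:
                last = exc
                xstart = exc.x + rng.normal(scale=1e-3, size=exc.x.size)
        raise last

    cur = _minimize_retry(np.asarray(x0, dtype=float).ravel())
    cur.x = surface.canonicalize(cur.x)
    cur_x, cur_v = cur.x, cur.V
    if cur.is_minimum is not False:
        mid, _ = add_minimum(net, cur.as_minimum() if config.characterize else Minimum(
            V=cur_v, nu_bar=1.0, kappa=max(surface.ndof - surface.n_zero_modes, 1),
            coords=cur_x.copy()), config.e_tol, config.rmsd_tol,
            metric=surface.distance)
    else:
        mid = -1

    accepted = 0
    trajectory = []
    kbt = KB * config.temperature
    for _ in range(config.n_steps):
        xt = cur_x + rng.uniform(-1.0, 1.0, size=cur_x.size) * config.cartesian_step
        for mv in config.group_rotations:
            if rng.random() < mv.probability:
                ang = math.radians(rng.uniform(-mv.max_angle_deg, mv.max_angle_deg))
                xt = rotate_group(xt, mv.atoms, mv.axis, ang)
        try:
            trial = _minimize_retry(xt)
        except ConvergenceError:
            trajectory.append(mid)
            continue
        if trial.is_minimum is False:
            trajectory.append(mid)
            continue
        trial.x = surface.canonicalize(trial.x)
        if config.characterize:
            cand = trial.as_minimum()
        else:
            cand = Minimum(
                V=trial.V,
                nu_bar=1.0,
                kappa=max(surface.ndof - surface.n_zero_modes, 1),
                coords=trial.x.copy(),
            )
        new_id, _ = add_minimum(net, cand, config.e_tol, config.rmsd_tol,
                                metric=surface.distance)
        # Metropolis on minimized energies
        if trial.V <= cur_v or rng.random() < math.exp(-(trial.V - cur_v) / kbt):
            cur_x, cur_v, mid = trial.x, trial.V, new_id
            accepted += 1
        trajectory.append(mid)

    return BasinHoppingResult(
        network=net, accepted=accepted, attempted=config.n_steps, trajectory=trajectory
    )
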