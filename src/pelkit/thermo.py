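"""Harmonic superposition thermodynamics.

The total canonical partition function is a sum over the catchment basins of
the local minima, each treated as a classical harmonic well:

    Z_i(T) = n_i exp(-V_i / k_B T) / (beta h nu_bar_i)^kappa

with n_i the number of permutation-inversion isomers, nu_bar_i the geometric
mean normal-mode frequency and kappa the number of vibrational degrees of
freedom.  Local free energies are F_i = -k_B T ln Z_i, occupation
probabilities p_i = Z_i / sum_j Z_j, and the heat capacity follows from the
standard fluctuation relation applied to the superposition ensemble.  All
sums are evaluated in log space so that energy gaps much larger than k_B T
(e.g. the ~13 kcal/mol cis/trans gap of a capped dipeptide at low T) do not
overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import KB, PLANCK
from .ktn import KineticTransitionNetwork, Minimum, TransitionState


class DomainError(ValueError):
    pass


def _check_T(T: float) -> None:
    if T <= 0:
        raise DomainError("temperature must be positive")


def ln_z_min(m: Minimum, T: float) -> float:
    """ln of the classical harmonic basin partition function of a minimum."""
    _check_T(T)
    kbt = KB * T
    return (
        math.log(m.n_iso)
        - m.V / kbt
        - m.kappa * math.log(PLANCK * m.nu_bar / kbt)
    )


def z_min(m: Minimum, T: float) -> float:
    return math.exp(ln_z_min(m, T))


def ln_z_ts(t: TransitionState, kappa: int, T: float) -> float:
    """ln partition function of a transition state: kappa-1 real modes."""
    _check_T(T)
    kbt = KB * T
    out = math.log(t.n_iso) - t.V / kbt
    if kappa > 1:
        out -= (kappa - 1) * math.log(PLANCK * t.nu_bar_real / kbt)
    return out


def z_ts(t: TransitionState, kappa: int, T: float) -> float:
    return math.exp(ln_z_ts(t, kappa, T))


def _ln_z_array(net: KineticTransitionNetwork, T: float) -> tuple[list[int], np.ndarray]:
    ids = sorted(net.minima)
    lnz = np.array([ln_z_min(net.minima[i], T) for i in ids])
    return ids, lnz


def populations(net: KineticTransitionNetwork, T: float) -> dict[int, float]:
    """Equilibrium occupation probability of every minimum at T."""
    _check_T(T)
    if net.n_minima < 1:
        raise DomainError("network has no minima")
    ids, lnz = _ln_z_array(net, T)
    lnp = lnz - logsumexp(lnz)
    return dict(zip(ids, np.exp(lnp)))


def free_energies(net: KineticTransitionNetwork, T: float) -> dict[int, float]:
    """Local free energy F_i = -k_B T ln Z_i of every minimum at T."""
    ids, lnz = _ln_z_array(net, T)
    return dict(zip(ids, -KB * T * lnz))


def ts_free_energy(net: KineticTransitionNetwork, tid: int, T: float) -> float:
    """F = -k_B T ln Z of a transition state (imaginary mode excluded)."""
    return -KB * T * ln_z_ts(net.transition_states[tid], net.kappa, T)


def group_free_energy(net: KineticTransitionNetwork, ids, T: float) -> float:
    """-k_B T ln sum of basin partition functions over a group of minima."""
    _check_T(T)
    ids = list(ids)
    if not ids:
        raise ValueError("empty group")
    lnz = np.array([ln_z_min(net.minima[i], T) for i in ids])
    return float(-KB * T * logsumexp(lnz))


def delta_f(net: KineticTransitionNetwork, group_a, group_b, T: float) -> float:
    """Free-energy gap F(group_b) - F(group_a) at temperature T.

    Groups are disjoint, non-empty sets of minimum ids (e.g. all C5-family
    minima vs all C7eq-family minima).
    """
    a, b = set(group_a), set(group_b)
    if not a or not b:
        raise ValueError("groups must be non-empty")
    if a & b:
        raise ValueError("groups must be disjoint")
    return group_free_energy(net, b, T) - group_free_energy(net, a, T)


@dataclass
class ThermoResult:
    """Ensemble thermodynamics on a temperature grid."""

    T: np.ndarray
    ln_Z: np.ndarray
    U: np.ndarray  # internal energy V(T), kcal/mol
    Cv: np.ndarray  # heat capacity, kcal mol^-1 K^-1
    Cv_per_atom: np.ndarray | None
    populations: np.ndarray  # (n_T, n_minima), column order = sorted ids
    minimum_ids: list[int]
    peaks_T: np.ndarray  # temperatures of local Cv maxima

    def to_table(self):
        import pandas as pd

        cols = {"T": self.T, "ln_Z": self.ln_Z, "U": self.U, "Cv": self.Cv}
        if self.Cv_per_atom is not None:
            cols["Cv_per_atom"] = self.Cv_per_atom
        return pd.DataFrame(cols)


def _moments(net: KineticTransitionNetwork, T: float):
    """Helper: ln Z, <V + kappa k T>, Var(V + kappa k T) under p_i(T)."""
    ids, lnz = _ln_z_array(net, T)
    lnzt = logsumexp(lnz)
    p = np.exp(lnz - lnzt)
    kbt = KB * T
    kappas = np.array([net.minima[i].kappa for i in ids], dtype=float)
    e = np.array([net.minima[i].V for i in ids]) + kappas * kbt
    mean = float(p @ e)
    var = float(p @ (e - mean) ** 2)
    return ids, lnzt, p, mean, var, kappas


def heat_capacity(
    net: KineticTransitionNetwork,
    T_grid,
    n_atoms: int | None = None,
) -> ThermoResult:
    """Superposition heat capacity on a temperature grid.

    Closed form for classical harmonic wells: with E_i = V_i + kappa_i k_B T,

        U(T)  = <E>_p
        Cv(T) = k_B <kappa>_p + Var_p(E) / (k_B T^2)

    which reduces to ``kappa k_B + (<V^2> - <V>^2)/(k_B T^2)`` when all
    minima share kappa.  Peak locations are reported from a local-maximum
    scan over the grid.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    if T_grid.size < 3:
        raise ValueError("temperature grid needs at least 3 points for peaks")
    if np.any(T_grid <= 0) or np.any(np.diff(T_grid) <= 0):
        raise ValueError("grid must be strictly increasing and positive")

    n_t = T_grid.size
    ids = sorted(net.minima)
    lnZ = np.empty(n_t)
    U = np.empty(n_t)
    Cv = np.empty(n_t)
    pops = np.empty((n_t, len(ids)))
    for k, T in enumerate(T_grid):
        _, lnzt, p, mean, var, kappas = _moments(net, T)
        lnZ[k] = lnzt
        U[k] = mean
        Cv[k] = KB * float(p @ kappas) + var / (KB * T * T)
        pops[k] = p

    interior = (Cv[1:-1] > Cv[:-2]) & (Cv[1:-1] > Cv[2:])
    peaks = T_grid[1:-1][interior]
    return ThermoResult(
        T=T_grid,
        ln_Z=lnZ,
        U=U,
        Cv=Cv,
        Cv_per_atom=Cv / n_atoms if n_atoms else None,
        populations=pops,
        minimum_ids=ids,
        peaks_T=peaks,
    )


def ensemble_ln_z(net: KineticTransitionNetwork, T: float) -> float:
    _, lnz = _ln_z_array(net, T)
    return float(logsumexp(lnz))


def heat_capacity_numerical(
    net: KineticTransitionNetwork, T: float, rel_step: float = 1e-4
) -> float:
    """Heat capacity by numerical differentiation of ln Z (reference route).

    Uses Cv = d/dT (k_B T^2 d ln Z / dT) evaluated with a five-point central
    stencil on ln Z; independent of the closed-form fluctuation expression.
    """
    _check_T(T)
    h = rel_step * T
    ts = T + h * np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    lnz = np.array([ensemble_ln_z(net, t) for t in ts])
    dlnz = (lnz[0] - 8 * lnz[1] + 8 * lnz[3] - lnz[4]) / (12 * h)
    d2lnz = (-lnz[0] + 16 * lnz[1] - 30 * lnz[2] + 16 * lnz[3] - lnz[4]) / (
        12 * h * h
    )
    # Cv = 2 k T dlnZ/dT + k T^2 d2lnZ/dT2
    return float(2 * KB * T * dlnz + KB * T * T * d2lnz)
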