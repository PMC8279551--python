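"""Stationary points and the kinetic transition network.

A kinetic transition network (KTN) is a multigraph whose nodes are local
minima of a potential energy surface and whose edges are first-order saddle
points (transition states), each linking exactly two minima (possibly the
same one, for a degenerate rearrangement).  The network is persisted as two
whitespace-separated text files, one record per stationary point, following
the conventions of stationary-point databases in the energy-landscape
literature: the vibrational information is stored as ln of the product of
normal-mode frequencies (in s^-1), from which the geometric mean is derived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import networkx as nx


class IntegrityError(ValueError):
    """A record violates the structural constraints of the network."""


class ParseError(ValueError):
    """A database line could not be parsed."""


class DimensionError(ValueError):
    """A candidate stationary point has incompatible degrees of freedom."""


@dataclass
class Minimum:
    """A local minimum of the potential energy surface.

    Parameters
    ----------
    V : float
        Potential energy, kcal/mol.
    nu_bar : float
        Geometric mean of the normal-mode frequencies, s^-1.
    kappa : int
        Number of vibrational degrees of freedom.
    n_iso : int
        Number of distinct permutation-inversion isomers.
    coords : ndarray, optional
        Cartesian coordinates (flat or (N, 3)), Angstrom.
    family, isomer : str, optional
        Conformer-family tag (e.g. ``"C7eq"``) and peptide-bond isomer tag
        (``"cis"``/``"trans"``).
    """

    V: float
    nu_bar: float
    kappa: int
    n_iso: int = 1
    coords: np.ndarray | None = None
    family: str | None = None
    isomer: str | None = None
    inertia: tuple[float, float, float] | None = None
    id: int | None = None

    def __post_init__(self) -> None:
        if self.nu_bar <= 0:
            raise IntegrityError("nu_bar must be positive")
        if self.kappa < 1:
            raise IntegrityError("kappa must be >= 1")
        if self.n_iso < 1:
            raise IntegrityError("n_iso must be >= 1")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)

    @property
    def ln_prod_nu(self) -> float:
        """ln of the product of the kappa normal-mode frequencies."""
        return self.kappa * math.log(self.nu_bar)


@dataclass
class TransitionState:
    """A first-order saddle linking two minima.

    ``nu_bar_real`` is the geometric mean over the kappa-1 *real* normal
    modes; the imaginary mode is excluded.
    """

    V: float
    nu_bar_real: float
    min_a: int
    min_b: int
    n_iso: int = 1
    coords: np.ndarray | None = None
    inertia: tuple[float, float, float] | None = None
    id: int | None = None

    def __post_init__(self) -> None:
        if self.nu_bar_real <= 0:
            raise IntegrityError("nu_bar_real must be positive")
        if self.n_iso < 1:
            raise IntegrityError("n_iso must be >= 1")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)

    def ln_prod_nu(self, kappa: int) -> float:
        """ln prod of the kappa-1 real frequencies."""
        return (kappa - 1) * math.log(self.nu_bar_real)

    def other_end(self, mid: int) -> int:
        if mid == self.min_a:
            return self.min_b
        if mid == self.min_b:
            return self.min_a
        raise KeyError(f"minimum {mid} is not an endpoint of TS {self.id}")


class KineticTransitionNetwork:
    """Container for minima and transition states with multigraph adjacency."""

    def __init__(self, ts_energy_tol: float = 1e-6) -> None:
        self.minima: dict[int, Minimum] = {}
        self.transition_states: dict[int, TransitionState] = {}
        self.ts_energy_tol = ts_energy_tol
        self._next_min_id = 0
        self._next_ts_id = 0

    # -- construction -----------------------------------------------------

    def add_minimum_record(self, m: Minimum) -> int:
        """Insert a minimum without deduplication; returns its id."""
        if self.minima:
            kappa0 = next(iter(self.minima.values())).kappa
            if m.kappa != kappa0:
                raise DimensionError(
                    f"kappa={m.kappa} does not match network kappa={kappa0}"
                )
        mid = m.id if m.id is not None else self._next_min_id
        if mid in self.minima:
            raise IntegrityError(f"duplicate minimum id {mid}")
        m.id = mid
        self.minima[mid] = m
        self._next_min_id = max(self._next_min_id, mid + 1)
        return mid

    def add_ts_record(self, t: TransitionState, permissive: bool = False) -> int:
        if t.min_a not in self.minima or t.min_b not in self.minima:
            raise IntegrityError(
                f"transition state references unknown minima ({t.min_a}, {t.min_b})"
            )
        lo = max(self.minima[t.min_a].V, self.minima[t.min_b].V)
        if t.V < lo - self.ts_energy_tol and not permissive:
            raise IntegrityError(
                f"transition state energy {t.V:.6g} below endpoint energy {lo:.6g}"
            )
        tid = t.id if t.id is not None else self._next_ts_id
        if tid in self.transition_states:
            raise IntegrityError(f"duplicate transition state id {tid}")
        t.id = tid
        self.transition_states[tid] = t
        self._next_ts_id = max(self._next_ts_id, tid + 1)
        return tid

    # -- views ------------------------------------------------------------

    @property
    def n_minima(self) -> int:
        return len(self.minima)

    @property
    def kappa(self) -> int:
        if not self.minima:
            raise IntegrityError("empty network has no kappa")
        return next(iter(self.minima.values())).kappa

    def graph(self) -> nx.MultiGraph:
        """Multigraph view; edge key is the transition-state id."""
        g = nx.MultiGraph()
        g.add_nodes_from(self.minima)
        for tid, t in self.transition_states.items():
            g.add_edge(t.min_a, t.min_b, key=tid, V=t.V)
        return g

    def connected_components(self) -> list[set[int]]:
        return [set(c) for c in nx.connected_components(self.graph())]

    def global_minimum(self) -> Minimum:
        return min(self.minima.values(), key=lambda m: (m.V, m.id))

    def adjacent_ts(self, mid: int) -> list[TransitionState]:
        return [
            t
            for t in self.transition_states.values()
            if mid in (t.min_a, t.min_b)
        ]

    def ids_by_family(self, family: str, isomer: str | None = None) -> set[int]:
        out = set()
        for mid, m in self.minima.items():
            if m.family == family and (isomer is None or m.isomer == isomer):
                out.add(mid)
        return out

    def copy(self) -> "KineticTransitionNetwork":
        net = KineticTransitionNetwork(ts_energy_tol=self.ts_energy_tol)
        for m in self.minima.values():
            net.add_minimum_record(replace(m))
        for t in self.transition_states.values():
            net.add_ts_record(replace(t))
        return net


# -- deduplicating insertion ----------------------------------------------


def best_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two conformations after optimal superposition.

    For 3D molecular coordinates (size divisible by 3, at least 3 sites)
    both sets are centered and aligned with the Kabsch algorithm (via
    scipy.spatial.transform.Rotation.align_vectors); for generic
    low-dimensional surfaces, where rigid-body symmetry is absent, the plain
    per-coordinate RMS difference is returned.
    """
    from scipy.spatial.transform import Rotation

    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise DimensionError("coordinate shapes differ")
    if a.size % 3 or a.size < 9:
        return float(np.sqrt(np.mean((a - b) ** 2)))
    a3 = a.reshape(-1, 3)
    b3 = b.reshape(-1, 3)
    a3 = a3 - a3.mean(axis=0)
    b3 = b3 - b3.mean(axis=0)
    _, rssd = Rotation.align_vectors(a3, b3)
    return float(rssd / math.sqrt(a3.shape[0]))


def add_minimum(
    net: KineticTransitionNetwork,
    cand: Minimum,
    e_tol: float = 1e-3,
    rmsd_tol: float = 0.05,
    metric=None,
) -> tuple[int, bool]:
    """Insert ``cand`` unless an equivalent minimum already exists.

    Two minima are equivalent when their energies differ by at most ``e_tol``
    and, if both carry coordinates, the configuration distance is at most
    ``rmsd_tol`` (best-superposition RMSD by default; a surface may supply a
    periodic-aware ``metric``).  Returns ``(id, is_new)``.
    """
    if e_tol <= 0 or rmsd_tol <= 0:
        raise ValueError("tolerances must be positive")
    dist = metric or best_rmsd
    for mid, m in net.minima.items():
        if abs(m.V - cand.V) > e_tol:
            continue
        if m.coords is not None and cand.coords is not None:
            if dist(m.coords, cand.coords) > rmsd_tol:
                continue
        return mid, False
    return net.add_minimum_record(cand), True


def add_transition_state(
    net: KineticTransitionNetwork,
    cand: TransitionState,
    e_tol: float = 1e-3,
    rmsd_tol: float = 0.05,
    metric=None,
) -> tuple[int, bool]:
    """Insert a transition state unless an equivalent one exists."""
    ends = {cand.min_a, cand.min_b}
    dist = metric or best_rmsd
    for tid, t in net.transition_states.items():
        if {t.min_a, t.min_b} != ends or abs(t.V - cand.V) > e_tol:
            continue
        if t.coords is not None and cand.coords is not None:
            if dist(t.coords, cand.coords) > rmsd_tol:
                continue
        return tid, False
    return net.add_ts_record(cand), True


# -- flat-file database I/O -------------------------------------------------

_FMT = "%.12g"


def _parse_line(line: str, path: str, lineno: int, min_cols: int) -> list[float]:
    parts = line.split()
    try:
        vals = [float(p) for p in parts]
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: malformed record: {line!r}") from exc
    if len(vals) < min_cols:
        raise ParseError(
            f"{path}:{lineno}: expected >= {min_cols} columns, got {len(vals)}"
        )
    return vals


def read_database(
    min_file,
    ts_file,
    permissive: bool = False,
    ts_energy_tol: float = 1e-6,
) -> KineticTransitionNetwork:
    """Load a stationary-point database.

    Minima file columns: ``V  ln(prod nu)  n_iso  kappa  [Ix Iy Iz]``.
    Transition-state file columns: ``V  ln(prod nu_real)  n_iso  min_a  min_b
    [Ix Iy Iz]`` with 1-based minima indices.  Lines starting with ``#`` are
    comments.
    """
    net = KineticTransitionNetwork(ts_energy_tol=ts_energy_tol)
    min_file, ts_file = str(min_file), str(ts_file)
    with open(min_file) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            v = _parse_line(line, min_file, lineno, 4)
            kappa = int(round(v[3]))
            inertia = tuple(v[4:7]) if len(v) >= 7 else None
            net.add_minimum_record(
                Minimum(
                    V=v[0],
                    nu_bar=math.exp(v[1] / kappa),
                    kappa=kappa,
                    n_iso=int(round(v[2])),
                    inertia=inertia,
                )
            )
    kappa = net.kappa if net.minima else None
    with open(ts_file) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            v = _parse_line(line, ts_file, lineno, 5)
            a, b = int(round(v[3])), int(round(v[4]))
            if a < 1 or a > net.n_minima or b < 1 or b > net.n_minima:
                raise IntegrityError(
                    f"{ts_file}:{lineno}: transition state references minimum "
                    f"{max(a, b)} of {net.n_minima}"
                )
            inertia = tuple(v[5:8]) if len(v) >= 8 else None
            net.add_ts_record(
                TransitionState(
                    V=v[0],
                    nu_bar_real=math.exp(v[1] / (kappa - 1)) if kappa > 1 else 1.0,
                    n_iso=int(round(v[2])),
                    min_a=a - 1,
                    min_b=b - 1,
                    inertia=inertia,
                ),
                permissive=permissive,
            )
    return net


def write_database(net: KineticTransitionNetwork, min_file, ts_file) -> None:
    """Write the database in the format read by :func:`read_database`.

    Minima are written in ascending id order; file indices are therefore
    1-based positions in that order.
    """
    order = sorted(net.minima)
    pos = {mid: i + 1 for i, mid in enumerate(order)}
    with open(str(min_file), "w") as fh:
        for mid in order:
            m = net.minima[mid]
            cols = [_FMT % m.V, _FMT % m.ln_prod_nu, str(m.n_iso), str(m.kappa)]
            if m.inertia is not None:
                cols += [_FMT % x for x in m.inertia]
            fh.write(" ".join(cols) + "\n")
    kappa = net.kappa if net.minima else 2
    with open(str(ts_file), "w") as fh:
        for tid in sorted(net.transition_states):
            t = net.transition_states[tid]
            ln_prod = t.ln_prod_nu(kappa) if kappa > 1 else 0.0
            cols = [
                _FMT % t.V,
                _FMT % ln_prod,
                str(t.n_iso),
                str(pos[t.min_a]),
                str(pos[t.min_b]),
            ]
            if t.inertia is not None:
                cols += [_FMT % x for x in t.inertia]
            fh.write(" ".join(cols) + "\n")


# -- ranking ----------------------------------------------------------------


def rank_shift(
    energies_a: dict[int, float], energies_b: dict[int, float]
) -> dict[int, float]:
    """Normalized shift in energy ranking between two energy assignments.

    Ranks are ascending-energy positions (0 = lowest); ties broken by id.
    The shift for each id is ``(rank_b - rank_a) / N``; a negative value
    means the item moved toward a higher rank (relatively stabilized) under
    the second assignment.
    """
    if set(energies_a) != set(energies_b):
        raise KeyError("id sets differ between the two energy maps")
    n = len(energies_a)
    if n < 1:
        raise ValueError("need at least one id")

    def ranks(en: dict[int, float]) -> dict[int, int]:
        order = sorted(en, key=lambda i: (en[i], i))
        return {mid: r for r, mid in enumerate(order)}

    ra, rb = ranks(energies_a), ranks(energies_b)
    return {mid: (rb[mid] - ra[mid]) / n for mid in energies_a}


@dataclass
class DiscretePath:
    """Alternating sequence m0, t1, m1, ..., tN, mN of ids in a network."""

    minima: list[int]
    transition_states: list[int]
    net: KineticTransitionNetwork = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.minima) != len(self.transition_states) + 1:
            raise IntegrityError("path must alternate minima and saddles")
        for i, tid in enumerate(self.transition_states):
            t = self.net.transition_states[tid]
            if {t.min_a, t.min_b} != {self.minima[i], self.minima[i + 1]} and not (
                t.min_a == t.min_b == self.minima[i] == self.minima[i + 1]
            ):
                raise IntegrityError(f"TS {tid} does not link step {i}")

    def __len__(self) -> int:
        return len(self.transition_states)

    @property
    def energies(self) -> np.ndarray:
        """Energy profile V(m0), V(t1), V(m1), ..."""
        out = [self.net.minima[self.minima[0]].V]
        for i, tid in enumerate(self.transition_states):
            out.append(self.net.transition_states[tid].V)
            out.append(self.net.minima[self.minima[i + 1]].V)
        return np.array(out)

    @property
    def roles(self) -> list[str]:
        out = ["min"]
        for _ in self.transition_states:
            out += ["ts", "min"]
        return out

    def highest_barrier(self) -> float:
        """max V along the path minus the energy of the first minimum."""
        if not self.transition_states:
            return 0.0
        vts = max(self.net.transition_states[t].V for t in self.transition_states)
        return vts - self.net.minima[self.minima[0]].V

    def to_table(self):
        import pandas as pd

        e = self.energies
        return pd.DataFrame(
            {"step": range(len(e)), "role": self.roles, "V": e}
        )
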