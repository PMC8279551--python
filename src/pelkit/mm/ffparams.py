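"""Curated force-field parameter set (AMBER functional form).

A compact, self-contained parameterization for capped alanine and serine
dipeptides in vacuum, assembled from the published AMBER protein
force-field family (Cornell-style charges and bonded terms with
ff99SB-lineage backbone torsions).  It follows the standard functional form

    V = sum Kb (r - r0)^2 + sum Ka (theta - theta0)^2
      + sum (Vn/2)(1 + cos(n phi - gamma))            (propers + impropers)
      + sum_{i<j} [ eps (rmin/r)^12 - 2 eps (rmin/r)^6 + qq/r ]

with 1-4 electrostatics divided by 1.2 and 1-4 Lennard-Jones by 2.0, and no
nonbonded truncation.  This is a reconstruction for in-package use, not a
verbatim copy of any distributed parameter database; small deviations from
any specific released force-field version are expected.

Units: kcal/mol, Angstrom, degrees (converted to radians at load), amu,
elementary charges.
"""

from __future__ import annotations

# Atom-type aliases: backbone CA uses a dedicated type in recent force
# fields; its bonded parameters duplicate the generic tetrahedral carbon.
TYPE_ALIASES = {"CX": "CT", "2C": "CT", "3C": "CT"}

MASSES = {
    "H": 1.008,
    "H1": 1.008,
    "HC": 1.008,
    "HO": 1.008,
    "C": 12.01,
    "CT": 12.01,
    "CX": 12.01,
    "2C": 12.01,
    "N": 14.01,
    "O": 16.00,
    "OH": 16.00,
}

ELEMENTS = {
    "H": "H",
    "H1": "H",
    "HC": "H",
    "HO": "H",
    "C": "C",
    "CT": "C",
    "CX": "C",
    "2C": "C",
    "N": "N",
    "O": "O",
    "OH": "O",
}

# Lennard-Jones: type -> (rmin/2 in Angstrom, epsilon in kcal/mol)
LENNARD_JONES = {
    "H": (0.6000, 0.0157),
    "HO": (0.0000, 0.0000),
    "HC": (1.4870, 0.0157),
    "H1": (1.3870, 0.0157),
    "CT": (1.9080, 0.1094),
    "CX": (1.9080, 0.1094),
    "2C": (1.9080, 0.1094),
    "C": (1.9080, 0.0860),
    "N": (1.8240, 0.1700),
    "O": (1.6612, 0.2100),
    "OH": (1.7210, 0.2104),
}

# Bonds: (type_i, type_j) -> (Kb kcal/mol/A^2, r0 A); canonical (alias-
# normalized, sorted) keys.
BONDS = {
    ("C", "CT"): (317.0, 1.522),
    ("C", "N"): (490.0, 1.335),
    ("C", "O"): (570.0, 1.229),
    ("CT", "CT"): (310.0, 1.526),
    ("CT", "HC"): (340.0, 1.090),
    ("CT", "H1"): (340.0, 1.090),
    ("CT", "N"): (337.0, 1.449),
    ("CT", "OH"): (320.0, 1.410),
    ("HO", "OH"): (553.0, 0.960),
    ("H", "N"): (434.0, 1.010),
}

# Angles: (ti, tj_central, tk) -> (Ka kcal/mol/rad^2, theta0 deg); outer
# types sorted.
ANGLES = {
    ("CT", "C", "N"): (70.0, 116.60),
    ("CT", "C", "O"): (80.0, 120.40),
    ("N", "C", "O"): (80.0, 122.90),
    ("C", "N", "CT"): (50.0, 121.90),
    ("C", "N", "H"): (50.0, 120.00),
    ("CT", "N", "H"): (50.0, 118.04),
    ("H", "N", "H"): (35.0, 120.00),
    ("C", "CT", "CT"): (63.0, 111.10),
    ("C", "CT", "H1"): (50.0, 109.50),
    ("C", "CT", "HC"): (50.0, 109.50),
    ("C", "CT", "N"): (63.0, 110.10),
    ("CT", "CT", "H1"): (50.0, 109.50),
    ("CT", "CT", "HC"): (50.0, 109.50),
    ("HC", "CT", "HC"): (35.0, 109.50),
    ("H1", "CT", "H1"): (35.0, 109.50),
    ("H1", "CT", "N"): (50.0, 109.50),
    ("CT", "CT", "N"): (80.0, 109.70),
    ("CT", "CT", "OH"): (50.0, 109.50),
    ("H1", "CT", "OH"): (50.0, 109.50),
    ("CT", "OH", "HO"): (55.0, 108.50),
}

# Proper torsions: (ti, tj, tk, tl) -> list of (height kcal/mol, phase deg,
# periodicity); "X" is a wildcard for the outer positions.  Heights are
# per-path (any file-format dividers already applied).  Specific
# (non-wildcard) entries REPLACE the wildcard match, as in the source force
# fields.
DIHEDRALS = {
    # amide rotation: the dominant cis/trans barrier
    ("X", "C", "N", "X"): [(2.5, 180.0, 2)],
    # the specific amide H path adds a 1-fold term favoring trans
    ("H", "N", "C", "O"): [(2.5, 180.0, 2), (1.0, 0.0, 1)],
    ("X", "CT", "N", "X"): [(0.0, 0.0, 2)],
    ("X", "C", "CT", "X"): [(0.0, 0.0, 2)],
    ("X", "CT", "CT", "X"): [(1.40 / 9.0, 0.0, 3)],
    ("X", "CT", "OH", "X"): [(0.50 / 3.0, 0.0, 3)],
    # backbone phi: C(-1)-N-CA-C
    ("C", "N", "CT", "C"): [(0.42, 0.0, 3), (0.27, 0.0, 2), (0.00, 0.0, 1)],
    # backbone psi: N-CA-C-N(+1)
    ("N", "CT", "C", "N"): [(0.55, 180.0, 3), (1.58, 180.0, 2), (0.45, 180.0, 1)],
    # phi': C(-1)-N-CA-CB
    ("C", "N", "CT", "CT"): [(0.40, 0.0, 3), (2.00, 0.0, 2), (2.00, 0.0, 1)],
    # psi': CB-CA-C-N(+1)
    ("CT", "CT", "C", "N"): [(0.40, 0.0, 3), (0.20, 0.0, 2), (0.20, 0.0, 1)],
}

# Impropers: applied per sp2 center with the central atom third; the same
# cosine form as propers.
IMPROPERS = {
    ("X", "X", "C", "O"): [(10.5, 180.0, 2)],
    ("X", "X", "N", "H"): [(1.0, 180.0, 2)],
}

SCALE_EE_14 = 1.0 / 1.2
SCALE_LJ_14 = 0.5


def normalize(t: str) -> str:
    return TYPE_ALIASES.get(t, t)


def bond_params(ti: str, tj: str):
    key = tuple(sorted((normalize(ti), normalize(tj))))
    if key not in BONDS:
        raise KeyError(f"no bond parameters for {key}")
    return BONDS[key]


def angle_params(ti: str, tj: str, tk: str):
    a, c = sorted((normalize(ti), normalize(tk)))
    key = (a, normalize(tj), c)
    if key not in ANGLES:
        raise KeyError(f"no angle parameters for {key}")
    return ANGLES[key]


def dihedral_params(ti: str, tj: str, tk: str, tl: str):
    ti, tj, tk, tl = (normalize(t) for t in (ti, tj, tk, tl))
    for a, b, c, d in ((ti, tj, tk, tl), (tl, tk, tj, ti)):
        if (a, b, c, d) in DIHEDRALS:
            return DIHEDRALS[(a, b, c, d)]
    for b, c in ((tj, tk), (tk, tj)):
        if ("X", b, c, "X") in DIHEDRALS:
            return DIHEDRALS[("X", b, c, "X")]
    raise KeyError(f"no torsion parameters for {(ti, tj, tk, tl)}")


def improper_params(tc: str, tlast: str):
    key = ("X", "X", normalize(tc), normalize(tlast))
    if key not in IMPROPERS:
        raise KeyError(f"no improper parameters for {key}")
    return IMPROPERS[key]
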