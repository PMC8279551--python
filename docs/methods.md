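# Methods

This note documents the models, numerical choices and limitations behind
pelkit. Units throughout: energies in kcal/mol, lengths in Å, frequencies
in s⁻¹, temperatures in K, masses in amu; k_B = 1.987204259×10⁻³
kcal mol⁻¹ K⁻¹ and h = 9.537070×10⁻¹⁴ kcal s mol⁻¹.

## Stationary-point databases

A kinetic transition network stores minima (energy `V`, ln of the product
of normal-mode frequencies, isomer count `n_iso`, vibrational degrees of
freedom `κ`, optional coordinates and conformer labels) and transition
states (same fields over the κ−1 real modes, plus the two connected
minimum ids; a saddle may connect a minimum to itself — a degenerate
rearrangement). Flat files hold one record per line with 1-based minimum
indices; ln∏ν is stored rather than the geometric mean ν̄ because sums of
log-frequencies round-trip exactly and match common database conventions.
Moment-of-inertia columns are accepted and preserved but unused (the
thermodynamic expressions here are vibrational-only). A transition state
whose energy falls below an endpoint minimum is rejected at load unless a
permissive flag is set. Duplicate detection for candidate minima uses an
energy window (default 10⁻³ kcal/mol) plus a configuration distance
(default 0.05 Å): best-superposition RMSD for molecular coordinates
(heavy atoms only for the built-in dipeptides, so that methyl/amide
hydrogen permutations collapse onto their canonical conformer), a
periodic-wrap RMS for torsional surfaces.

## Exploration

**Local minimization** runs L-BFGS and then, because quasi-Newton stalls
well above tight gradient targets, a modified-Newton polish
(eigenvalue-magnitude shifted, rigid-body modes ignored) until the RMS
gradient is ≤ 10⁻⁶ kcal mol⁻¹ Å⁻¹, the convergence target used for all
stationary points. Characterized minima carry κ and ν̄ from the
mass-weighted Hessian with the six rigid-body modes projected out
(κ = 3N−6); a point with any non-positive projected eigenvalue is flagged
as not-a-minimum and discarded by the samplers.

**Basin-hopping** perturbs with uniform Cartesian displacements (default
0.4 Å; 0.15 Å for the dipeptides where group moves do most of the work)
and rigid group rotations about designated bond axes (backbone φ, ψ, ω
and side-chain χ for the dipeptides; default amplitude 60°, 120° for the
dipeptide pipeline), minimizes, and applies a Metropolis test on
minimized energies at k_BT = 1 kcal/mol by default. All randomness flows
from one integer seed; identical seeds give byte-identical minima lists.
A protocol of many independent seeded runs is available by invoking the
`explore` command repeatedly with distinct seeds.

**Transition states.** Initial saddle candidates come from a doubly-nudged
elastic band: 11 interior images (default), spring constant 100
kcal mol⁻¹ Å⁻², energy-weighted upwind tangents, with 10% of the residual
perpendicular spring gradient retained for stability, relaxed by a
quenched-velocity integrator (band forces are non-conservative, so
line-search minimizers do not apply). Band relaxation need not converge
fully: interior energy maxima seed hybrid eigenvector-following, which
walks uphill along the lowest Hessian eigenvector while taking Newton
steps in the orthogonal complement, bounded by a 0.2 Å trust radius,
until the RMS gradient is ≤ 10⁻⁶. Because every system here has at most
~60 degrees of freedom, the lowest eigenpair comes from a dense
eigendecomposition of the (rigid-mode-shifted) Hessian rather than an
iterative Hessian-free scheme — simpler and exact at this scale. A
converged point is accepted only with exactly one negative eigenvalue
(Murrell–Laidler); zero or several raise typed errors. The two connected
minima come from approximate steepest descent: displace ±0.05 Å along the
reaction-coordinate eigenvector and minimize.

For peptide-bond isomerization the Cartesian linear interpolation of a
band degrades (a rotating amide shrinks through the molecule), so the
dipeptide pipeline seeds eigenvector-following directly from geometries
with the acetyl group rotated ±90° about the amide C–N axis — the top of
the rotation profile — from every trans minimum.

**Connection and refinement.** `connect_pair` runs Dijkstra on a mixed
graph (known saddle edges near-free; unknown pairs weighted by
min(exp(d/d₀), cap) of their superposition distance), attacks the gaps on
the current best mixed path with band + eigenvector-following + descent,
and repeats until a pure transition-state path exists or the attempt
budget is exhausted; the network only ever gains stationary points.
Refinement schemes: `shortcut` retries direct connections between distant
path endpoints, `shortcut_barrier` attacks the segment flanking the
highest saddle, and `untrap` reconnects minima ranked by (downhill
barrier toward the global minimum)/(energy above it) — the artificial
frustration diagnostic.

## Thermodynamics

Classical harmonic basins: Z_i = n_iso exp(−βV_i)/(βh ν̄_i)^κ, with
transition states using κ−1 real modes. Everything is computed in log
space (log-sum-exp): the ~13 kcal/mol cis/trans gaps would overflow naive
exponentials at low temperature. The heat capacity uses the closed-form
fluctuation expression C_v = k_B⟨κ⟩_p + Var_p(V + κk_BT)/(k_BT²), which
reduces to κk_B + (⟨V²⟩−⟨V⟩²)/(k_BT²) for uniform κ; an independent
numerical route (five-point stencils on ln Z) guards the closed form to
10⁻⁶ relative on random networks. Peaks are local maxima on the grid
(default 10–400 K, 1 K spacing). Rotational/translational contributions
are omitted by design; quantum vibrational corrections and anharmonicity
are out of scope. Free-energy gaps between conformer groups use
−k_BT ln ΣZ_i per group.

## Kinetics

Harmonic TST rates are implemented both as (k_BT/h)(Z‡/Z_i)e^{−βΔV} and
as the algebraically equal frequency form (n‡/n_i)·ν̄_i^κ/ν̄‡^{κ−1}·
e^{−βΔV}; the two routes are cross-checked in tests. Parallel saddles
between the same pair sum their rates. Graph transformation eliminates
intermediate nodes (fewest-neighbors-first; the result is
order-independent and tested as such) with
P′_uv = P_uv + P_ux P_xv/(1−P_xx) and τ′_u = τ_u + P_ux τ_x/(1−P_xx),
where 1−P_xx is accumulated from the off-diagonal branching sum for
stability as P_xx → 1. Two-state rate constants are
source-equilibrium-weighted steady-state fluxes — renormalized branching
with the *original* waiting time of the source — which satisfy detailed
balance k_AB p_A = k_BA p_B exactly; mean first-passage times eliminate
every retained node except one source at a time and are
equilibrium-weighted over the source macrostate. Degenerate-rearrangement
self-loops shorten per-visit waiting times without changing first-passage
observables (self-transitions of a continuous-time Markov chain are
unobservable), and the tests pin that invariance. The dense
master-equation reference (`mfpt_linear_solve`) performs Gaussian
elimination in extended precision because rate matrices mixing ~10¹³ s⁻¹
intra-well and ~10¹ s⁻¹ activated scales are too ill-conditioned for a
bare double-precision solve to serve as a 10⁻⁶ oracle.

## Disconnectivity graphs and classification

Superbasins at threshold E are connected components over saddles with
(free) energy < E, restricted to minima below E; thresholds are regularly
spaced (default ΔE = 1 kcal/mol) from the global-minimum energy to one
step above the highest saddle, guaranteeing a single root on a connected
network. Free-energy variants use the harmonic F of minima and saddles at
a chosen temperature. Export: JSON (nodes/parents/levels/leaf map) and an
SVG rendering with deepest-funnel-first layout and branch coloring by a
minimum label (e.g. cis/trans isomer).

Conformer classification computes φ, ψ, ω with the IUPAC sign convention
in (−180°, 180°]; the isomer is cis iff |ω| < 90° (boundary → trans), and
the family comes from a rectangular (φ,ψ) region table. The shipped table
is an *approximation* to the conventional nine-family segregation —
first-match-wins rectangles whose C7eq region extends down to ψ = 20° so
that conformers forming the seven-membered H-bonded ring are labeled C7
even when a force field places their ψ lower than usual — and is fully
user-configurable (`classify --regions`).

## Synthetic landscapes

The generators define the conditions under which the analysis stages are
validated. Funneled random networks draw minimum offsets uniform(0, 5)
kcal/mol above each funnel bottom, intra-funnel barriers log-uniform(0.5,
8) kcal/mol (bracketing the dipeptide gaps and barriers), frequencies
ν̄ = 10¹³·exp(N(0, 0.1)) s⁻¹, and join funnels only through saddles a
fixed barrier (default 13 kcal/mol, the cis/trans scale) above the higher
bottom; every network is a pure function of (spec, seed). The analytic
two-state oracle provides closed-form populations, ΔF(T) = ΔV −
κk_BT ln r, the heat-capacity anomaly (peaking at ΔV/k_BT ≈ 2.40 for
degenerate frequencies), and detailed-balanced rates. The planted
surfaces (1D double well, Gaussian sums, periodic torsional mimic with
von-Mises wells, a controllable ω ridge and a weak background tilt that
removes flat inter-well regions) make every pipeline stage testable
without any molecular engine. What passing these tests shows is that the
*analysis* is correct on landscapes with the assumed statistical
structure; they say nothing about force-field accuracy for real peptides.

## The built-in molecular-mechanics engine

`pelkit.mm` evaluates the standard fixed-charge force-field energy —
harmonic bonds and angles, cosine torsions and impropers, Lennard-Jones
and Coulomb with 1-2/1-3 exclusions and 1-4 scaling (electrostatics /1.2,
LJ /2.0), no cutoffs, vacuum — with analytic gradients (validated against
finite differences to 10⁻⁹ relative) and finite-difference Hessians
(step 10⁻⁴ Å). The parameter set is a compact reconstruction assembled
from the published AMBER protein force-field family: Cornell-style
residue charges for the acetyl/amide-capped alanine and serine templates
and ff99SB-lineage backbone torsions, written down from the literature
rather than extracted from any distributed parameter database. It is
*not* a verbatim copy of any released force-field version; relative
conformer energies deviate from published ff14SB values at the 0.2–1.2
kcal/mol level, which propagates into the dipeptide reference checks (see
limitations). Conformers are constructed from internal coordinates (NeRF
chain construction) with φ, ψ, ω and side-chain χ as dials, fixed to the
L-amino-acid chirality. Vibrational frequencies use the mass-weighted
Hessian with six rigid modes projected (κ = 3N−6 = 51 for Ac-Ala-NH2).
`n_iso` defaults to 1 everywhere: permutation-inversion isomer counts for
these systems are not tabulated anywhere convenient, and uniform symmetry
factors cancel in population ratios and branching probabilities; the field
is user-overridable.

An external-engine adapter (`mm_engine_adapter(..., backend="openmm")`)
raises a capability error with enabling instructions when OpenMM is
absent; the entire package and test suite run without it.

## Problem sizes and defaults in the shipped analyses

The dipeptide pipeline uses deterministic multistart from the nine family
centers (×2 peptide-bond isomers; ×9 side-chain rotamer combinations for
serine) merged with a 40-step basin-hopping run, DNEB + eigenvector-
following between the low-lying trans families, and rotation-seeded
saddle searches for the ω isomerization from every trans minimum. This
reliably reproduces the landscape this engine defines — alanine: 3 trans
+ 5 cis minima; serine: 22 trans minima including three C7eq and several
C5 rotamers — in a few minutes on one CPU. Random-network validation uses
≤30-minimum networks over 50–100 seeds.

## Known limitations

- Harmonic superposition and harmonic TST: no anharmonicity, no
  recrossing corrections; low-temperature quantities inherit the
  classical-oscillator form.
- The reconstructed parameter set shifts some features relative to
  published ff14SB results: the PII basin is absent (PII starts relax to
  C5 — behavior known from higher-level quantum surfaces of this system,
  but not expected of the force field), the C7ax gap is low by ~1
  kcal/mol, the cis/trans rotation barrier is high by ~3 kcal/mol, the
  serine C5 rotamer with a side-chain hydrogen bond falls below C7eq, and
  the alanine heat-capacity peak accordingly sits at ~47 K rather than
  ~150 K. These are faithful computations on this surface, not defects of
  the analysis stages, which are validated independently against oracles.
- Region-table boundaries are approximate and should be re-examined for
  residues beyond Ala/Ser.
- No implicit/explicit solvent; no quantum-chemistry adapter.
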