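# pelkit

Potential-energy-landscape analysis for model dipeptides, built from the
geometry-optimization toolkit of energy-landscape theory: basin-hopping
global optimization, doubly-nudged elastic band (DNEB) plus hybrid
eigenvector-following transition-state searches, harmonic superposition
thermodynamics, harmonic transition-state-theory rates contracted to
two-state observables by graph transformation, and disconnectivity graphs.

## Who this is for

Researchers studying the intrinsic (gas-phase) conformational preferences
of capped amino acids — systems like Ac-Ala-NH2 and Ac-Ser-NH2, whose
Ramachandran conformer families (C7eq, C5, C7ax, PII, αR, αL, αD, α′, β2)
interconvert over barriers spanning picosecond backbone moves to
millisecond peptide-bond (cis/trans) isomerizations. Instead of long
molecular dynamics, the landscape is characterized geometrically: a
database of minima and the first-order saddles connecting them (a kinetic
transition network), from which thermodynamics and kinetics follow in
closed form.

## The model

Each local minimum *i* contributes a classical harmonic basin to the
canonical partition function,

    Z(T) = Σ_i Z_i(T),   Z_i(T) = n_i exp(−V_i/k_BT) / (βh ν̄_i)^κ,

with `V_i` the minimum energy, `n_i` its permutation–inversion isomer
count, `ν̄_i` the geometric-mean normal-mode frequency and `κ` the number
of vibrational degrees of freedom. Free energies `F_i = −k_BT ln Z_i`,
occupation probabilities `p_i = Z_i/Z`, and the heat capacity

    C_v(T) = κ k_B + ( ⟨V²⟩_p − ⟨V⟩_p² ) / (k_B T²)

follow directly. Transition states use the same form over their κ−1 real
modes, giving harmonic TST rates `k = (k_BT/h)(Z‡/Z_i) e^{−ΔV/k_BT}`;
graph transformation (iterative node elimination with branching-probability
and waiting-time renormalization) contracts the network to exact two-state
rate constants and mean first-passage times. Superbasin analysis at a
ladder of energy thresholds yields disconnectivity graphs, optionally
colored by the ω-torsion isomer.

Molecular energies come from a built-in vacuum molecular-mechanics engine
(AMBER functional form with a curated parameter set for the two capped
dipeptides; see `docs/methods.md` for its provenance and limitations), or
from analytic benchmark surfaces with planted minima and saddles used
throughout the test suite. An adapter slot for an external OpenMM engine
exists and reports a capability error when that engine is not installed.

## Worked example

```python
import numpy as np
from pelkit.mm.pipeline import explore_dipeptide, lowest_in_family
from pelkit.thermo import delta_f, heat_capacity

surface, net = explore_dipeptide("ALA", seed=1, bh_steps=40)
c7eq = lowest_in_family(net, "C7eq")
c5 = lowest_in_family(net, "C5")
print(f"{net.n_minima} minima, {len(net.transition_states)} transition states")
print(f"V(C5) - V(C7eq) = {net.minima[c5].V - net.minima[c7eq].V:.3f} kcal/mol")
print(f"dF(C5 - C7eq, 150 K) = {delta_f(net, {c7eq}, {c5}, 150.0):.3f} kcal/mol")
res = heat_capacity(net, np.arange(10.0, 400.5, 1.0), n_atoms=19)
print(f"low-T heat-capacity peak at {res.peaks_T[0]:.0f} K")
```

prints (on this engine):

    8 minima, 9 transition states
    V(C5) - V(C7eq) = 0.223 kcal/mol
    dF(C5 - C7eq, 150 K) = 0.076 kcal/mol
    low-T heat-capacity peak at 47 K

i.e. the folded C7eq conformer (seven-membered hydrogen-bonded ring) is
the global minimum, the extended C5 conformer lies ~0.2 kcal/mol above it
and becomes nearly degenerate in free energy as vibrational entropy grows,
and their interconversion produces a low-temperature heat-capacity
anomaly. A command-line interface (`pelkit explore/connect/refine/thermo/
rates/tree/classify/rankshift/synth`) exposes the same stages on flat-file
stationary-point databases.

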