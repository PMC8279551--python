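"""Physical constants and unit conversions.

Internal unit system: energy in kcal/mol, length in Angstrom, frequency in
s^-1, temperature in K, mass in amu (atomic mass units).
"""

# Boltzmann constant, kcal mol^-1 K^-1
KB = 1.987204259e-3

# Planck constant, kcal s mol^-1
PLANCK = 9.537070e-14

# Coulomb prefactor: (e^2 / Angstrom) in kcal/mol
COULOMB = 332.0637128

# Conversion of a Hessian eigenvalue in kcal mol^-1 A^-2 amu^-1 to an
# angular-frequency squared in s^-2:  4184 J/kcal / (1e-20 m^2/A^2
# * 1.66053906660e-27 kg/amu * 6.02214076e23 /mol)
EIGENVALUE_TO_OMEGA_SQ = 4184.0 / (1e-20 * 1.66053906660e-27 * 6.02214076e23)

TWO_PI = 6.283185307179586
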