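"""Physical constants and the package-wide unit system.

One consistent unit system is used everywhere: lengths in Angstrom (Å),
energies in kcal mol⁻¹, temperature in K, pressure in atm, charges in
elementary charge units.  Electrochemical quantities use SI (A, V, Ω, C).
"""

#: Coulomb prefactor so that E = COULOMB_KCAL * q_i * q_j / r gives kcal mol⁻¹
#: with charges in e and r in Å.
COULOMB_KCAL = 332.06371

#: Boltzmann constant, kcal mol⁻¹ K⁻¹.
KB_KCAL = 0.0019872041

#: 1 atm expressed in kcal mol⁻¹ Å⁻³ (for the P·V work term).
ATM_TO_KCAL_PER_A3 = 101325.0 * 6.02214076e23 * 1e-30 / 4184.0

#: Hartree → kcal mol⁻¹ (used by the Espinosa binding-energy relation).
HARTREE_TO_KCAL = 627.5095

#: Faraday constant, C mol⁻¹.
FARADAY = 96485.33212

#: Avogadro constant, mol⁻¹.
AVOGADRO = 6.02214076e23

#: Å³ per (g mol⁻¹) / (g cm⁻³): converts molar mass over density to volume.
A3_PER_GMOL_PER_GCM3 = 1e24 / AVOGADRO

#: Atomic masses, g mol⁻¹, for box sizing from a target density.  Coarse
#: toy sites may use any of these labels; unknown elements fall back to
#: carbon so that a density-based box is always computable.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "Cl": 35.45,
    # coarse-grained pseudo-elements used by the toy system
    "R6": 76.096,    # C6H4 aromatic ring fragment
    "Am": 16.023,    # NH2 amine group
    "Wa": 18.015,    # one-bead water
    "Bu": 138.230,   # pyrrolidinium + pentyl bulk fragment
}

DEFAULT_MASS = 12.011
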