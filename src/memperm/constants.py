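"""Physical constants and unit conversions.

Internal unit system: length in Å, time in ns, energy in kcal mol⁻¹,
temperature in K, mass in amu.  GRO files (nm) are converted on read.
"""

#: Boltzmann constant, kcal mol⁻¹ K⁻¹
KB_KCAL = 0.0019872041

#: nm → Å
NM_TO_ANGSTROM = 10.0

#: Å² ns⁻¹ → cm² s⁻¹  (1 Å² = 1e-16 cm², 1 ns = 1e-9 s)
A2_PER_NS_TO_CM2_PER_S = 1.0e-7

#: kcal mol⁻¹ nm⁻² → kcal mol⁻¹ Å⁻²
KCAL_PER_NM2_TO_PER_A2 = 1.0e-2


def force_constant_nm2_to_a2(k_nm2: float) -> float:
    """Convert a harmonic force constant from kcal mol⁻¹ nm⁻² to kcal mol⁻¹ Å⁻²."""
    return k_nm2 * KCAL_PER_NM2_TO_PER_A2


#: default simulation temperature for lipid bilayers, K
DEFAULT_TEMPERATURE = 303.15

#: atomic masses used when a coordinate format carries no mass information, amu
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "NA": 22.990,
    "CL": 35.45,
    "G": 12.011,  # coarse glycerol bead
    "R": 12.011,  # coarse ring bead
    "A": 14.027,  # coarse side-chain bead (CH2)
    "B": 14.027,
    "D": 14.027,
}
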