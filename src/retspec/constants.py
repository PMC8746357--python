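"""Physical constants and element data used throughout the package.

Units are the molecular-mechanics conventions: lengths in Å, charges in
elementary charges e, energies in kcal/mol, potentials in kcal/(mol·e).
"""

# hc in eV·nm; reproduces published (nm, eV) absorption-maximum pairs at
# their printed 2-decimal precision.
HC_EV_NM = 1239.84193

# Coulomb constant in kcal·Å/(mol·e²).
COULOMB_K = 332.0637

# Boltzmann constant in kcal/(mol·K); kT at 300 K = 0.59616 kcal/mol.
KB_KCAL_MOL_K = 0.0019872

# 1 kcal/mol expressed in amu·Å²/ps² (thermochemical calorie; exact).
KCAL_MOL_TO_AMU_A2_PS2 = 418.4

# Speed of light in cm/ps, for cm⁻¹ → angular frequency conversion.
C_CM_PER_PS = 0.0299792458

# Bondi van der Waals radii, Å.
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "HE": 1.40,
    "NE": 1.54,
    "AR": 1.88,
    "SI": 2.10,
    "SE": 1.90,
}


def vdw_radius(element: str) -> float:
    """Bondi vdW radius for an element symbol (case-insensitive)."""
    from .errors import ValidationError

    try:
        return BONDI_RADII[element.strip().upper()]
    except KeyError:
        raise ValidationError(
            f"no van der Waals radius tabulated for element {element!r}"
        ) from None
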