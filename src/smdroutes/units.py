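"""Physical constants and unit conversions.

Internal units throughout the package are kcal/mol (energy), Å (length)
and ps (time); conversions happen only at I/O boundaries.
"""

#: Boltzmann constant in kcal·mol⁻¹·K⁻¹ (CODATA, molar gas constant / 4184).
KB_KCAL_PER_MOL_K: float = 0.0019872041

#: 1 kcal·mol⁻¹·Å⁻¹ expressed as a per-molecule force in piconewtons:
#: 4184 J·mol⁻¹·Å⁻¹ / N_A, converted to pN (1e22 scale factor).
KCAL_PER_MOL_ANGSTROM_IN_PN: float = 4184.0 / 6.02214076e23 * 1.0e22

#: kJ/mol per kcal/mol (thermochemical calorie).
KJ_PER_KCAL: float = 4.184


def kBT(temperature: float) -> float:
    """Thermal energy in kcal/mol at ``temperature`` kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    return KB_KCAL_PER_MOL_K * temperature
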