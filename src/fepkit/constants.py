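"""Physical constants and unit conventions.

All energies are in kcal/mol, distances in Angstrom, temperatures in
Kelvin throughout the package.
"""

#: Boltzmann constant in kcal/mol/K.
KB = 0.0019872041


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
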