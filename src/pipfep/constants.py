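"""Physical constants and unit conventions.

Units throughout the package: energies in kcal/mol, distances in Angstrom,
charges in units of the elementary charge e, temperatures in Kelvin.
"""

#: Boltzmann constant, kcal/(mol K).
BOLTZMANN_KCAL: float = 0.0019872041

#: Coulomb constant C such that E = C q1 q2 / r, in kcal Angstrom / (mol e^2).
COULOMB_KCAL: float = 332.0636

#: Default simulation temperature, K (isothermal ensemble used for the study).
DEFAULT_TEMPERATURE: float = 303.15


def kT(temperature: float) -> float:
    """Thermal energy in kcal/mol at the given temperature."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return BOLTZMANN_KCAL * temperature
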