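"""Physical constants in kcal/mol-compatible units (CODATA 2018)."""

#: Gas constant, kcal mol^-1 K^-1 (energies throughout are per mole).
KB_KCAL_PER_MOL_K = 1.987204259e-3

#: Boltzmann constant over Planck constant, s^-1 K^-1 (Eyring prefactor kB*T/h).
KB_OVER_H_PER_S_K = 2.0836619123e10

SECONDS_PER_DAY = 86400.0

ROOM_TEMPERATURE_K = 298.15


def thermal_energy(temperature_kelvin: float) -> float:
    """kB*T in kcal/mol for a temperature in kelvin."""
    if temperature_kelvin < 0:
        raise ValueError("temperature must be non-negative")
    return KB_KCAL_PER_MOL_K * temperature_kelvin
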