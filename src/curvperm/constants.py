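"""Physical constants and package-wide unit conventions.

Units are fixed across the package: distances in nm, times in ns, energies
in kJ/mol, diffusion coefficients in nm^2/ns, force constants in
kJ mol^-1 nm^-2.  A permeability computed in nm/ns is numerically equal to
the same permeability in m/s, so values can be reported in m/s without
conversion.
"""

#: Boltzmann (gas) constant in kJ mol^-1 K^-1.
KB = 0.0083144621

#: Default thermodynamic temperature (K) for all operations.
DEFAULT_TEMPERATURE = 320.0


def kbt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kJ/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
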