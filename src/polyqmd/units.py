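"""Unit conventions of the simulation.

Energies are kcal/mol, lengths Å, and temperature is expressed in
kcal/mol/k_B, so one temperature unit corresponds to roughly 500 K
(1 kcal/mol divided by the Boltzmann constant). The native time unit (tu)
maps to 50 fs, so a 500 tu replica-exchange interval is ~25 ps and a
1e6 tu replica is ~50 ns.
"""

#: Boltzmann constant in kcal/mol/K.
KB_KCAL_PER_MOL_K = 0.0019872041

#: Kelvin per simulation temperature unit (1 kcal/mol / k_B).
KELVIN_PER_UNIT = 1.0 / KB_KCAL_PER_MOL_K

#: Rounded conversion sometimes used for axis labelling ("about 500 K").
KELVIN_PER_UNIT_ROUNDED = 500.0

#: Femtoseconds per simulation time unit (500 tu ≈ 25 ps).
FS_PER_TU = 50.0


def temperature_to_kelvin(t_unit: float, rounded: bool = False) -> float:
    """Convert a simulation temperature (kcal/mol/k_B) to Kelvin."""
    factor = KELVIN_PER_UNIT_ROUNDED if rounded else KELVIN_PER_UNIT
    return t_unit * factor


def tu_to_ns(tu: float) -> float:
    """Convert a duration in simulation time units to nanoseconds."""
    return tu * FS_PER_TU * 1.0e-6
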