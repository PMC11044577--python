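"""Unit system for the package.

All quantities are expressed in a single consistent unit system borrowed
from biomolecular simulation practice:

* mass        — unified atomic mass units (u)
* length      — nanometres (nm)
* time        — picoseconds (ps)
* energy      — kJ/mol, which equals exactly 1 u·nm²/ps²

Because 1 kJ/mol == 1 u·nm²/ps², no conversion factors appear anywhere in
the dynamics: ``m * v**2`` is directly an energy in kJ/mol. Friction
coefficients are u/ps, memory kernels u/ps².
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant in kJ/(mol·K).
KB = 0.00831446


@dataclass(frozen=True)
class UnitSystem:
    """The fixed unit system (u, nm, ps, kJ/mol).

    The class exists mainly to make unit conventions explicit and
    greppable; the package does not support other unit systems.
    """

    mass_unit: str = "u"
    length_unit: str = "nm"
    time_unit: str = "ps"
    energy_unit: str = "kJ/mol"
    boltzmann_constant: float = KB

    def thermal_energy(self, temperature: float) -> float:
        """Return kT in kJ/mol for a temperature in kelvin."""
        return self.boltzmann_constant * temperature


UNITS = UnitSystem()


def thermal_energy(temperature: float) -> float:
    """kT in kJ/mol for a temperature in kelvin (module-level shortcut)."""
    return UNITS.thermal_energy(temperature)
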