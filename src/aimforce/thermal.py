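"""Thermal context: temperature and the thermal energy scale k_B*T.

Forces are in pN and lengths in nm throughout the package, so k_B is
carried in pN*nm/K and k_B*T in pN*nm (1 pN*nm = 1e-21 J = 0.2439 kcal/mol
at face value; at 298 K, k_B*T = 4.114 pN*nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import ValidationError

#: Boltzmann constant in pN*nm/K (exact SI value rescaled).
BOLTZMANN_PN_NM = 1.380649e-2

#: Default experiment temperature (K). Room-temperature single-molecule work.
DEFAULT_TEMPERATURE = 298.0


@dataclass(frozen=True)
class ThermalContext:
    """Temperature and derived thermal energy for mechanics/kinetics formulas."""

    temperature: float = DEFAULT_TEMPERATURE
    thermal_energy: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValidationError(f"temperature must be > 0 K, got {self.temperature}")
        object.__setattr__(self, "thermal_energy", BOLTZMANN_PN_NM * self.temperature)


#: Shared room-temperature context (k_B*T = 4.114 pN*nm to 4 significant figures).
ROOM_TEMPERATURE = ThermalContext()
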