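"""Physical constants and default material parameters for magnetite.

All quantities are SI. Lengths elsewhere in the package are expressed in
nanometres at the geometry level and converted to metres when energies are
assembled.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

MU0 = 4e-7 * math.pi  # vacuum permeability (T m / A)
KB = 1.380649e-23     # Boltzmann constant (J/K)

#: Spontaneous magnetization of magnetite at room temperature (A/m).
MS_MAGNETITE = 480e3

#: First cubic magnetocrystalline anisotropy constant of magnetite (J/m^3).
#: Negative sign puts the easy axes along <111>.
K1_MAGNETITE = -1.1e4

#: Room temperature used throughout (K).
T_ROOM = 293.0


@dataclass(frozen=True)
class MaterialParams:
    """Magnetic material constants of the crystals.

    Parameters
    ----------
    Ms : float
        Spontaneous magnetization (A/m).
    K1, K2 : float
        Cubic magnetocrystalline anisotropy constants (J/m^3). ``K1 < 0``
        makes <111> the easy axes, as appropriate for magnetite.
    temperature : float
        Absolute temperature (K) used to express energies in units of kT.
    """

    Ms: float = MS_MAGNETITE
    K1: float = K1_MAGNETITE
    K2: float = 0.0
    temperature: float = T_ROOM

    def __post_init__(self) -> None:
        if self.Ms <= 0:
            raise ValueError("Ms must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kT(self) -> float:
        """Thermal energy k_B*T (J)."""
        return KB * self.temperature


#: Material parameters used for all idealized barrier calculations.
MAGNETITE = MaterialParams()

#: Idealized magnetite with anisotropy switched off (pure dipolar physics).
MAGNETITE_ISOTROPIC = MaterialParams(K1=0.0, K2=0.0)
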