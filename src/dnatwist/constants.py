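"""Physical constants and unit conventions.

Angles are in degrees at every public interface; radians appear only inside
rotation math and in the rod-model conversion.  Lengths are in Angstrom for
geometry and in nm only for elasticity outputs.  Energies are kcal/mol.
"""

from __future__ import annotations

import numpy as np

#: Boltzmann constant, kcal mol^-1 K^-1
KB_KCAL_MOL_K: float = 1.987204259e-3

#: Default simulation temperature, K
DEFAULT_TEMPERATURE_K: float = 300.0

#: Standard base-pair rise used by the homogeneous rod model, nm
L_BP_NM: float = 0.34

DEG2RAD: float = np.pi / 180.0
RAD2DEG: float = 180.0 / np.pi


def kbt(temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL_MOL_K * temperature
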