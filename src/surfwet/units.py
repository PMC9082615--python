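"""Unit conventions and physical constants.

Internal units throughout the package:

* length              nm
* number density      nm^-3
* surface excess      nm^-2
* surface tension     mN/m  (equivalently mJ/m^2)
* energy              mN/m * nm^2  (= 1e-21 J), so that tension x area is an energy
* temperature         K
* angle               radians internally, degrees at every public interface

Concentrations cross the package boundary in mol/l and are converted exactly once,
at the I/O surface, with 1 mol/l = 0.602214 nm^-3 (Avogadro's number / 1e24).
"""

from __future__ import annotations

import numpy as np

#: 1 mol/l expressed as a number density in nm^-3.
MOLAR_TO_NM3: float = 0.602214

#: Boltzmann constant in (mN/m * nm^2) per kelvin.  1 mN/m * nm^2 = 1e-21 J.
KB_MN_M_NM2: float = 1.380649e-2

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE: float = 300.0


def molar_to_nm3(c_mol_l):
    """Convert a concentration from mol/l to nm^-3."""
    return np.asarray(c_mol_l, dtype=float) * MOLAR_TO_NM3


def nm3_to_molar(c_nm3):
    """Convert a number density from nm^-3 to mol/l."""
    return np.asarray(c_nm3, dtype=float) / MOLAR_TO_NM3


def kT(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in mN/m * nm^2 (about 4.14 at 300 K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_MN_M_NM2 * temperature


def deg_to_rad(theta_deg):
    return np.deg2rad(theta_deg)


def rad_to_deg(theta_rad):
    return np.rad2deg(theta_rad)
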