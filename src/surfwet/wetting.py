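"""Adsorption onto soft solid surfaces: the wetting-coefficient law.

A surfactant molecule adsorbing from water onto a soft surface (a flexible
monolayer it can partially sink into) trades two interfacial areas.  In the
continuum picture the adsorption free energy is

    DG_s = A_c^* (gamma_sm - gamma_sw) - A_c gamma_mw,                   (free energy)

where A_c is the molecule-surface contact area, A_c^* the bare cross-section
of the molecule (the patch of surface head groups it replaces), and gamma_mw,
gamma_sm, gamma_sw the molecule-water, surface-molecule and surface-water
tensions.  Eliminating gamma_sw with the Young equation
gamma cos(theta) = gamma_sv - gamma_sw turns this into

    DG_s = DG_s^(0) + A_c^* gamma cos(theta),
    DG_s^(0) = A_c^* (gamma_sm - gamma_sv) - A_c gamma_mw,

so the adsorption coefficient K_s = b_s exp(-beta DG_s) obeys

    K_s(cos theta) = K_s^(0) exp(-beta gamma A_c^* cos theta):

ln K_s is affine in the wetting coefficient, decreasing — hydrophobic
surfaces adsorb more.  For a sphere A_c^*/A_m = 1/4 and for an infinite
cylinder 1/pi; real rodlike molecules fall in between.

Both reference coefficients scale exponentially with the molecular surface
area via effective molecular surface tensions gamma~_s, gamma~_v:

    K_s^(0) = b_s exp(beta gamma~_s A_m),   K_v = b_v exp(beta gamma~_v A_m).

Eliminating A_m couples the two interfaces:

    ln(K_s/b_s) = [(gamma~_s - gamma (A_c^*/A_m) cos theta) / gamma~_v] * ln(K_v/b_v),

a linear relation between the log-coefficients whose slope decreases linearly
with cos(theta).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .units import DEFAULT_TEMPERATURE, kT

__all__ = [
    "MoleculeGeometry", "WettingModel", "cross_section_ratio",
    "adsorption_free_energy", "ks_of_costheta", "fit_area_scaling",
    "ks_kv_correlation", "POLARITY_CONTACT_ANGLE", "ALCOHOL_REFERENCE",
]

SPHERE_RATIO = 0.25
CYLINDER_RATIO = 1.0 / np.pi

#: Head-group charge-scaling factor -> water contact angle (degrees) of the
#: reference hydroxyl-terminated monolayer surfaces.  Reference constants from
#: the emulated simulation study; shipped for convenience, not recomputed here.
POLARITY_CONTACT_ANGLE = {0.0: 135.0, 0.4: 120.0, 0.6: 97.0, 0.7: 76.0, 0.8: 45.0}

#: Reported water-vapor fit results for the three reference alcohols
#: (K_v in nm, Gamma_inf in nm^-2, xi dimensionless).  Reference constants
#: from the emulated simulation study, for worked examples and documentation.
ALCOHOL_REFERENCE = {
    "methanol": {"K_v": 0.8, "gamma_inf": 6.52, "xi": 0.650},
    "propanol": {"K_v": 21.0, "gamma_inf": 5.06, "xi": 0.950},
    "pentanol": {"K_v": 410.0, "gamma_inf": 4.80, "xi": 0.998},
}


@dataclass
class MoleculeGeometry:
    """Cross-section convention of the adsorbing molecule.

    A_m : nm^2 total molecular surface area; shape : sphere, cylinder or
    custom_ratio; ratio : A_c^*/A_m (derived for sphere/cylinder, supplied
    for custom).
    """

    A_m: float
    shape: str = "sphere"
    ratio: float | None = None

    def __post_init__(self):
        if self.A_m <= 0:
            raise ValueError("A_m must be positive")
        self.ratio = cross_section_ratio(self.shape, ratio=self.ratio)

    @property
    def A_c_star(self) -> float:
        return self.ratio * self.A_m


def cross_section_ratio(shape: str, ratio: float | None = None,
                        **dims) -> float:
    """Ratio A_c^*/A_m of the adsorption cross-section to the molecular area.

    sphere -> 1/4 (A_m = 4 pi R^2, A_c^* = pi R^2); cylinder -> 1/pi in the
    infinite-length limit (A_m = 2 pi R L, A_c^* = 2 R L); custom_ratio
    passes ``ratio`` through, warning outside the rodlike interval
    [0.25, 0.32].  Any radius/length keywords are accepted and ignored: the
    ratio is scale-free.
    """
    if shape == "sphere":
        return SPHERE_RATIO
    if shape == "cylinder":
        return CYLINDER_RATIO
    if shape == "custom_ratio":
        if ratio is None:
            raise ValueError("custom_ratio requires an explicit ratio")
        if not 0.25 <= ratio <= 0.32:
            warnings.warn(
                f"A_c*/A_m = {ratio} lies outside the rodlike interval "
                "[0.25, 0.32]", stacklevel=2)
        return float(ratio)
    raise ValueError(f"unknown shape {shape!r}")


def adsorption_free_energy(gamma_mw: float, gamma_sm: float, gamma_sw: float,
                           A_c: float, A_c_star: float,
                           T: float = DEFAULT_TEMPERATURE) -> float:
    """Continuum adsorption free energy, in units of k_B T:

        DG_s = [A_c^* (gamma_sm - gamma_sw) - A_c gamma_mw] / k_B T.

    Tensions in mN/m, areas in nm^2.
    """
    if A_c <= 0 or A_c_star <= 0:
        raise ValueError("areas must be positive")
    dg = A_c_star * (gamma_sm - gamma_sw) - A_c * gamma_mw
    return dg / kT(T)


@dataclass
class WettingModel:
    """Parameters coupling adsorption coefficients to the wetting coefficient.

    K_s0 : nm, solid-water adsorption coefficient at cos(theta) = 0;
    b_s, b_v : nm, prefactors of the area-scaling laws; gamma_tilde_s,
    gamma_tilde_v : mN/m, effective molecular surface tensions; gamma : mN/m,
    water surface tension; T : K.
    """

    K_s0: float
    b_s: float
    b_v: float
    gamma_tilde_s: float
    gamma_tilde_v: float
    gamma: float
    T: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        for name in ("K_s0", "b_s", "b_v", "gamma_tilde_s", "gamma_tilde_v",
                     "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def beta(self) -> float:
        """1/k_B T in (mN/m * nm^2)^-1."""
        return 1.0 / kT(self.T)


def ks_of_costheta(costheta, model: WettingModel,
                   geometry: MoleculeGeometry) -> np.ndarray | float:
    """Adsorption coefficient K_s (nm) at wetting coefficient cos(theta):

        K_s = K_s0 * exp(-beta gamma A_c^* cos theta).
    """
    costheta = np.asarray(costheta, dtype=float)
    if np.any(np.abs(costheta) > 1):
        raise ValueError("|cos theta| must be <= 1")
    ks = model.K_s0 * np.exp(-model.beta * model.gamma * geometry.A_c_star
                             * costheta)
    return ks[()] if ks.ndim == 0 else ks


def fit_area_scaling(points, T: float = DEFAULT_TEMPERATURE) -> dict:
    """Fit K = b * exp(beta gamma~ A_m) to (A_m, K) pairs.

    Linear regression of ln K on A_m; slope = beta gamma~, intercept = ln b.
    Returns a dict with ``b_nm``, ``gamma_tilde_mN_m`` and, for n >= 3 points,
    their standard errors.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need at least 2 (A_m, K) pairs")
    A_m, K = pts[:, 0], pts[:, 1]
    if np.any(K <= 0):
        raise ValueError("adsorption coefficients must be positive")
    X = np.column_stack([np.ones_like(A_m), A_m])
    y = np.log(K)
    coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    intercept, slope = coef
    out = {"b_nm": float(np.exp(intercept)),
           "gamma_tilde_mN_m": float(slope * kT(T)),
           "n_points": len(pts)}
    if len(pts) >= 3:
        dof = len(pts) - 2
        resid = y - X @ coef
        s2 = float(resid @ resid) / dof if dof else 0.0
        cov = s2 * np.linalg.inv(X.T @ X)
        out["se_ln_b"] = float(np.sqrt(cov[0, 0]))
        out["se_gamma_tilde_mN_m"] = float(np.sqrt(cov[1, 1]) * kT(T))
    return out


def ks_kv_correlation(K_v, costheta: float, model: WettingModel,
                      geometry_ratio: float = SPHERE_RATIO) -> np.ndarray | float:
    """Predict K_s from K_v at a given wetting coefficient.

    Obtained by eliminating the molecular area between the two area-scaling
    laws and the cos(theta) law:

        ln(K_s/b_s) = [(gamma~_s - gamma * ratio * cos theta) / gamma~_v]
                      * ln(K_v/b_v).

    K_v <= b_v is rejected (it would imply a non-positive molecular area).
    """
    K_v = np.asarray(K_v, dtype=float)
    if np.any(K_v <= model.b_v):
        raise ValueError("K_v <= b_v implies a non-positive molecular area")
    if abs(costheta) > 1:
        raise ValueError("|cos theta| must be <= 1")
    prefactor = ((model.gamma_tilde_s - model.gamma * geometry_ratio * costheta)
                 / model.gamma_tilde_v)
    ks = model.b_s * (K_v / model.b_v) ** prefactor
    return ks[()] if ks.ndim == 0 else ks


def area_from_kv(K_v: float, model: WettingModel) -> float:
    """Invert the water-vapor area-scaling law: A_m = ln(K_v/b_v)/(beta gamma~_v)."""
    if K_v <= model.b_v:
        raise ValueError("K_v <= b_v implies a non-positive molecular area")
    return float(np.log(K_v / model.b_v) / (model.beta * model.gamma_tilde_v))
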