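"""Contact-angle change of a surfactant-laden sessile droplet.

A neat droplet obeys the Young equation gamma cos(theta) = gamma_sv -
gamma_sw.  Dissolved surfactant adsorbs to the water-vapor and solid-water
interfaces of the droplet and lowers both tensions (the solid-vapor tension
is taken as unaffected: the short-chained surfactants modeled here do not
adsorb at the dry solid).  The modified Young equation reads

    [gamma + Dg_v(c0)] cos(theta + Dtheta) = gamma_sv - gamma_sw - Dg_s(c0),

which, since gamma_sv - gamma_sw = gamma cos(theta), is solved for the new
contact angle from

    cos(theta + Dtheta) = [gamma cos(theta) - Dg_s(c0)] / [gamma + Dg_v(c0)].

The right-hand side is an explicit cosine: the solve is a direct inversion on
the [-1, 1] bracket, with explicit regime flags (``complete_wetting`` above
+1, ``dewetting`` below -1) instead of clamping.

For small changes the balance linearizes, and in the Henry/dilute-tension
regime (Gamma = K c, Dg = -k_B T Gamma) it collapses to

    Dtheta = -k_B T c0 (K_s + K_v cos theta) / (gamma sin theta).

The numerator K_s + K_v cos(theta) encodes the competition between the two
interfaces: on hydrophilic surfaces (K_s negligible) Dtheta ~ -cot(theta),
diverging toward complete wetting as theta -> 0; on hydrophobic surfaces the
rapidly growing K_s dominates.  Angles are degrees at every public interface
and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .isotherms import LangmuirFit
from .tension import TensionModel, dgamma_of_c
from .units import kT, molar_to_nm3
from .wetting import MoleculeGeometry, WettingModel, ks_of_costheta

__all__ = ["DropletState", "DeltaThetaResult", "delta_theta_full",
           "delta_theta_linear", "landscape"]

FLAG_OK = "ok"
FLAG_COMPLETE_WETTING = "complete_wetting"
FLAG_DEWETTING = "dewetting"
FLAG_BEYOND_MODEL = "beyond_model"


@dataclass
class DropletState:
    """A sessile droplet with surfactant at concentration c0.

    theta_deg : neat contact angle (0 < theta < 180); gamma0 : mN/m neat
    water surface tension; c0 : mol/l; fit_v/model_v and fit_s/model_s :
    Langmuir fit and tension model for the water-vapor and solid-water
    interfaces.
    """

    theta_deg: float
    gamma0: float
    c0: float
    fit_v: LangmuirFit
    model_v: TensionModel
    fit_s: LangmuirFit
    model_s: TensionModel

    def __post_init__(self):
        if not 0.0 < self.theta_deg < 180.0:
            raise ValueError("theta must lie strictly between 0 and 180 deg")
        if self.gamma0 <= 0:
            raise ValueError("gamma0 must be positive")
        if self.c0 < 0:
            raise ValueError("c0 must be >= 0")

    def replace(self, **kwargs) -> "DropletState":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass
class DeltaThetaResult:
    dtheta_deg: float
    flag: str
    diagnostics: dict


def _tension_changes(state: DropletState) -> tuple[float, float]:
    dg_v = dgamma_of_c(state.c0, state.fit_v, state.model_v).dgamma
    dg_s = dgamma_of_c(state.c0, state.fit_s, state.model_s).dgamma
    return float(dg_v), float(dg_s)


def delta_theta_full(state: DropletState) -> DeltaThetaResult:
    """Contact-angle change from the full modified Young equation.

    Uses the closed-form (nonlinear) tension reduction for both interfaces.
    Raises when the surfactant-laden water-vapor tension would be
    non-positive (beyond the model's regime); returns flagged results, not
    clamped angles, when the implied cosine leaves [-1, 1].
    """
    theta = np.deg2rad(state.theta_deg)
    dg_v, dg_s = _tension_changes(state)
    gamma_c = state.gamma0 + dg_v
    if gamma_c <= 0:
        raise ValueError(
            f"beyond-model: water-vapor tension {gamma_c:.3g} mN/m <= 0 at "
            f"c0 = {state.c0} mol/l")
    cos_new = (state.gamma0 * np.cos(theta) - dg_s) / gamma_c
    diag = {"dgamma_v_mN_m": dg_v, "dgamma_s_mN_m": dg_s,
            "gamma_c0_mN_m": gamma_c, "cos_new": float(cos_new)}
    if cos_new > 1.0:
        return DeltaThetaResult(float("nan"), FLAG_COMPLETE_WETTING, diag)
    if cos_new < -1.0:
        return DeltaThetaResult(float("nan"), FLAG_DEWETTING, diag)
    dtheta = np.rad2deg(np.arccos(cos_new)) - state.theta_deg
    return DeltaThetaResult(float(dtheta), FLAG_OK, diag)


def delta_theta_linear(state: DropletState) -> DeltaThetaResult:
    """Linearized contact-angle change in the Henry/dilute regime:

        Dtheta = -k_B T c0 (K_s + K_v cos theta) / (gamma0 sin theta),

    returned in degrees.  The diagnostics expose the competition numerator
    K_s + K_v cos(theta).  Invalid within 1 degree of theta = 0 or 180
    (sin theta in the denominator).
    """
    if state.theta_deg < 1.0 or state.theta_deg > 179.0:
        raise ValueError("linearization invalid within 1 deg of 0 or 180")
    theta = np.deg2rad(state.theta_deg)
    K_v, K_s = state.fit_v.K, state.fit_s.K
    c_nm3 = molar_to_nm3(state.c0)
    numerator = K_s + K_v * np.cos(theta)
    dtheta_rad = (-kT(state.model_v.T) * c_nm3 * numerator
                  / (state.gamma0 * np.sin(theta)))
    return DeltaThetaResult(
        float(np.rad2deg(dtheta_rad)), FLAG_OK,
        {"numerator_nm": float(numerator), "K_v_nm": K_v, "K_s_nm": K_s})


def landscape(c0: float, theta_grid_deg, K_v: float, model: WettingModel,
              geometry: MoleculeGeometry, gamma0: float) -> pd.DataFrame:
    """Linearized Dtheta across surface hydrophilicities at fixed c0.

    For each neat contact angle in ``theta_grid_deg`` the solid-water
    adsorption coefficient follows the wetting-coefficient law
    K_s = K_s(cos theta), and Dtheta the linearized Young balance.  Returns a
    DataFrame with columns theta_deg, costheta, K_s_nm, dtheta_deg,
    dtheta_tan_theta (the -cot(theta)-scaling diagnostic: constant across the
    hydrophilic branch when K_s is negligible) and min_abs (True on the row
    where |Dtheta| is smallest).
    """
    theta_grid = np.asarray(theta_grid_deg, dtype=float)
    if np.any((theta_grid < 1.0) | (theta_grid > 179.0)):
        raise ValueError("theta grid must lie within [1, 179] deg")
    theta = np.deg2rad(theta_grid)
    costheta = np.cos(theta)
    K_s = np.asarray(ks_of_costheta(costheta, model, geometry), dtype=float)
    c_nm3 = molar_to_nm3(c0)
    dtheta = np.rad2deg(-kT(model.T) * c_nm3 * (K_s + K_v * costheta)
                        / (gamma0 * np.sin(theta)))
    df = pd.DataFrame({
        "theta_deg": theta_grid,
        "costheta": costheta,
        "K_s_nm": K_s,
        "dtheta_deg": dtheta,
        "dtheta_tan_theta": dtheta * np.tan(theta),
    })
    df["min_abs"] = False
    df.loc[df["dtheta_deg"].abs().idxmin(), "min_abs"] = True
    return df
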