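"""Surface-tension reduction from surfactant adsorption.

Integrating the Gibbs adsorption equation d(gamma) = -Gamma d(mu) along the
Langmuir isotherm with the constant-Kirkwood-Buff chemical potential (see
:mod:`surfwet.solution_thermo`) gives a closed form for the tension reduction
as a function of the adsorbed amount:

    Delta_gamma(Gamma) = (k_B T Gamma_inf / xi) * ln(1 - xi Gamma / Gamma_inf),

with the correction factor xi = 1 - Gamma_inf (G_mm - G_mw)/K.  The
integration is exact, not perturbative: partial fractions turn the
concentration integral into two logarithms whose combination collapses to the
single log above.  xi = 1 recovers the classical Szyszkowski equation
Delta_gamma = k_B T Gamma_inf ln(1 - Gamma/Gamma_inf).

In the dilute limit the law is linear and ideal,

    Delta_gamma = -k_B T Gamma,

with second-order term -(k_B T xi / 2 Gamma_inf) Gamma^2, so the linear form
holds for Gamma << Gamma_inf / xi.  The surface pressure is pi = -Delta_gamma.

Saturation behavior: as Gamma -> Gamma_inf the closed form stays finite for
xi < 1 (limit (k_B T Gamma_inf/xi) ln(1-xi)) and diverges logarithmically for
xi = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .isotherms import LangmuirFit
from .units import DEFAULT_TEMPERATURE, kT

__all__ = ["TensionModel", "TensionResult", "dgamma_of_gamma",
           "dgamma_linear", "dgamma_of_c"]


@dataclass
class TensionModel:
    """Parameters of the tension-reduction law for one interface.

    gamma_inf : nm^-2 saturation coverage (must match the isotherm fit it is
    composed with); xi : dimensionless correction factor; T : K; gamma0 :
    mN/m neat-interface tension, used only when absolute tensions are
    requested (always user-supplied — the neat tension of a particular water
    model is an input, not a constant of this package).
    """

    gamma_inf: float
    xi: float = 1.0
    T: float = DEFAULT_TEMPERATURE
    gamma0: float | None = None

    def __post_init__(self):
        if self.gamma_inf <= 0:
            raise ValueError("gamma_inf must be positive")
        if self.xi <= 0:
            raise ValueError("xi must be positive")

    @property
    def kT(self) -> float:
        return kT(self.T)


@dataclass
class TensionResult:
    """Tension reduction with its companion quantities.

    dgamma : mN/m (<= 0); surface_pressure : mN/m (= -dgamma); linear_ok :
    False where the linear law is outside its validity range; beyond_model :
    True where an absolute tension gamma0 + dgamma would be non-positive
    (only evaluated when the model carries gamma0).
    """

    dgamma: np.ndarray | float
    surface_pressure: np.ndarray | float
    linear_ok: np.ndarray | bool = True
    beyond_model: np.ndarray | bool = False


def _beyond(model: TensionModel, dgamma):
    if model.gamma0 is None:
        return np.zeros(np.shape(dgamma), bool) if np.ndim(dgamma) else False
    return model.gamma0 + dgamma <= 0


def dgamma_of_gamma(gamma, model: TensionModel) -> TensionResult:
    """Closed-form tension reduction at adsorption ``gamma`` (nm^-2)."""
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma < 0):
        raise ValueError("adsorption must be >= 0")
    if np.any(gamma >= model.gamma_inf):
        raise ValueError("beyond saturation: Gamma >= Gamma_inf")
    x = model.xi * gamma / model.gamma_inf
    # for xi <= 1 and Gamma < Gamma_inf, x < 1 always holds
    dg = (model.kT * model.gamma_inf / model.xi) * np.log1p(-x)
    dg = dg[()] if dg.ndim == 0 else dg
    return TensionResult(dgamma=dg, surface_pressure=-dg,
                         beyond_model=_beyond(model, dg))


def dgamma_linear(gamma, model: TensionModel) -> TensionResult:
    """Dilute-limit linear law Delta_gamma = -k_B T * Gamma.

    ``linear_ok`` is False where Gamma > 0.1 * Gamma_inf / xi, i.e. where the
    quadratic term is no longer negligible.
    """
    gamma = np.asarray(gamma, dtype=float)
    dg = -model.kT * gamma
    dg = dg[()] if dg.ndim == 0 else dg
    ok = gamma <= 0.1 * model.gamma_inf / model.xi
    ok = ok[()] if np.ndim(ok) == 0 else ok
    return TensionResult(dgamma=dg, surface_pressure=-dg, linear_ok=ok,
                         beyond_model=_beyond(model, dg))


def dgamma_of_c(c0_mol_l, fit: LangmuirFit, model: TensionModel) -> TensionResult:
    """Tension reduction at bulk concentration c0: Langmuir adsorption
    composed with the closed-form law.

    The isotherm fit and the tension model must agree on Gamma_inf — they
    describe the same interface.
    """
    if not np.isclose(fit.gamma_inf, model.gamma_inf, rtol=1e-6):
        raise ValueError(
            f"inconsistent Gamma_inf: fit has {fit.gamma_inf} nm^-2, tension "
            f"model has {model.gamma_inf} nm^-2")
    gamma = fit.predict(np.asarray(c0_mol_l, dtype=float))
    return dgamma_of_gamma(gamma, model)
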