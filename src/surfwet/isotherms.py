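"""Langmuir isotherm fitting and the Henry adsorption coefficient.

Adsorption data (c0 in mol/l, Gamma in nm^-2) are fit to the Langmuir isotherm

    Gamma(c0) = Gamma_inf * k_c c / (1 + k_c c),   c = c0 in nm^-3,

with k_c an adsorption volume (nm^3) and Gamma_inf the saturation coverage
(nm^-2).  In the dilute limit this reduces to Henry's law Gamma = K c with the
adsorption coefficient K = k_c * Gamma_inf, a length (nm): K_v at the
water-vapor interface, K_s at a solid-water interface.

Because both coordinates of simulation-derived isotherm points carry
uncertainty, the default estimator is orthogonal distance regression
(scipy.odr).  When no uncertainties are supplied the fit falls back to
ordinary least squares on Gamma: ODR with fabricated weights would only
launder an arbitrary choice into the covariance.  Parameters are fitted in
log space to enforce positivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

with warnings.catch_warnings():
    # scipy.odr emits a deprecation notice on import in scipy >= 1.17 while
    # remaining fully functional; keep the package import quiet
    warnings.simplefilter("ignore", DeprecationWarning)
    from scipy import odr
from scipy.optimize import curve_fit

from .synthetic import IsothermSeries, langmuir_gamma
from .units import MOLAR_TO_NM3, molar_to_nm3

__all__ = ["LangmuirFit", "fit_langmuir", "henry_predict"]


@dataclass
class LangmuirFit:
    """Fitted Langmuir parameters.

    k_c : nm^3; gamma_inf : nm^-2; K = k_c * gamma_inf : nm (maintained as an
    identity, never stored independently); covariance : 2x2 in (k_c,
    gamma_inf) space; fit_window : (c_lo, c_hi) mol/l actually used.
    """

    k_c: float
    gamma_inf: float
    covariance: np.ndarray
    fit_window: tuple[float, float]
    method: str = "odr"
    n_points: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.k_c <= 0 or self.gamma_inf <= 0:
            raise ValueError("k_c and gamma_inf must be positive")

    @property
    def K(self) -> float:
        """Henry adsorption coefficient K = k_c * gamma_inf (nm)."""
        return self.k_c * self.gamma_inf

    def predict(self, c0_mol_l):
        """Langmuir adsorption at the given concentration(s), nm^-2."""
        return langmuir_gamma(c0_mol_l, self.k_c, self.gamma_inf)

    def to_dict(self) -> dict:
        return {
            "k_c_nm3": self.k_c,
            "gamma_inf_nm2": self.gamma_inf,
            "K_nm": self.K,
            "covariance": np.asarray(self.covariance).tolist(),
            "fit_window_mol_l": list(self.fit_window),
            "method": self.method,
            "n_points": self.n_points,
            **self.metadata,
        }


def _initial_guess(c_nm3: np.ndarray, gamma: np.ndarray) -> tuple[float, float]:
    """Gamma_inf from 1.2x the largest observed coverage; k_c from the Henry
    slope of the two most dilute points."""
    gamma_inf0 = 1.2 * float(np.max(gamma))
    order = np.argsort(c_nm3)
    low = order[:2]
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = gamma[low] / c_nm3[low]
    slopes = slopes[np.isfinite(slopes) & (slopes > 0)]
    K0 = float(np.mean(slopes)) if len(slopes) else gamma_inf0
    k_c0 = max(K0 / gamma_inf0, 1e-8)
    return k_c0, gamma_inf0


def _langmuir_log(beta, c_nm3):
    k_c, gamma_inf = np.exp(beta)
    return gamma_inf * k_c * c_nm3 / (1.0 + k_c * c_nm3)


def _fit_once(c_nm3, gamma, sx, sy, use_odr, beta0_log):
    if use_odr:
        data = odr.RealData(c_nm3, gamma, sx=np.maximum(sx, 1e-12),
                            sy=np.maximum(sy, 1e-12))
        problem = odr.ODR(data, odr.Model(_langmuir_log), beta0=beta0_log,
                          maxit=200)
        out = problem.run()
        if out.info >= 4:
            raise RuntimeError(
                f"ODR did not converge: {'; '.join(out.stopreason)}")
        beta_log, cov_log = out.beta, out.cov_beta * out.res_var
    else:
        def model(c, *beta):
            return _langmuir_log(np.asarray(beta), c)

        beta_log, cov_log = curve_fit(model, c_nm3, gamma, p0=beta0_log,
                                      maxfev=10000)
    params = np.exp(beta_log)
    jac = np.diag(params)  # d(k_c, G_inf)/d(log params)
    cov = jac @ np.asarray(cov_log) @ jac
    return params, cov


def fit_langmuir(series: IsothermSeries, weighting: str = "auto",
                 window_kc_c: float = 2.0) -> LangmuirFit:
    """Fit the Langmuir isotherm to a (c0, Gamma) series.

    Parameters
    ----------
    series
        Data with optional per-point standard deviations in both coordinates.
    weighting
        ``"odr"`` — orthogonal distance regression using the stated sd's;
        ``"ols"`` — unweighted least squares on Gamma;
        ``"auto"`` (default) — ODR when any sd is positive, OLS otherwise.
    window_kc_c
        The fit targets the dilute-to-moderate regime: after an initial fit,
        points with k_c * c > ``window_kc_c`` are dropped and the fit is run
        once more.  The window is recorded in the fit metadata.  Pass
        ``numpy.inf`` to keep all points.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 points to fit (2 parameters + "
                         "covariance)")
    gamma = series.gamma
    if np.all(gamma <= 0):
        raise ValueError("all adsorption values are zero; nothing to fit")
    c_nm3 = molar_to_nm3(series.c0)
    sx = molar_to_nm3(series.sd_c0)
    sy = np.asarray(series.sd_gamma, dtype=float)

    if weighting == "auto":
        use_odr = bool(np.any(sx > 0) or np.any(sy > 0))
    elif weighting in ("odr", "ols"):
        use_odr = weighting == "odr"
    else:
        raise ValueError(f"unknown weighting mode {weighting!r}")

    k_c0, gamma_inf0 = _initial_guess(c_nm3, gamma)
    beta0 = np.log([k_c0, gamma_inf0])
    params, cov = _fit_once(c_nm3, gamma, sx, sy, use_odr, beta0)

    keep = c_nm3 * params[0] <= window_kc_c
    refit = bool(np.any(~keep)) and int(np.sum(keep)) >= 3
    if refit:
        params, cov = _fit_once(c_nm3[keep], gamma[keep], sx[keep], sy[keep],
                                use_odr, np.log(params))
    used = keep if refit else np.ones(len(c_nm3), bool)

    return LangmuirFit(
        k_c=float(params[0]), gamma_inf=float(params[1]), covariance=cov,
        fit_window=(float(series.c0[used].min()), float(series.c0[used].max())),
        method="odr" if use_odr else "ols", n_points=int(used.sum()),
        metadata={"window_kc_c": window_kc_c, "refit": refit},
    )


def henry_predict(fit: LangmuirFit, c0_mol_l):
    """Henry's-law adsorption Gamma = K * c0 (nm^-2).

    Valid for c0 << 1/k_c (in nm^-3); at k_c*c = 0.1 the Langmuir value is
    already ~9% below this line.
    """
    return fit.K * np.asarray(c0_mol_l, dtype=float) * MOLAR_TO_NM3
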