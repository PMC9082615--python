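"""Kirkwood-Buff solution thermodynamics and the non-ideality factor xi.

The Kirkwood-Buff (KB) integrals

    G_ij = integral 0..inf of 4 pi r^2 (g_ij(r) - 1) dr        (nm^3)

link bulk pair correlations to solution thermodynamics.  With the
molecule-molecule and molecule-water integrals G_mm and G_mw treated as
constants (they are nearly concentration-independent in the dilute regime),
the surfactant chemical potential follows the constant-KB form

    beta mu(c0) = const + ln c0 - ln(1 + (G_mm - G_mw) c0),

which reduces to the ideal beta mu = ln c0 + const when G_mm = G_mw.

Feeding this chemical potential and the Langmuir isotherm through the Gibbs
adsorption equation (see :mod:`surfwet.tension`) produces a surface-tension
law whose sole non-ideality parameter is the dimensionless correction factor

    xi = 1 - Gamma_inf (G_mm - G_mw) / K.

Its numerator Gamma_inf*(G_mm - G_mw) grows roughly linearly with molecular
size, while the adsorption coefficient K in the denominator grows
exponentially with it — so xi matters for small surfactants and tends to 1
for large ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import RadialDistribution
from .units import DEFAULT_TEMPERATURE, molar_to_nm3

__all__ = ["KBResult", "kb_integral", "chemical_potential",
           "correction_factor", "SolutionThermo"]


@dataclass
class KBResult:
    """A Kirkwood-Buff integral with its convergence diagnostic.

    value : nm^3 — the KB integral estimate.
    plateau_spread : nm^3 — range of the running integral over the averaging
    window (0 when a fixed cutoff is used); large spread signals a
    non-plateauing integrand.
    r_cut : nm — cutoff actually applied (upper end of the window).
    converged : whether the spread is below the flagging threshold.
    """

    value: float
    plateau_spread: float
    r_cut: float
    converged: bool


def kb_integral(rdf: RadialDistribution, r_cut: float | str = "plateau",
                tail_tol: float = 0.05, plateau_fraction: float = 0.2,
                spread_tol: float = 0.05) -> KBResult:
    """Kirkwood-Buff integral of a gridded g(r) by the trapezoidal rule.

    Parameters
    ----------
    r_cut
        Either a numeric cutoff (nm), or ``"plateau"`` (default): average the
        running integral over the final ``plateau_fraction`` of the range,
        which damps the truncation oscillations of finite-range RDFs that
        never formally converge.
    tail_tol
        The mean of g over the last 10% of the range must lie within this
        tolerance of 1 (the integrand must have decayed).

    A running integral whose spread over the averaging window exceeds
    ``spread_tol * max(|G|, 0.01 nm^3)`` triggers a warning; the best estimate
    is still returned, with ``converged=False``.
    """
    r, g = rdf.r, rdf.g
    n_tail = max(len(r) // 10, 2)
    tail_mean = float(g[-n_tail:].mean())
    if abs(tail_mean - 1.0) > tail_tol:
        raise ValueError(
            f"g(r) tail has not decayed to 1 (mean {tail_mean:.3f} over the "
            f"final 10% of the range)")
    integrand = 4.0 * np.pi * r * r * (g - 1.0)
    running = np.concatenate(
        [[0.0], np.cumsum(np.diff(r) * (integrand[1:] + integrand[:-1]) / 2.0)])

    if isinstance(r_cut, str):
        if r_cut != "plateau":
            raise ValueError(f"unknown r_cut mode {r_cut!r}")
        n_win = max(int(len(r) * plateau_fraction), 2)
        window = running[-n_win:]
        value = float(window.mean())
        spread = float(window.max() - window.min())
        cut = float(r[-1])
    else:
        if not rdf.r[0] <= r_cut <= rdf.r[-1]:
            raise ValueError(f"r_cut {r_cut} outside the RDF range")
        value = float(np.interp(r_cut, r, running))
        spread = 0.0
        cut = float(r_cut)

    converged = spread <= spread_tol * max(abs(value), 1e-2)
    if not converged:
        warnings.warn(
            f"KB running integral has not plateaued (spread {spread:.3g} nm^3 "
            f"about {value:.3g} nm^3); returning the window average",
            RuntimeWarning, stacklevel=2)
    return KBResult(value=value, plateau_spread=spread, r_cut=cut,
                    converged=converged)


def chemical_potential(c0_mol_l, G_mm: float, G_mw: float,
                       T: float = DEFAULT_TEMPERATURE):
    """Surfactant chemical potential (constant-KB form), in units of k_B T and
    up to an additive constant:

        beta mu = ln c - ln(1 + (G_mm - G_mw) c),   c in nm^-3.

    G_mm = G_mw recovers the ideal-solution beta mu = ln c.
    """
    c = molar_to_nm3(c0_mol_l)
    if np.any(np.asarray(c) <= 0):
        raise ValueError("concentration must be positive")
    dG = G_mm - G_mw
    arg = 1.0 + dG * c
    if np.any(np.asarray(arg) <= 0):
        raise ValueError(
            f"1 + (G_mm - G_mw) c is non-positive at c0={c0_mol_l}; the "
            "constant-KB form breaks down at this concentration")
    return np.log(c) - np.log(arg)


def correction_factor(G_mm: float, G_mw: float, gamma_inf: float, K: float,
                      T: float = DEFAULT_TEMPERATURE) -> float:
    """Non-ideality correction factor of the surface-tension law:

        xi = 1 - Gamma_inf * (G_mm - G_mw) / K.

    Dimensionless (the temperature argument is accepted for interface
    symmetry with the other thermodynamic operations but does not enter).
    Values outside (0, 1] are physically unusual for simple surfactants and
    are flagged with a warning, not forbidden.
    """
    if gamma_inf <= 0 or K <= 0:
        raise ValueError("gamma_inf and K must be positive")
    xi = 1.0 - gamma_inf * (G_mm - G_mw) / K
    if not 0.0 < xi <= 1.0:
        warnings.warn(f"correction factor xi = {xi:.4g} outside (0, 1]; "
                      "check the KB inputs", RuntimeWarning, stacklevel=2)
    return xi


@dataclass
class SolutionThermo:
    """Bundled solution-thermodynamic state of one surfactant.

    Holds the KB integrals, the saturation coverage and adsorption
    coefficient, and the derived correction factor xi (always recomputed from
    the other fields, never set independently).
    """

    G_mm: float
    G_mw: float
    gamma_inf: float
    K: float
    T: float = DEFAULT_TEMPERATURE

    @property
    def xi(self) -> float:
        return correction_factor(self.G_mm, self.G_mw, self.gamma_inf,
                                 self.K, self.T)

    def mu(self, c0_mol_l):
        return chemical_potential(c0_mol_l, self.G_mm, self.G_mw, self.T)
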