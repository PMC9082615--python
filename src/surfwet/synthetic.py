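"""Synthetic stand-ins for MD observables, with known ground truth.

Three generators emulate the statistical structure of the simulation outputs
the analysis pipeline consumes:

* slab-geometry water/surfactant density profiles with a tanh-edged water slab
  and a Gaussian interfacial adsorption peak of analytically known surface
  excess;
* radial distribution functions with closed-form Kirkwood-Buff integrals
  (ideal, hard-sphere, exponential-decay families);
* Langmuir-distributed (c0, Gamma) isotherm series with independent Gaussian
  noise in both coordinates, matching the rationale for orthogonal distance
  regression.

All randomness flows through one seeded generator per call; the same seed
yields byte-identical output.  The water slab edge is a tanh sigmoid so that
the Gibbs dividing surface coincides with the sigmoid midpoint analytically.
By default a single interface (half-slab) is generated; a two-sided mode
mirrors the profile about the slab center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import DensityProfile
from .units import molar_to_nm3

__all__ = [
    "SlabSpec", "SurfactantTruth", "RdfSpec", "RadialDistribution",
    "make_slab_profiles", "make_rdf", "make_isotherm_series", "IsothermSeries",
]

#: bulk density of liquid water at ambient conditions, nm^-3
WATER_BULK_DENSITY = 33.0


@dataclass
class SlabSpec:
    """Geometry of a synthetic liquid slab with one planar interface.

    box_height : nm, extent of the z grid.
    slab_center : nm, midpoint of the (conceptual full) slab.
    slab_thickness : nm, full slab thickness (5 nm in the emulated setups).
    interface_width : nm, tanh width parameter of the liquid edge.
    bulk_water_density : nm^-3.
    geometry : water_vapor or solid_water (label; shapes are shared).
    """

    box_height: float = 10.0
    slab_center: float = 7.5
    slab_thickness: float = 5.0
    interface_width: float = 0.25
    bulk_water_density: float = WATER_BULK_DENSITY
    geometry: str = "water_vapor"

    def __post_init__(self):
        if not 0 < self.slab_thickness < self.box_height:
            raise ValueError("need 0 < slab_thickness < box_height")
        if self.interface_width <= 0:
            raise ValueError("interface_width must be positive")
        if self.bulk_water_density <= 0:
            raise ValueError("bulk_water_density must be positive")
        if self.geometry not in ("water_vapor", "solid_water"):
            raise ValueError(f"unknown geometry {self.geometry!r}")

    @property
    def edge(self) -> float:
        """z of the liquid edge (= Gibbs dividing surface), liquid above."""
        return self.slab_center - self.slab_thickness / 2.0


@dataclass
class SurfactantTruth:
    """Ground truth for one synthetic surfactant profile.

    c0 : mol/l bulk concentration; gamma_true : nm^-2 interfacial excess;
    peak_width : nm Gaussian sigma of the adsorption peak; seed for noise.
    """

    c0: float = 0.1
    gamma_true: float = 1.0
    peak_width: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.c0 < 0:
            raise ValueError("c0 must be >= 0")
        if self.gamma_true < 0:
            raise ValueError("gamma_true must be >= 0 for an adsorbing species")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be positive")


def make_slab_profiles(spec: SlabSpec, truth: SurfactantTruth,
                       dz: float = 0.02, noise: float = 0.0,
                       two_sided: bool = False,
                       ) -> tuple[DensityProfile, DensityProfile]:
    """Generate matched (water, surfactant) density profiles.

    The water profile is a tanh-edged slab; its Gibbs dividing surface is the
    sigmoid midpoint ``spec.edge`` by symmetry.  The surfactant profile is the
    bulk concentration modulated by the same sigmoid (so its own excess over
    the dividing surface vanishes) plus a Gaussian peak centered on the
    dividing surface whose analytic area equals ``truth.gamma_true``.

    ``noise`` adds multiplicative Gaussian perturbations (relative sd) drawn
    from ``default_rng(truth.seed)``; densities are clipped at zero.
    """
    if truth.peak_width >= spec.slab_thickness / 2.0:
        raise ValueError(
            f"peak_width {truth.peak_width} nm is not interfacial: must be "
            f"< slab_thickness/2 = {spec.slab_thickness / 2.0} nm")
    if noise < 0:
        raise ValueError("noise must be >= 0")

    n = int(round(spec.box_height / dz))
    z = np.arange(n + 1) * dz
    edge = spec.edge
    w = spec.interface_width

    def gauss_peak(center):
        return (truth.gamma_true / (truth.peak_width * np.sqrt(2.0 * np.pi))
                * np.exp(-0.5 * ((z - center) / truth.peak_width) ** 2))

    c0_nm3 = molar_to_nm3(truth.c0)
    envelope = 0.5 * (1.0 + np.tanh((z - edge) / w))
    peak = gauss_peak(edge)
    if two_sided:
        edge_hi = spec.slab_center + spec.slab_thickness / 2.0
        if edge_hi + 3.0 * w > spec.box_height:
            raise ValueError("two-sided slab does not fit in the box")
        envelope = envelope * 0.5 * (1.0 + np.tanh((edge_hi - z) / w))
        peak = peak + gauss_peak(edge_hi)

    water = spec.bulk_water_density * envelope
    surf = c0_nm3 * envelope + peak

    if noise > 0:
        rng = np.random.default_rng(truth.seed)
        water = np.clip(water * (1.0 + noise * rng.standard_normal(water.shape)), 0, None)
        surf = np.clip(surf * (1.0 + noise * rng.standard_normal(surf.shape)), 0, None)

    wp = DensityProfile(z, water, species="water", geometry=spec.geometry)
    sp = DensityProfile(z, surf, species="surfactant", geometry=spec.geometry)
    return wp, sp


@dataclass
class RdfSpec:
    """A synthetic radial distribution function with a closed-form KB integral.

    form : ``ideal`` (g = 1, G = 0), ``hard_sphere`` (g = 0 below sigma,
    G = -(4/3) pi sigma^3) or ``exp_decay`` (g = 1 + a exp(-r/lambda),
    G = 8 pi a lambda^3 for integration to infinity).
    """

    form: str = "ideal"
    sigma: float = 0.4
    amplitude: float = 0.5
    decay_length: float = 0.3
    r_max: float = 3.0

    def __post_init__(self):
        if self.form not in ("ideal", "hard_sphere", "exp_decay"):
            raise ValueError(f"unknown rdf form {self.form!r}")
        if self.form == "hard_sphere" and not 0 < self.sigma < self.r_max:
            raise ValueError("need 0 < sigma < r_max")
        if self.form == "exp_decay":
            if self.decay_length <= 0:
                raise ValueError("decay_length must be positive")
            if self.r_max < 5 * self.decay_length:
                raise ValueError("r_max must be >= 5 * decay_length")
            if self.amplitude < -1:
                raise ValueError("amplitude < -1 makes g(0) negative")

    def closed_form_kb(self) -> float:
        """Exact KB integral of the continuous form (integration to infinity)."""
        if self.form == "ideal":
            return 0.0
        if self.form == "hard_sphere":
            return -(4.0 / 3.0) * np.pi * self.sigma ** 3
        a, lam = self.amplitude, self.decay_length
        return 8.0 * np.pi * a * lam ** 3

    def truncation_correction(self) -> float:
        """KB-integral mass beyond r_max (zero except for exp_decay)."""
        if self.form != "exp_decay":
            return 0.0
        a, lam, r = self.amplitude, self.decay_length, self.r_max
        return 4.0 * np.pi * a * np.exp(-r / lam) * (
            r * r * lam + 2 * r * lam ** 2 + 2 * lam ** 3)


@dataclass
class RadialDistribution:
    """Gridded g(r) for a species pair (``mm`` or ``mw``)."""

    r: np.ndarray
    g: np.ndarray
    pair: str = "mm"

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.r.shape != self.g.shape or self.r.ndim != 1:
            raise ValueError("r and g must be 1-D arrays of equal length")
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("r grid must be strictly increasing")
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")


def make_rdf(spec: RdfSpec, dr: float = 0.001, pair: str = "mm") -> RadialDistribution:
    """Sample an RdfSpec on a uniform grid [0, r_max]."""
    n = int(round(spec.r_max / dr))
    r = np.arange(n + 1) * dr
    if spec.form == "ideal":
        g = np.ones_like(r)
    elif spec.form == "hard_sphere":
        g = np.where(r < spec.sigma, 0.0, 1.0)
    else:
        g = 1.0 + spec.amplitude * np.exp(-r / spec.decay_length)
    return RadialDistribution(r, g, pair=pair)


@dataclass
class IsothermSeries:
    """(c0, Gamma) adsorption data with per-point uncertainties.

    Concentrations in mol/l, adsorption in nm^-2.  ``truth`` records the
    generating Langmuir parameters when the series is synthetic.
    """

    c0: np.ndarray
    gamma: np.ndarray
    sd_c0: np.ndarray
    sd_gamma: np.ndarray
    interface: str = "water_vapor"
    surface_theta: float | None = None
    truth: dict | None = None

    def __post_init__(self):
        self.c0 = np.atleast_1d(np.asarray(self.c0, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.sd_c0 = np.atleast_1d(np.asarray(self.sd_c0, dtype=float))
        self.sd_gamma = np.atleast_1d(np.asarray(self.sd_gamma, dtype=float))
        m = len(self.c0)
        if not (len(self.gamma) == len(self.sd_c0) == len(self.sd_gamma) == m):
            raise ValueError("all isotherm columns must have equal length")
        if np.any(self.c0 < 0):
            raise ValueError("concentrations must be >= 0")

    def __len__(self):
        return len(self.c0)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"c0_mol_l": self.c0, "gamma_nm2": self.gamma,
                             "sd_c0": self.sd_c0, "sd_gamma": self.sd_gamma})

    @classmethod
    def from_dataframe(cls, df, interface: str = "water_vapor",
                       surface_theta: float | None = None):
        return cls(df["c0_mol_l"].to_numpy(), df["gamma_nm2"].to_numpy(),
                   df.get("sd_c0", 0.0 * df["c0_mol_l"]).to_numpy(),
                   df.get("sd_gamma", 0.0 * df["gamma_nm2"]).to_numpy(),
                   interface=interface, surface_theta=surface_theta)


def langmuir_gamma(c0_mol_l, k_c: float, gamma_inf: float):
    """Langmuir adsorption Gamma(c0) = Gamma_inf * k_c c / (1 + k_c c),
    with c the concentration in nm^-3."""
    c = molar_to_nm3(c0_mol_l)
    return gamma_inf * k_c * c / (1.0 + k_c * c)


def make_isotherm_series(k_c: float, gamma_inf: float, concentrations,
                         noise_x: float = 0.0, noise_y: float = 0.0,
                         seed: int = 0, interface: str = "water_vapor",
                         surface_theta: float | None = None) -> IsothermSeries:
    """Draw a (c0, Gamma) series from a Langmuir curve with biaxial noise.

    ``noise_x`` and ``noise_y`` are relative Gaussian standard deviations
    applied independently to the concentration and adsorption coordinates
    (both coordinates of simulation-derived isotherms carry uncertainty,
    which is what motivates orthogonal-distance fitting downstream).
    Reported sd columns are the noise level times the unperturbed values.
    """
    if k_c <= 0 or gamma_inf <= 0:
        raise ValueError("k_c and gamma_inf must be positive")
    if noise_x < 0 or noise_y < 0:
        raise ValueError("noise levels must be >= 0")
    c0 = np.asarray(concentrations, dtype=float)
    gamma = langmuir_gamma(c0, k_c, gamma_inf)
    rng = np.random.default_rng(seed)
    c_obs = c0 * (1.0 + noise_x * rng.standard_normal(c0.shape))
    g_obs = gamma * (1.0 + noise_y * rng.standard_normal(gamma.shape))
    c_obs = np.clip(c_obs, 0.0, None)
    g_obs = np.clip(g_obs, 0.0, None)
    truth = {"k_c_nm3": k_c, "gamma_inf_nm2": gamma_inf,
             "K_nm": k_c * gamma_inf, "noise_x": noise_x, "noise_y": noise_y,
             "seed": seed}
    return IsothermSeries(c_obs, g_obs, noise_x * c0, noise_y * gamma,
                          interface=interface, surface_theta=surface_theta,
                          truth=truth)
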