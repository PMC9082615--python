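"""Interface location and surface-excess adsorption from 1-D density profiles.

The raw observable is a gridded density profile c(z) of a species near a planar
interface (water-vapor or solid-water).  This module locates the effective
interface — the Gibbs dividing surface of water, defined as the plane where the
excess water adsorption vanishes — and integrates the surfactant profile against
it to obtain the surface excess

    Gamma = integral over z of [ c(z) - c_bulk * H(liquid side) ] dz,

the adsorbed amount per unit area (nm^-2).  Integration uses the trapezoidal
rule on a resampled grid of subinterval 0.1 nm by default.

No orientation is assumed: the liquid may sit at either end of the grid (the
two geometries naturally have opposite orientations), and every operation
either infers the liquid side from a water profile or takes it explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import io

__all__ = [
    "DensityProfile",
    "BulkWindow",
    "InterfaceFrame",
    "find_bulk",
    "gibbs_dividing_surface",
    "solid_boundary",
    "excess_adsorption",
    "infer_liquid_side",
    "measure_adsorption",
]


@dataclass
class DensityProfile:
    """A species density on a uniform 1-D grid.

    Attributes
    ----------
    z : array, nm — strictly increasing, uniformly spaced grid.
    density : array, nm^-3 — non-negative density per grid point.
    species : label, e.g. ``"water"`` or ``"surfactant"``.
    geometry : ``"water_vapor"`` or ``"solid_water"``.
    """

    z: np.ndarray
    density: np.ndarray
    species: str = ""
    geometry: str = "water_vapor"

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.z.ndim != 1 or self.z.shape != self.density.shape:
            raise ValueError("z and density must be 1-D arrays of equal length")
        if len(self.z) < 4:
            raise ValueError("profile needs at least 4 grid points")
        dz = np.diff(self.z)
        if np.any(dz <= 0):
            raise ValueError("grid must be strictly increasing")
        if not np.allclose(dz, dz[0], rtol=1e-6, atol=1e-12):
            raise ValueError("grid must be uniformly spaced")
        if np.any(self.density < -1e-12):
            raise ValueError("density must be non-negative")
        self.density = np.clip(self.density, 0.0, None)
        if self.geometry not in ("water_vapor", "solid_water"):
            raise ValueError(f"unknown geometry {self.geometry!r}")

    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0])

    @classmethod
    def from_file(cls, path, species: str = "", geometry: str = "water_vapor"):
        z, density, meta = io.read_xy(path)
        return cls(z, density,
                   species=species or meta.get("species", ""),
                   geometry=meta.get("geometry", geometry))

    def to_file(self, path, extra_metadata: dict | None = None):
        meta = {"species": self.species, "geometry": self.geometry,
                "columns": "z_nm density_nm-3"}
        meta.update(extra_metadata or {})
        io.write_xy(path, self.z, self.density, meta)


@dataclass
class BulkWindow:
    z_lo: float
    z_hi: float
    c_bulk: float

    @property
    def width(self) -> float:
        return self.z_hi - self.z_lo


@dataclass
class InterfaceFrame:
    """Effective interface position plus the bulk reference it was built from."""

    z0: float
    bulk_window: BulkWindow
    c_bulk: float
    liquid_side: str = "upper"
    extras: dict = field(default_factory=dict)


def infer_liquid_side(water: DensityProfile) -> str:
    """Return ``"upper"`` or ``"lower"``: the grid end where water density is high."""
    n = len(water.z)
    lower = water.density[: n // 2].mean()
    upper = water.density[n // 2:].mean()
    return "upper" if upper > lower else "lower"


def _maximal_flat_run(density: np.ndarray, start: int, tol: float) -> int:
    """Last index j such that density[start..j] all lie within tol*mean of the
    running window mean.  Vectorised scan from ``start``."""
    seg = density[start:]
    means = np.cumsum(seg) / np.arange(1, len(seg) + 1)
    cmax = np.maximum.accumulate(seg)
    cmin = np.minimum.accumulate(seg)
    ok = (cmax - means <= tol * means) & (means - cmin <= tol * means)
    bad = np.flatnonzero(~ok)
    end = bad[0] if len(bad) else len(seg)
    return start + end - 1


def find_bulk(profile: DensityProfile, flatness_tol: float = 0.02,
              min_width: float = 1.0) -> BulkWindow:
    """Locate the bulk plateau of a profile and its mean density.

    The bulk is the flat region in the liquid interior where the density is
    roughly uniform.  Among all maximal contiguous runs in which every point
    deviates less than ``flatness_tol`` (relative) from the run mean, the run
    with the highest mean density at least ``min_width`` wide is returned —
    this selects the liquid plateau over the (near-zero) vapor plateau without
    assuming an orientation.

    Raises
    ------
    ValueError
        If no qualifying window at least ``min_width`` (nm) wide exists
        ("no bulk plateau").
    """
    d = profile.density
    n = len(d)
    w_pts = max(int(round(min_width / profile.dz)), 2)
    best: tuple[float, int, int] | None = None  # (mean, i, j)
    i = 0
    while i < n - 1:
        j = _maximal_flat_run(d, i, flatness_tol)
        if j - i + 1 >= w_pts:
            mean = float(d[i:j + 1].mean())
            if best is None or mean > best[0]:
                best = (mean, i, j)
            i = j + 1
        else:
            i += 1
    if best is None or best[0] <= 0:
        raise ValueError(
            f"no bulk plateau: no window >= {min_width} nm within "
            f"flatness tolerance {flatness_tol}")
    mean, i, j = best
    return BulkWindow(float(profile.z[i]), float(profile.z[j]), mean)


def gibbs_dividing_surface(water: DensityProfile, c_bulk: float | None = None,
                           liquid_side: str | None = None,
                           tail_tol: float = 1e-2) -> float:
    """Gibbs dividing surface of the water phase.

    z0 is the plane at which the excess water adsorption vanishes: the profile
    integral over the full range equals the integral of the sharp-interface
    step c_bulk * H(liquid side of z0).  Because that balance is affine in z0
    it is solved exactly from the cumulative trapezoid:

        liquid upper:  z0 = z_hi - M / c_bulk,
        liquid lower:  z0 = z_lo + M / c_bulk,   M = trapz(c_w, z).

    Preconditions: the water density must decay to ~0 on the vapor/solid side
    (checked against ``tail_tol`` * c_bulk).
    """
    if liquid_side is None:
        liquid_side = infer_liquid_side(water)
    if c_bulk is None:
        c_bulk = find_bulk(water).c_bulk
    if c_bulk <= 0:
        raise ValueError("water bulk density must be positive")
    tail = water.density[0] if liquid_side == "upper" else water.density[-1]
    if tail > tail_tol * c_bulk:
        raise ValueError(
            f"water tail does not decay on the vapor side "
            f"({tail:.3g} vs bulk {c_bulk:.3g} nm^-3)")
    mass = float(np.trapezoid(water.density, water.z))
    if liquid_side == "upper":
        z0 = water.z[-1] - mass / c_bulk
    else:
        z0 = water.z[0] + mass / c_bulk
    if not (water.z[0] < z0 < water.z[-1]):
        raise ValueError("dividing surface fell outside the profile range")
    return float(z0)


def solid_boundary(oh_profile: DensityProfile, water_side: str = "upper") -> float:
    """Effective solid boundary: half-height crossing of the head-group peak
    on the water side, linearly interpolated between grid points.

    Raises if the profile is flat (no peak) or if the density re-crosses the
    half-maximum further out on the water side (ambiguous multimodal peak);
    the error message lists all candidate crossings.
    """
    d = oh_profile.density
    z = oh_profile.z
    peak = int(np.argmax(d))
    if d[peak] <= 0:
        raise ValueError("no head-group peak: profile is flat")
    half = d[peak] / 2.0

    if water_side == "upper":
        idx = range(peak, len(d) - 1)
    elif water_side == "lower":
        idx = range(peak, 0, -1)
    else:
        raise ValueError("water_side must be 'upper' or 'lower'")

    crossings = []
    for i in idx:
        j = i + 1 if water_side == "upper" else i - 1
        a, b = d[i], d[j]
        if (a - half) * (b - half) <= 0 and a != b:
            frac = (a - half) / (a - b)
            crossings.append(float(z[i] + frac * (z[j] - z[i])))
    # keep only downward (peak-to-water) crossings followed by re-rises
    if not crossings:
        raise ValueError("no half-height crossing on the water side")
    if len(crossings) > 1:
        raise ValueError(
            "ambiguous water-side flank (density re-crosses half-maximum); "
            f"candidate positions: {[round(c, 4) for c in crossings]}")
    return crossings[0]


def excess_adsorption(surfactant: DensityProfile, z0: float, c_bulk: float,
                      dz: float = 0.1, liquid_side: str = "upper",
                      margin: float = 1.5) -> float:
    """Surface excess Gamma (nm^-2) of the surfactant across the interface at z0.

    Gamma = trapz over the profile range of c(z), at subinterval ``dz``
    (resampling by linear interpolation if the input grid differs), minus the
    sharp-interface bulk contribution c_bulk * (extent of the liquid side of
    z0), which is evaluated analytically so the step introduces no quadrature
    artifact.

    Both endpoints must lie at least ``margin`` nm beyond z0 — i.e. well inside
    the vapor/solid phase on one side and well inside the bulk liquid on the
    other — otherwise the integral would truncate the interfacial region.
    """
    z_lo, z_hi = float(surfactant.z[0]), float(surfactant.z[-1])
    if z0 - z_lo < margin or z_hi - z0 < margin:
        raise ValueError(
            f"integration endpoints must be at least {margin} nm beyond the "
            f"interface at z0={z0:.3f} (profile spans [{z_lo:.3f}, {z_hi:.3f}])")
    n = max(int(np.floor((z_hi - z_lo) / dz)), 2)
    grid = z_lo + np.arange(n + 1) * dz
    grid = grid[grid <= z_hi + 1e-12]
    if grid[-1] < z_hi - 1e-12:
        grid = np.append(grid, z_hi)
    c = np.interp(grid, surfactant.z, surfactant.density)
    total = float(np.trapezoid(c, grid))
    liquid_extent = (z_hi - z0) if liquid_side == "upper" else (z0 - z_lo)
    return total - c_bulk * liquid_extent


def measure_adsorption(water: DensityProfile, surfactant: DensityProfile,
                       dz: float = 0.1, flatness_tol: float = 0.02,
                       margin: float = 1.5) -> tuple[InterfaceFrame, float]:
    """End-to-end surface excess from a (water, surfactant) profile pair.

    Locates the liquid side and the Gibbs dividing surface from the water
    profile, the surfactant bulk concentration from its own plateau, and
    integrates the excess.  Returns (InterfaceFrame, Gamma).
    """
    side = infer_liquid_side(water)
    z0 = gibbs_dividing_surface(water, liquid_side=side)
    bulk = find_bulk(surfactant, flatness_tol=flatness_tol)
    gamma = excess_adsorption(surfactant, z0, bulk.c_bulk, dz=dz,
                              liquid_side=side, margin=margin)
    frame = InterfaceFrame(z0=z0, bulk_window=bulk, c_bulk=bulk.c_bulk,
                           liquid_side=side)
    return frame, gamma
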