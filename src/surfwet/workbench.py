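"""End-to-end pipeline: generation -> profiles -> fits -> thermo -> predictions.

The pipeline is a pure function of (config, seeds): stages run in dependency
order, each writing its artifact plus a JSON metadata sidecar (parameters,
seed, package version), and identical reruns produce byte-identical numeric
output.  A stage failure halts the run with the failing stage named; partial
outputs are retained.

The configuration is a single YAML-style mapping with all physical constants
explicit — in particular the neat surface tension gamma0 is always supplied,
never defaulted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .droplet import (DropletState, delta_theta_full, delta_theta_linear,
                      landscape)
from .isotherms import fit_langmuir
from .profiles import DensityProfile, measure_adsorption
from .solution_thermo import correction_factor, kb_integral
from .synthetic import (IsothermSeries, RdfSpec, SlabSpec, SurfactantTruth,
                        langmuir_gamma, make_isotherm_series, make_rdf,
                        make_slab_profiles)
from .tension import TensionModel, dgamma_of_c
from .units import MOLAR_TO_NM3, DEFAULT_TEMPERATURE
from .wetting import MoleculeGeometry, WettingModel, ks_of_costheta

__all__ = ["RunConfig", "run_pipeline", "validate_units", "demo_config",
           "PipelineError"]

STAGES = ["generate", "adsorption", "fit", "thermo", "tension", "wetting",
          "droplet"]

INTERFACES = ["water_vapor", "solid_water"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``raw`` keeps the full mapping; convenience accessors pull the common
    physical constants.  Round-trips losslessly through YAML.
    """

    raw: dict = field(default_factory=dict)

    @property
    def stages(self) -> list[str]:
        return list(self.raw.get("stages", STAGES))

    @property
    def outdir(self) -> Path:
        return Path(self.raw.get("outdir", "results/pipeline"))

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def temperature(self) -> float:
        return float(self.raw.get("temperature_K", DEFAULT_TEMPERATURE))

    @property
    def gamma0(self) -> float:
        if "gamma0_mN_m" not in self.raw:
            raise ValueError("config must state gamma0_mN_m explicitly")
        return float(self.raw["gamma0_mN_m"])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.raw, sort_keys=True))


# --------------------------------------------------------------------------
# unit-aware table normalisation

#: supported column-name unit suffixes -> (internal suffix, multiplier)
_UNIT_SUFFIXES = {
    "_mol_l": ("_nm3", MOLAR_TO_NM3),
    "_deg": ("_rad", np.pi / 180.0),
    "_nm-3": ("_nm-3", 1.0),
    "_nm3": ("_nm3", 1.0),
    "_nm-2": ("_nm-2", 1.0),
    "_nm2": ("_nm2", 1.0),
    "_mN_m": ("_mN_m", 1.0),
    "_nm": ("_nm", 1.0),
}


def validate_units(table: pd.DataFrame) -> pd.DataFrame:
    """Normalise a table whose column names declare units by suffix.

    Supported unit suffixes: ``_nm``, ``_nm3``/``_nm-3``, ``_nm2``/``_nm-2``,
    ``_mol_l``, ``_mN_m``, ``_deg``.  Concentrations are converted to nm^-3
    (1 mol/l = 0.602214 nm^-3) and angles to radians; all other supported
    units are already internal.  A column with no supported unit suffix is an
    error.
    """
    out = {}
    for col in table.columns:
        for suffix, (new_suffix, factor) in _UNIT_SUFFIXES.items():
            if col.endswith(suffix):
                base = col[: -len(suffix)]
                out[base + new_suffix] = table[col].to_numpy(dtype=float) * factor
                break
        else:
            raise ValueError(
                f"column {col!r} does not declare a supported unit "
                f"(expected one of {sorted(_UNIT_SUFFIXES)})")
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# stages

def _sidecar(config: RunConfig, stage: str, params: dict) -> dict:
    return {"stage": stage, "seed": config.seed,
            "surfwet_version": __version__, "parameters": params}


def _iface_cfg(config: RunConfig, interface: str) -> dict:
    try:
        return config.raw["interfaces"][interface]
    except KeyError as exc:
        raise KeyError(f"config lacks interfaces.{interface}") from exc


def _stage_generate(config: RunConfig, ctx: dict) -> dict:
    gen = config.raw.get("generate", {})
    outdir = config.outdir / "synthetic"
    outdir.mkdir(parents=True, exist_ok=True)
    slab = SlabSpec(**gen.get("slab", {}))
    report = {}
    for k, interface in enumerate(INTERFACES):
        icfg = _iface_cfg(config, interface)
        k_c, g_inf = float(icfg["k_c_nm3"]), float(icfg["gamma_inf_nm2"])
        concs = [float(c) for c in icfg["concentrations_mol_l"]]
        paths = []
        for i, c0 in enumerate(concs):
            truth = SurfactantTruth(
                c0=c0, gamma_true=float(langmuir_gamma(c0, k_c, g_inf)),
                peak_width=float(gen.get("peak_width_nm", 0.3)),
                seed=config.seed + 1000 * k + i)
            water, surf = make_slab_profiles(
                slab, truth, noise=float(gen.get("profile_noise", 0.0)))
            stem = outdir / f"{interface}_{i:02d}"
            water.to_file(f"{stem}_water.dat", {"c0_mol_l": c0})
            surf.to_file(f"{stem}_surfactant.dat",
                         {"c0_mol_l": c0, "gamma_true_nm2": truth.gamma_true,
                          "seed": truth.seed})
            paths.append(str(stem))
        report[interface] = {"n_profiles": len(paths), "profiles": paths}
    for pair, spec_kwargs in gen.get("rdf", {}).items():
        rdf = make_rdf(RdfSpec(**spec_kwargs), pair=pair)
        path = outdir / f"rdf_{pair}.dat"
        io.write_xy(path, rdf.r, rdf.g, {"pair": pair, **spec_kwargs})
        report[f"rdf_{pair}"] = str(path)
    io.write_sidecar(outdir / "generate", _sidecar(config, "generate", gen))
    ctx["synthetic_dir"] = outdir
    return report


def _stage_adsorption(config: RunConfig, ctx: dict) -> dict:
    outdir = config.outdir
    syn = ctx.get("synthetic_dir", outdir / "synthetic")
    report = {}
    for interface in INTERFACES:
        icfg = _iface_cfg(config, interface)
        concs = [float(c) for c in icfg["concentrations_mol_l"]]
        rows = []
        for i, c0 in enumerate(concs):
            stem = Path(syn) / f"{interface}_{i:02d}"
            wpath, spath = f"{stem}_water.dat", f"{stem}_surfactant.dat"
            if not Path(wpath).exists():
                raise FileNotFoundError(f"missing profile file {wpath}")
            water = DensityProfile.from_file(wpath, species="water")
            surf = DensityProfile.from_file(spath, species="surfactant")
            frame, gamma = measure_adsorption(water, surf)
            rows.append({"c0_mol_l": frame.c_bulk / MOLAR_TO_NM3,
                         "gamma_nm2": gamma, "sd_c0": 0.0, "sd_gamma": 0.0})
        df = pd.DataFrame(rows)
        path = outdir / f"isotherm_{interface}.csv"
        io.write_isotherm_csv(path, df)
        io.write_sidecar(path, _sidecar(config, "adsorption",
                                        {"interface": interface}))
        ctx.setdefault("isotherms", {})[interface] = IsothermSeries.from_dataframe(
            df, interface=interface)
        report[interface] = str(path)
    return report


def _stage_fit(config: RunConfig, ctx: dict) -> dict:
    fit_cfg = config.raw.get("fit", {})
    report = {}
    for interface in INTERFACES:
        series = ctx.get("isotherms", {}).get(interface)
        if series is None:
            path = config.outdir / f"isotherm_{interface}.csv"
            if not path.exists():
                raise FileNotFoundError(f"missing isotherm table {path}")
            series = IsothermSeries.from_dataframe(io.read_isotherm_csv(path),
                                                   interface=interface)
        fit = fit_langmuir(series, weighting=fit_cfg.get("weighting", "auto"))
        ctx.setdefault("fits", {})[interface] = fit
        path = config.outdir / f"fit_{interface}.json"
        path.write_text(json.dumps(fit.to_dict(), indent=2) + "\n")
        io.write_sidecar(path, _sidecar(config, "fit", fit_cfg))
        report[interface] = fit.to_dict()
    return report


def _stage_thermo(config: RunConfig, ctx: dict) -> dict:
    syn = ctx.get("synthetic_dir", config.outdir / "synthetic")
    thermo_cfg = config.raw.get("thermo", {})
    G = {}
    for pair in ("mm", "mw"):
        key = f"G_{pair}_nm3"
        if key in thermo_cfg:
            G[pair] = float(thermo_cfg[key])
            continue
        path = Path(syn) / f"rdf_{pair}.dat"
        if not path.exists():
            raise FileNotFoundError(f"missing RDF file {path}")
        r, g, _ = io.read_xy(path)
        from .synthetic import RadialDistribution

        G[pair] = kb_integral(RadialDistribution(r, g, pair=pair)).value
    report = {"G_mm_nm3": G["mm"], "G_mw_nm3": G["mw"]}
    for interface in INTERFACES:
        fit = ctx.get("fits", {}).get(interface)
        if fit is None:
            raise PipelineError("thermo", f"no fit available for {interface}")
        xi = correction_factor(G["mm"], G["mw"], fit.gamma_inf, fit.K,
                               config.temperature)
        report[f"xi_{interface}"] = xi
        ctx.setdefault("xi", {})[interface] = xi
    path = config.outdir / "thermo.json"
    path.write_text(json.dumps(report, indent=2) + "\n")
    io.write_sidecar(path, _sidecar(config, "thermo", thermo_cfg))
    return report


def _tension_models(config: RunConfig, ctx: dict) -> dict:
    models = {}
    for interface in INTERFACES:
        fit = ctx["fits"][interface]
        xi = ctx.get("xi", {}).get(interface, 1.0)
        gamma0 = config.gamma0 if interface == "water_vapor" else None
        models[interface] = TensionModel(gamma_inf=fit.gamma_inf, xi=xi,
                                         T=config.temperature, gamma0=gamma0)
    return models


def _stage_tension(config: RunConfig, ctx: dict) -> dict:
    models = _tension_models(config, ctx)
    ctx["tension_models"] = models
    c_grid = np.asarray(config.raw.get("tension", {}).get(
        "c0_grid_mol_l", np.linspace(0.0, 0.5, 26).tolist()), dtype=float)
    report = {}
    for interface in INTERFACES:
        fit = ctx["fits"][interface]
        res = dgamma_of_c(c_grid, fit, models[interface])
        lin_ok = np.asarray(
            fit.predict(c_grid) <= 0.1 * fit.gamma_inf / models[interface].xi)
        df = pd.DataFrame({
            "c0_mol_l": c_grid,
            "dgamma_mN_m": np.asarray(res.dgamma),
            "pi_mN_m": np.asarray(res.surface_pressure),
            "validity_flag": np.where(lin_ok, "linear_ok", "nonlinear"),
        })
        path = config.outdir / f"tension_{interface}.csv"
        df.to_csv(path, index=False)
        io.write_sidecar(path, _sidecar(config, "tension",
                                        {"interface": interface,
                                         "xi": models[interface].xi}))
        report[interface] = str(path)
    return report


def _stage_wetting(config: RunConfig, ctx: dict) -> dict:
    wcfg = config.raw.get("wetting")
    if not wcfg:
        return {"skipped": "no wetting section in config"}
    model = WettingModel(
        K_s0=float(wcfg["K_s0_nm"]), b_s=float(wcfg["b_s_nm"]),
        b_v=float(wcfg["b_v_nm"]),
        gamma_tilde_s=float(wcfg["gamma_tilde_s_mN_m"]),
        gamma_tilde_v=float(wcfg["gamma_tilde_v_mN_m"]),
        gamma=config.gamma0, T=config.temperature)
    geometry = MoleculeGeometry(A_m=float(wcfg["A_m_nm2"]),
                                shape=wcfg.get("shape", "sphere"),
                                ratio=wcfg.get("ratio"))
    ctx["wetting_model"] = model
    ctx["molecule_geometry"] = geometry
    costheta = np.linspace(-0.95, 0.95, 39)
    df = pd.DataFrame({"costheta": costheta,
                       "K_s_nm": ks_of_costheta(costheta, model, geometry)})
    path = config.outdir / "ks_of_costheta.csv"
    df.to_csv(path, index=False)
    io.write_sidecar(path, _sidecar(config, "wetting", wcfg))
    return {"table": str(path), "A_c_star_nm2": geometry.A_c_star}


def _stage_droplet(config: RunConfig, ctx: dict) -> dict:
    dcfg = config.raw.get("droplet", {})
    theta = float(dcfg.get("theta_deg", config.raw.get("theta_deg", 90.0)))
    c_grid = np.asarray(dcfg.get("c0_grid_mol_l",
                                 np.linspace(0.0, 0.2, 21).tolist()),
                        dtype=float)
    models = ctx.get("tension_models") or _tension_models(config, ctx)
    rows = []
    for c0 in c_grid:
        state = DropletState(theta_deg=theta, gamma0=config.gamma0, c0=float(c0),
                             fit_v=ctx["fits"]["water_vapor"],
                             model_v=models["water_vapor"],
                             fit_s=ctx["fits"]["solid_water"],
                             model_s=models["solid_water"])
        full = delta_theta_full(state)
        lin = delta_theta_linear(state)
        rows.append({"c0_mol_l": c0, "dtheta_deg": full.dtheta_deg,
                     "dtheta_linear_deg": lin.dtheta_deg, "flag": full.flag})
    df = pd.DataFrame(rows)
    path = config.outdir / "dtheta_curve.csv"
    df.to_csv(path, index=False)
    io.write_sidecar(path, _sidecar(config, "droplet",
                                    {"theta_deg": theta}))
    report = {"curve": str(path), "theta_deg": theta}
    if ctx.get("wetting_model") is not None:
        grid = np.linspace(10.0, 170.0, 33)
        land = landscape(float(dcfg.get("landscape_c0_mol_l", 0.016)), grid,
                         ctx["fits"]["water_vapor"].K, ctx["wetting_model"],
                         ctx["molecule_geometry"], config.gamma0)
        lpath = config.outdir / "dtheta_landscape.csv"
        land.to_csv(lpath, index=False)
        report["landscape"] = str(lpath)
    return report


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "adsorption": _stage_adsorption,
    "fit": _stage_fit,
    "thermo": _stage_thermo,
    "tension": _stage_tension,
    "wetting": _stage_wetting,
    "droplet": _stage_droplet,
}


def run_pipeline(config: RunConfig | dict, stages: list[str] | None = None) -> dict:
    """Execute the pipeline stages in dependency order.

    Returns the aggregated run report: fitted (k_c, Gamma_inf, K), xi per
    interface, and paths of every artifact written.  Raises
    :class:`PipelineError` naming the first failing stage; earlier stages'
    outputs are retained on disk.
    """
    if isinstance(config, dict):
        config = RunConfig(config)
    config.outdir.mkdir(parents=True, exist_ok=True)
    todo = stages if stages is not None else config.stages
    unknown = [s for s in todo if s not in _STAGE_FUNCS]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")
    ctx: dict = {}
    report: dict = {"stages": {}}
    for stage in STAGES:  # canonical order regardless of listing order
        if stage not in todo:
            continue
        try:
            report["stages"][stage] = _STAGE_FUNCS[stage](config, ctx)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
    (config.outdir / "report.json").write_text(
        json.dumps(report, indent=2, default=str) + "\n")
    return report


def demo_config(outdir="results/pipeline", seed: int = 0) -> RunConfig:
    """A bundled end-to-end demonstration configuration on synthetic data.

    Parameters emulate a propanol-like surfactant: K_v ~ 21 nm at the
    water-vapor interface and a weaker solid-water adsorption, with
    exponential-decay and hard-sphere RDFs giving analytically known KB
    integrals.
    """
    concs = [0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.35, 0.5]
    return RunConfig({
        "seed": seed,
        "outdir": str(outdir),
        "temperature_K": 300.0,
        "gamma0_mN_m": 65.0,
        "theta_deg": 97.0,
        "generate": {
            "slab": {"box_height": 10.0, "slab_center": 7.5,
                     "slab_thickness": 5.0, "interface_width": 0.25,
                     "bulk_water_density": 33.0},
            "peak_width_nm": 0.3,
            "profile_noise": 0.0,
            "rdf": {"mm": {"form": "exp_decay", "amplitude": 0.5,
                           "decay_length": 0.25, "r_max": 3.5},
                    "mw": {"form": "hard_sphere", "sigma": 0.25,
                           "r_max": 3.5}},
        },
        "interfaces": {
            "water_vapor": {"k_c_nm3": 4.15, "gamma_inf_nm2": 5.06,
                            "concentrations_mol_l": concs},
            "solid_water": {"k_c_nm3": 1.2, "gamma_inf_nm2": 4.5,
                            "concentrations_mol_l": concs},
        },
        "fit": {"weighting": "auto"},
        "tension": {"c0_grid_mol_l": np.linspace(0.0, 0.5, 26).tolist()},
        "wetting": {"K_s0_nm": 5.4, "b_s_nm": 0.05, "b_v_nm": 0.05,
                    "gamma_tilde_s_mN_m": 25.6, "gamma_tilde_v_mN_m": 32.7,
                    "A_m_nm2": 2.0, "shape": "sphere"},
        "droplet": {"theta_deg": 97.0,
                    "c0_grid_mol_l": np.linspace(0.0, 0.2, 21).tolist(),
                    "landscape_c0_mol_l": 0.016},
    })
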