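#!/usr/bin/env python
"""Generate the synthetic MD-like inputs for the whole analysis.

Writes, under results/synthetic/:
  * water/surfactant density profile pairs for a ladder of bulk
    concentrations at a water-vapor-like and a solid-water-like interface,
  * molecule-molecule and molecule-water RDFs with closed-form KB integrals,
  * noisy (c0, Gamma) isotherm series for the fitting study.

Everything is seeded; ground-truth parameters are recorded in sidecars.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from surfwet import io
from surfwet.synthetic import (RdfSpec, SlabSpec, SurfactantTruth,
                               langmuir_gamma, make_isotherm_series,
                               make_rdf, make_slab_profiles)

OUT = Path(__file__).resolve().parents[1] / "scratch" / "synthetic"
SEED = 2024

# propanol-like water-vapor interface and a weaker solid-water one
INTERFACES = {
    "water_vapor": {"k_c_nm3": 4.15, "gamma_inf_nm2": 5.06},
    "solid_water": {"k_c_nm3": 1.2, "gamma_inf_nm2": 4.5},
}
CONCENTRATIONS = [0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.35, 0.5]

# amplitudes chosen so G_mm - G_mw ~ +0.26 nm^3, a propanol-like
# self-association strength in water
RDFS = {
    "mm": RdfSpec(form="exp_decay", amplitude=0.5, decay_length=0.25,
                  r_max=3.5),
    "mw": RdfSpec(form="hard_sphere", sigma=0.25, r_max=3.5),
}


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    slab = SlabSpec()
    for k, (interface, pars) in enumerate(INTERFACES.items()):
        for i, c0 in enumerate(CONCENTRATIONS):
            gamma_true = float(langmuir_gamma(c0, pars["k_c_nm3"],
                                              pars["gamma_inf_nm2"]))
            truth = SurfactantTruth(c0=c0, gamma_true=gamma_true,
                                    peak_width=0.3, seed=SEED + 100 * k + i)
            water, surf = make_slab_profiles(slab, truth)
            stem = OUT / f"{interface}_{i:02d}"
            water.to_file(f"{stem}_water.dat", {"c0_mol_l": c0})
            surf.to_file(f"{stem}_surfactant.dat",
                         {"c0_mol_l": c0, "gamma_true_nm2": gamma_true})
        print(f"{interface}: wrote {len(CONCENTRATIONS)} profile pairs "
              f"(k_c = {pars['k_c_nm3']} nm^3, "
              f"Gamma_inf = {pars['gamma_inf_nm2']} nm^-2)")

    for pair, spec in RDFS.items():
        rdf = make_rdf(spec, pair=pair)
        io.write_xy(OUT / f"rdf_{pair}.dat", rdf.r, rdf.g,
                    {"pair": pair, "form": spec.form,
                     "closed_form_kb_nm3": spec.closed_form_kb()})
        print(f"rdf_{pair}: {spec.form}, closed-form G = "
              f"{spec.closed_form_kb():+.4f} nm^3")

    series = make_isotherm_series(
        INTERFACES["water_vapor"]["k_c_nm3"],
        INTERFACES["water_vapor"]["gamma_inf_nm2"],
        CONCENTRATIONS, noise_x=0.05, noise_y=0.05, seed=SEED)
    io.write_isotherm_csv(OUT / "isotherm_noisy.csv", series.to_dataframe())
    io.write_sidecar(OUT / "isotherm_noisy.csv",
                     {"truth": series.truth, "seed": SEED})
    print(f"isotherm_noisy.csv: 5%/5% biaxial noise, seed {SEED}")


if __name__ == "__main__":
    main()
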