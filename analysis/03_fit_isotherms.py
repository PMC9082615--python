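#!/usr/bin/env python
"""Fit Langmuir isotherms and study ODR parameter recovery under noise.

Part 1: fit the measured (quadrature-derived) isotherms of both interfaces
and compare (k_c, Gamma_inf, K) against the generator truth.

Part 2: a seeded recovery study — 100 synthetic series with 5% noise in both
coordinates, fit by orthogonal distance regression; reports the median
relative error of the Henry coefficient K.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from surfwet import io
from surfwet.isotherms import fit_langmuir
from surfwet.synthetic import IsothermSeries, make_isotherm_series

ROOT = Path(__file__).resolve().parents[1] / "results"
TRUTH = {"water_vapor": (4.15, 5.06), "solid_water": (1.2, 4.5)}


def main():
    report = {}
    for interface, (k_c, g_inf) in TRUTH.items():
        df = io.read_isotherm_csv(ROOT / f"isotherm_{interface}.csv")
        fit = fit_langmuir(IsothermSeries.from_dataframe(df,
                                                         interface=interface))
        report[interface] = fit.to_dict()
        print(f"{interface}: k_c = {fit.k_c:.4f} nm^3 (truth {k_c}), "
              f"Gamma_inf = {fit.gamma_inf:.4f} nm^-2 (truth {g_inf}), "
              f"K = {fit.K:.3f} nm (truth {k_c * g_inf:.3f})")

    k_c, g_inf = TRUTH["water_vapor"]
    K_true = k_c * g_inf
    concs = np.geomspace(0.005, 0.5, 8)
    errors = []
    for seed in range(100):
        series = make_isotherm_series(k_c, g_inf, concs, 0.05, 0.05,
                                      seed=seed)
        errors.append(abs(fit_langmuir(series).K - K_true) / K_true)
    report["recovery_study"] = {
        "n_series": 100, "noise": 0.05,
        "median_rel_K_error": float(np.median(errors)),
        "q90_rel_K_error": float(np.quantile(errors, 0.9)),
    }
    print(f"ODR recovery over 100 noisy series: median |dK|/K = "
          f"{np.median(errors):.3f}, 90th pct = "
          f"{np.quantile(errors, 0.9):.3f}")

    (ROOT / "langmuir_fits.json").write_text(
        json.dumps(report, indent=2, default=str) + "\n")


if __name__ == "__main__":
    main()
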