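"""Fit the two scaling laws on the published 26-protocol cohort.

noise = c * wCBDI^(-1/2): image noise against the weighted dose index;
nCBDI = c * kVp^3: normalized dose output against tube potential.
Reports the fit coefficients, Pearson correlations, residual SDs and the
per-potential maximum deviations. Writes results/scaling_fits.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cbctqa.dosimetry import CGY_TO_MGY, normalized_cbdi
from cbctqa.fits import fit_fixed_power, normalized_cross_correlation
from cbctqa.protocols import fixture_path

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table1 = pd.read_csv(fixture_path("table1.csv"))
    table2 = pd.read_csv(fixture_path("table2_catphan.csv"))
    merged = table2.merge(table1[["name", "kvp", "mAs"]], on="name")
    ncbdi = np.array([
        normalized_cbdi(w, m) for w, m in zip(merged["wcbdi_cGy"], merged["mAs"])
    ])
    kvp = merged["kvp"].to_numpy(dtype=float)

    inv_sqrt = fit_fixed_power(merged["wcbdi_cGy"], merged["noise_hu"], -0.5)
    cube = fit_fixed_power(kvp, ncbdi, 3.0)
    r_noise = normalized_cross_correlation(merged["noise_hu"], merged["wcbdi_cGy"] ** -0.5)
    r_cube = normalized_cross_correlation(ncbdi, kvp**3)

    # deviations from the cubic curve, per potential group, in mGy/100 mAs
    dev_mgy = np.abs(ncbdi - cube.predict(kvp)) * CGY_TO_MGY
    groups = {
        int(k): {
            "max_abs_deviation_mGy_per_100mAs": round(float(dev_mgy[kvp == k].max()), 3),
            "mean_abs_deviation_mGy_per_100mAs": round(float(dev_mgy[kvp == k].mean()), 3),
            "n": int((kvp == k).sum()),
        }
        for k in sorted(set(kvp))
    }

    report = {
        "noise_vs_wcbdi": inv_sqrt.to_dict() | {"pearson_r_vs_inverse_sqrt": r_noise},
        "ncbdi_vs_kvp3": cube.to_dict() | {"pearson_r_vs_cube": r_cube},
        "cubic_curve_deviation_by_kvp": groups,
    }
    OUT.mkdir(exist_ok=True)
    (OUT / "scaling_fits.json").write_text(json.dumps(report, indent=2))

    print(f"noise vs wCBDI^-1/2: c = {inv_sqrt.coefficient:.2f} HU sqrt(cGy), "
          f"residual SD = {inv_sqrt.residual_sd:.2f} HU, r = {r_noise:.3f}")
    print(f"nCBDI vs kVp^3: c = {cube.coefficient:.3e} cGy/100 mAs per kV^3, "
          f"r = {r_cube:.3f}")
    print("mean |deviation| from the cubic curve by potential (mGy/100 mAs):")
    for k, g in groups.items():
        print(f"  {k} kVp: {g['mean_abs_deviation_mGy_per_100mAs']:.3f} "
              f"(max {g['max_abs_deviation_mGy_per_100mAs']:.3f}, n={g['n']})")


if __name__ == "__main__":
    main()
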