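"""Normalized dose indices and tube-potential ratio arithmetic.

Combines the measured weighted cone-beam dose indices (wCBDI) with each
protocol's mAs to get nCBDI (dose per 100 mAs), then compares the
125-vs-100 kV group ratio with the cube of the potential ratio. Writes
results/dose_indices.csv.
"""

from pathlib import Path

import pandas as pd

from cbctqa.dosimetry import DoseIndexRecord, normalized_cbdi
from cbctqa.fits import group_ncbdi_ratio, kvp_power_ratio
from cbctqa.protocols import fixture_path

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table1 = pd.read_csv(fixture_path("table1.csv"))
    table2 = pd.read_csv(fixture_path("table2_catphan.csv"))
    merged = table2.merge(table1[["name", "kvp", "mAs"]], on="name")

    records = [
        DoseIndexRecord(
            protocol_name=row["name"], kvp=row["kvp"], mAs=row["mAs"],
            wcbdi=row["wcbdi_cGy"],
            ncbdi=normalized_cbdi(row["wcbdi_cGy"], row["mAs"]),
        )
        for _, row in merged.iterrows()
    ]
    df = pd.DataFrame(
        {
            "name": [r.protocol_name for r in records],
            "kvp": [r.kvp for r in records],
            "mAs": [r.mAs for r in records],
            "wcbdi_cGy": [r.wcbdi for r in records],
            "ncbdi_cGy_per_100mAs": [r.ncbdi for r in records],
            "ncbdi_mGy_per_100mAs": [r.ncbdi_mgy for r in records],
        }
    )
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "dose_indices.csv", index=False)

    ratio, sd = group_ncbdi_ratio(records, 125.0, 100.0)
    print("mean nCBDI by tube potential (mGy/100 mAs):")
    print(df.groupby("kvp")["ncbdi_mGy_per_100mAs"].mean().round(2).to_string())
    print(f"\n125 kV / 100 kV nCBDI ratio: {ratio:.2f} +/- {sd:.2f}")
    print(f"cube of the potential ratio (125/100)^3: {kvp_power_ratio(125, 100, 3)}")
    print(f"square of the potential ratio (125/100)^2: {kvp_power_ratio(125, 100, 2)}")
    print(f"(120/100)^3 for comparison with other platforms: {kvp_power_ratio(120, 100, 3)}")


if __name__ == "__main__":
    main()
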