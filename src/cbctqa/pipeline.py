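"""End-to-end study orchestration.

Takes a protocol table plus either measured inputs (chamber readings,
HU volumes) or the simulate flag, and produces the study artifacts: a dose
table (wCBDI / nCBDI per protocol), a per-protocol image-quality metrics
table, the two scaling-law fits (nCBDI vs kVp^3, noise vs wCBDI^-1/2), the
125-vs-100 kV normalized-dose ratio, and optional figures. Everything is
deterministic given the seed; a manifest records config, seed and input
hashes so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import dosimetry, fits
from .dosimetry import ChamberReadingSet
from .errors import CbctQaError, DegenerateDataError
from .image_qa import ImageVolume, compute_qa_metrics, metrics_to_row
from .protocols import Protocol, read_protocol_table
from .synthetic import (
    SimulationConfig,
    add_noise_for_dose,
    build_digital_phantom,
    simulate_chamber_readings,
)

logger = logging.getLogger(__name__)

SIMULATE = "simulate"


@dataclass
class StudyResult:
    """All study outputs plus provenance."""

    dose_table: pd.DataFrame
    metrics_table: Optional[pd.DataFrame]
    fits: dict[str, fits.FitResult]
    ratios: dict[str, tuple[float, float]]
    provenance: dict

    def write(self, out_dir: "str | Path", make_plots: bool = False) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.dose_table.to_csv(out / "dose_table.csv", index=False)
        if self.metrics_table is not None:
            self.metrics_table.to_csv(out / "metrics_table.csv", index=False)
        with open(out / "fits.json", "w") as fh:
            json.dump(
                {
                    "fits": {k: f.to_dict() for k, f in self.fits.items()},
                    "ratios": {k: {"ratio": r, "sd": s} for k, (r, s) in self.ratios.items()},
                },
                fh,
                indent=2,
            )
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)
        if make_plots:
            self.plot(out)

    def plot(self, out_dir: Path) -> None:
        """Diagnostic figures; artifacts only, never inputs to any check."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        d = self.dose_table
        fig, ax = plt.subplots()
        ax.plot(d["kvp"], d["ncbdi_mGy_per_100mAs"], "o", label="protocols")
        if "ncbdi_vs_kvp3" in self.fits:
            kv = np.linspace(d["kvp"].min(), d["kvp"].max(), 100)
            ax.plot(kv, self.fits["ncbdi_vs_kvp3"].predict(kv) * 10, "-",
                    label="c$\\cdot$kVp$^3$")
        ax.set_xlabel("tube potential (kVp)")
        ax.set_ylabel("nCBDI (mGy/100 mAs)")
        ax.legend()
        fig.savefig(out_dir / "ncbdi_vs_kvp.png", dpi=120)
        plt.close(fig)

        if self.metrics_table is not None:
            merged = d.merge(self.metrics_table, on="name")
            fig, ax = plt.subplots()
            ax.plot(merged["wcbdi_cGy"], merged["noise_hu"], "o", label="protocols")
            if "noise_vs_wcbdi" in self.fits:
                w = np.linspace(merged["wcbdi_cGy"].min(), merged["wcbdi_cGy"].max(), 100)
                ax.plot(w, self.fits["noise_vs_wcbdi"].predict(w), "-",
                        label="c/$\\sqrt{wCBDI}$")
            ax.set_xlabel("wCBDI (cGy)")
            ax.set_ylabel("noise (HU)")
            ax.legend()
            fig.savefig(out_dir / "noise_vs_wcbdi.png", dpi=120)
            plt.close(fig)

            fig, ax = plt.subplots()
            ax.plot(merged["wcbdi_cGy"], merged["cnr"], "o")
            ax.set_xlabel("wCBDI (cGy)")
            ax.set_ylabel("CNR")
            fig.savefig(out_dir / "cnr_vs_wcbdi.png", dpi=120)
            plt.close(fig)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(
    protocols: Union[Sequence[Protocol], str, Path],
    readings: Union[Mapping[str, ChamberReadingSet], str, Path, None] = SIMULATE,
    volumes: Union[Mapping[str, ImageVolume], None, str] = SIMULATE,
    config: Optional[SimulationConfig] = None,
    seed: Optional[int] = None,
    cnr_denominator: str = "background",
) -> StudyResult:
    """Run the full protocol-comparison study.

    ``readings`` / ``volumes`` may be real inputs, ``"simulate"`` (default)
    to generate them from the config, or ``None`` to skip that arm (a
    readings-only run still produces the dose table and dose fit, with the
    image metrics marked absent).
    """
    provenance: dict = {"inputs": {}}
    if isinstance(protocols, (str, Path)):
        provenance["inputs"]["protocol_table"] = _sha256(Path(protocols))
        protocols = read_protocol_table(protocols)
    protocols = list(protocols)
    cfg = config if config is not None else SimulationConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    rng = cfg.rng()
    provenance["seed"] = cfg.seed
    provenance["config"] = _config_summary(cfg)

    # --- dose arm ------------------------------------------------------
    if isinstance(readings, (str, Path)) and readings != SIMULATE:
        provenance["inputs"]["readings"] = _sha256(Path(readings))
        readings = dosimetry.read_readings_csv(readings)
    if readings == SIMULATE:
        logger.info("simulating chamber readings for %d protocols", len(protocols))
        pairs = [(p, simulate_chamber_readings(p, cfg, rng=rng)) for p in protocols]
    elif readings is None:
        raise CbctQaError("chamber readings are required to compute the dose table")
    else:
        missing = [p.name for p in protocols if p.name not in readings]
        if missing:
            raise CbctQaError(f"no chamber readings for protocols: {missing}")
        pairs = [(p, readings[p.name]) for p in protocols]
    records = dosimetry.dose_index_table(pairs)
    dose_df = dosimetry.records_to_frame(records)

    result_fits: dict[str, fits.FitResult] = {
        "ncbdi_vs_kvp3": fits.fit_fixed_power(
            [r.kvp for r in records], [r.ncbdi for r in records], 3.0
        )
    }
    ratios: dict[str, tuple[float, float]] = {}
    try:
        ratios["ncbdi_125_over_100"] = fits.group_ncbdi_ratio(records, 125.0, 100.0)
    except DegenerateDataError:
        logger.info("cohort lacks a 125 or 100 kVp group; skipping the ratio")

    # --- image arm -----------------------------------------------------
    metrics_df = None
    if volumes is not None:
        if cnr_denominator != "background":
            logger.warning(
                "CNR uses the %s-SD denominator; the literal definition divides "
                "by the background SD", cnr_denominator,
            )
        rows = []
        by_name = {r.protocol_name: r for r in records}
        if volumes == SIMULATE:
            logger.info("simulating phantom volumes (grid %s)", cfg.grid_shape)
            clean = build_digital_phantom(cfg)
            for p in protocols:
                noisy = add_noise_for_dose(clean, by_name[p.name].wcbdi, cfg, rng=rng)
                m = compute_qa_metrics(noisy, cfg.layout, cnr_denominator=cnr_denominator)
                logger.info("protocol %s: noise %.1f HU, lcd %s", p.name, m.noise, m.lcd)
                rows.append(metrics_to_row(p.name, m))
        else:
            unknown = [n for n in volumes if n not in by_name]
            if unknown:
                raise CbctQaError(
                    f"volumes reference protocols absent from the table: {unknown}"
                )
            for name, vol in volumes.items():
                m = compute_qa_metrics(vol, cfg.layout, cnr_denominator=cnr_denominator)
                rows.append(metrics_to_row(name, m))
        metrics_df = pd.DataFrame(rows)
        merged = dose_df.merge(metrics_df, on="name")
        result_fits["noise_vs_wcbdi"] = fits.fit_fixed_power(
            merged["wcbdi_cGy"], merged["noise_hu"], -0.5
        )

    return StudyResult(
        dose_table=dose_df,
        metrics_table=metrics_df,
        fits=result_fits,
        ratios=ratios,
        provenance=provenance,
    )


def _config_summary(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["layout"] = {
        "module_centers": cfg.layout.module_centers,
        "module_diameter": cfg.layout.module_diameter,
        "n_sensitometry": len(cfg.layout.sensitometry_inserts),
        "n_low_contrast": len(cfg.layout.low_contrast_inserts),
        "n_beads": len(cfg.layout.bead_positions),
    }
    return d
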