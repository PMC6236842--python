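"""Cone-beam dose indices from pencil-chamber readings.

The cone-beam dose index (CBDI) is measured with a 10 cm pencil chamber in
a 16 cm CTDI head phantom, at the center and at the 12:00 / 3:00 / 6:00 /
9:00 o'clock peripheral bores. The weighted index combines them with the
usual 1/3-2/3 weighting:

    D_periphery = (D12 + D3 + D9 + D6) / 4          (half rotation)
    wCBDI_half  = (D_center + 2 * D_periphery) / 3
    wCBDI_full  = (D_center + 2 * D12) / 3          (rotational symmetry)

and the normalized index nCBDI is wCBDI per 100 mAs, which isolates the
tube-potential dependence of the dose output. Internal dose unit is cGy
throughout; a x10 conversion to mGy is offered only at the reporting layer
to avoid silent unit mixing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import DegenerateDataError, IncompleteReadingsError
from .protocols import Protocol, Trajectory, tube_current_time_product

logger = logging.getLogger(__name__)

CGY_TO_MGY = 10.0


@dataclass(frozen=True)
class ChamberReadingSet:
    """Pencil-chamber doses (cGy) at the center and four clock positions.

    For full-rotation scans the 3:00/6:00/9:00 positions may be omitted;
    rotational symmetry makes the 12:00 reading representative.
    """

    d_center: float
    d_12: float
    d_3: Optional[float] = None
    d_6: Optional[float] = None
    d_9: Optional[float] = None
    trajectory: Trajectory = Trajectory.HALF

    def __post_init__(self) -> None:
        object.__setattr__(self, "trajectory", Trajectory.parse(self.trajectory))
        missing = self.missing_positions()
        if missing:
            raise IncompleteReadingsError(
                f"{self.trajectory.value}-rotation reading set missing positions: "
                + ", ".join(missing)
            )
        for pos, value in self._present().items():
            if value < 0 or not math.isfinite(value):
                raise IncompleteReadingsError(f"dose at {pos} must be finite and >= 0")

    def _present(self) -> dict[str, float]:
        out = {"center": self.d_center, "12:00": self.d_12}
        for pos, v in (("3:00", self.d_3), ("6:00", self.d_6), ("9:00", self.d_9)):
            if v is not None:
                out[pos] = v
        return out

    def missing_positions(self) -> list[str]:
        missing = []
        if self.d_center is None:
            missing.append("center")
        if self.d_12 is None:
            missing.append("12:00")
        if self.trajectory is Trajectory.HALF:
            for pos, v in (("3:00", self.d_3), ("6:00", self.d_6), ("9:00", self.d_9)):
                if v is None:
                    missing.append(pos)
        return missing

    @property
    def has_all_peripherals(self) -> bool:
        return None not in (self.d_3, self.d_6, self.d_9)


@dataclass(frozen=True)
class DoseIndexRecord:
    """Per-protocol dose summary: wCBDI (cGy) and nCBDI (cGy/100 mAs)."""

    protocol_name: str
    kvp: float
    mAs: float
    wcbdi: float
    ncbdi: float

    @property
    def ncbdi_mgy(self) -> float:
        """nCBDI in mGy/100 mAs (reporting convenience)."""
        return self.ncbdi * CGY_TO_MGY


def peripheral_dose(r: ChamberReadingSet) -> float:
    """Mean of the four peripheral doses, (D12 + D3 + D9 + D6)/4."""
    if not r.has_all_peripherals:
        raise IncompleteReadingsError(
            "peripheral dose needs all four clock positions; missing: "
            + ", ".join(p for p, v in (("3:00", r.d_3), ("6:00", r.d_6), ("9:00", r.d_9)) if v is None)
        )
    return (r.d_12 + r.d_3 + r.d_9 + r.d_6) / 4.0


def weighted_cbdi(r: ChamberReadingSet) -> float:
    """Weighted cone-beam dose index in cGy.

    Half rotation: (D_center + 2*D_periphery)/3 with D_periphery the
    four-position mean. Full rotation: (D_center + 2*D12)/3; if all four
    peripherals were measured anyway their mean is used instead (strictly
    more information under the same symmetry argument) and this is logged.
    """
    if r.trajectory is Trajectory.HALF:
        return (r.d_center + 2.0 * peripheral_dose(r)) / 3.0
    if r.has_all_peripherals:
        logger.info("full-rotation reading set has all peripherals; using their mean")
        return (r.d_center + 2.0 * peripheral_dose(r)) / 3.0
    return (r.d_center + 2.0 * r.d_12) / 3.0


def normalized_cbdi(wcbdi: float, mAs: float) -> float:
    """wCBDI per 100 mAs, in cGy/100 mAs. Multiply by 10 for mGy/100 mAs."""
    if not mAs > 0:
        raise ValueError(f"mAs must be > 0, got {mAs}")
    return wcbdi / mAs * 100.0


def dose_index_table(
    readings: Sequence[tuple[Protocol, ChamberReadingSet]],
) -> list[DoseIndexRecord]:
    """Assemble per-protocol dose index records, in input order."""
    names = [p.name for p, _ in readings]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise DegenerateDataError(f"duplicate protocol names: {sorted(dupes)}")
    records = []
    for p, r in readings:
        w = weighted_cbdi(r)
        mas = tube_current_time_product(p)
        records.append(
            DoseIndexRecord(
                protocol_name=p.name, kvp=p.kvp, mAs=mas, wcbdi=w,
                ncbdi=normalized_cbdi(w, mas),
            )
        )
    return records


def records_to_frame(records: Iterable[DoseIndexRecord]) -> pd.DataFrame:
    rows = [
        {
            "name": r.protocol_name,
            "kvp": r.kvp,
            "mAs": r.mAs,
            "wcbdi_cGy": r.wcbdi,
            "ncbdi_cGy_per_100mAs": r.ncbdi,
            "ncbdi_mGy_per_100mAs": r.ncbdi_mgy,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def read_readings_csv(path: "str | Path") -> dict[str, ChamberReadingSet]:
    """Read a chamber-readings CSV (protocol,trajectory,d_center,d_12[,d_3,d_6,d_9])."""
    df = pd.read_csv(path)

    def opt(row, col):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return float(row[col])

    out: dict[str, ChamberReadingSet] = {}
    for _, row in df.iterrows():
        out[str(row["protocol"]).strip()] = ChamberReadingSet(
            d_center=float(row["d_center"]),
            d_12=float(row["d_12"]),
            d_3=opt(row, "d_3"),
            d_6=opt(row, "d_6"),
            d_9=opt(row, "d_9"),
            trajectory=Trajectory.parse(row["trajectory"]),
        )
    return out


def readings_to_frame(
    readings: Sequence[tuple[Protocol, ChamberReadingSet]],
) -> pd.DataFrame:
    rows = []
    for p, r in readings:
        rows.append(
            {
                "protocol": p.name,
                "trajectory": r.trajectory.value,
                "d_center": r.d_center,
                "d_12": r.d_12,
                "d_3": r.d_3,
                "d_6": r.d_6,
                "d_9": r.d_9,
            }
        )
    return pd.DataFrame(rows)
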