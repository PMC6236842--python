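"""CBCT acquisition protocols and their derived quantities.

A protocol is the operator-facing description of a cone-beam acquisition:
tube potential (kVp), tube current (mA), x-ray pulse width, gantry
trajectory (half rotation over 200 deg or full rotation over 360 deg) and
gantry speed. Two quantities follow arithmetically and are what the dose
and image-quality analyses consume:

* the number of projections, ``round(scan_angle / gantry_speed * frame_rate)``,
  with the pulsed-fluoro frame rate fixed at 15 projections/s by default
  (the unique value consistent with vendor protocol tables: a 200 deg half
  scan at 6 deg/s yields 500 projections);
* the tube current-time product in mAs,
  ``current * pulse_width * projection_count``.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import FormatError, InvalidProtocolError

#: Projections acquired per second. Not printed on protocol sheets; fixed at
#: the unique value consistent with the vendor tables (see module docstring).
DEFAULT_FRAME_RATE = 15.0

HALF_SCAN_ANGLE = 200.0
FULL_SCAN_ANGLE = 360.0


class Trajectory(str, enum.Enum):
    """Gantry rotation trajectory."""

    HALF = "half"
    FULL = "full"

    @classmethod
    def parse(cls, value: "str | Trajectory") -> "Trajectory":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise InvalidProtocolError(
                f"unknown trajectory {value!r}; expected 'half' or 'full'"
            ) from None

    @property
    def scan_angle(self) -> float:
        return HALF_SCAN_ANGLE if self is Trajectory.HALF else FULL_SCAN_ANGLE


@dataclass(frozen=True)
class Protocol:
    """One CBCT acquisition technique.

    Parameters
    ----------
    name
        Protocol label, e.g. ``"Head"``.
    kvp
        Peak tube potential in kV.
    current
        Tube current in mA.
    pulse_width
        X-ray pulse duration in ms (20 ms on the platform studied).
    trajectory
        ``Trajectory.HALF`` (200 deg) or ``Trajectory.FULL`` (360 deg).
    gantry_speed
        Gantry rotation speed in deg/s.
    frame_rate
        Projections acquired per second; default 15/s.
    metadata
        Opaque carrier for fields that do not enter any computation
        (bowtie filter, start/stop angles, reconstruction settings).
    """

    name: str
    kvp: float
    current: float
    pulse_width: float = 20.0
    trajectory: Trajectory = Trajectory.HALF
    gantry_speed: float = 6.0
    frame_rate: float = DEFAULT_FRAME_RATE
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        object.__setattr__(self, "trajectory", Trajectory.parse(self.trajectory))
        for attr in ("kvp", "current", "pulse_width", "gantry_speed", "frame_rate"):
            value = getattr(self, attr)
            if not value > 0:
                raise InvalidProtocolError(
                    f"protocol {self.name!r}: {attr} must be > 0, got {value}"
                )

    @property
    def scan_angle(self) -> float:
        """Total gantry rotation in degrees (200 for half, 360 for full)."""
        return self.trajectory.scan_angle

    @property
    def scan_duration(self) -> float:
        """Scan time in seconds."""
        return self.scan_angle / self.gantry_speed


def projection_count(p: Protocol) -> int:
    """Number of projections acquired: round(scan_angle / speed * frame_rate)."""
    p.validate()
    return round(p.scan_angle / p.gantry_speed * p.frame_rate)


def tube_current_time_product(p: Protocol) -> float:
    """Total tube current-time product in mAs.

    current [mA] * pulse width [s] * number of projections.
    """
    return p.current * (p.pulse_width / 1000.0) * projection_count(p)


_REQUIRED_COLUMNS = {
    "name": ("name", "protocol", "protocol_name"),
    "kvp": ("kvp", "tube_potential", "kv"),
    "current": ("current", "current_ma", "tube_current", "ma"),
    "trajectory": ("trajectory", "gantry_rotation_trajectory"),
    "gantry_speed": ("gantry_speed", "gantry_speed_deg_s", "speed"),
}
_OPTIONAL_COLUMNS = {
    "pulse_width": ("pulse_width", "pulse_width_ms"),
    "mas": ("mas", "tube_current_time_product"),
    "projections": ("projections", "number_of_projections", "projection_count"),
}


def _normalize(col: str) -> str:
    """Lower-case, strip units in parentheses, collapse separators."""
    col = col.strip().lower()
    if "(" in col:
        col = col[: col.index("(")]
    return col.strip().replace(" ", "_").replace("-", "_")


def read_protocol_table(path: "str | Path") -> list[Protocol]:
    """Read a protocol table CSV into a list of :class:`Protocol`.

    The header is matched case-insensitively with units stripped. Derived
    columns (``mAs``, ``projections``), when present, are validated against
    recomputation; a mismatch is reported as a ``UserWarning`` carrying both
    values and the recomputed protocol is kept.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise FormatError(f"{path}: protocol table has no data rows")
    cols = {_normalize(c): c for c in df.columns}

    def find(aliases: tuple[str, ...]) -> "str | None":
        for a in aliases:
            if a in cols:
                return cols[a]
        return None

    mapping: dict[str, str] = {}
    for key, aliases in _REQUIRED_COLUMNS.items():
        col = find(aliases)
        if col is None:
            raise FormatError(f"{path}: missing required column {key!r}")
        mapping[key] = col
    for key, aliases in _OPTIONAL_COLUMNS.items():
        col = find(aliases)
        if col is not None:
            mapping[key] = col

    protocols: list[Protocol] = []
    for _, row in df.iterrows():
        p = Protocol(
            name=str(row[mapping["name"]]).strip(),
            kvp=float(row[mapping["kvp"]]),
            current=float(row[mapping["current"]]),
            pulse_width=float(row[mapping["pulse_width"]]) if "pulse_width" in mapping else 20.0,
            trajectory=Trajectory.parse(row[mapping["trajectory"]]),
            gantry_speed=float(row[mapping["gantry_speed"]]),
        )
        if "projections" in mapping and not pd.isna(row[mapping["projections"]]):
            stated, computed = int(row[mapping["projections"]]), projection_count(p)
            if stated != computed:
                warnings.warn(
                    f"protocol {p.name!r}: stated projections {stated} != "
                    f"recomputed {computed}",
                    stacklevel=2,
                )
        if "mas" in mapping and not pd.isna(row[mapping["mas"]]):
            stated_mas = float(row[mapping["mas"]])
            computed_mas = tube_current_time_product(p)
            if abs(stated_mas - computed_mas) > 0.5:
                warnings.warn(
                    f"protocol {p.name!r}: stated mAs {stated_mas} != "
                    f"recomputed {computed_mas:.1f}",
                    stacklevel=2,
                )
        protocols.append(p)
    return protocols


def load_reference_protocols() -> list[Protocol]:
    """The 26-protocol cohort shipped with the package."""
    return read_protocol_table(fixture_path("table1.csv"))


def fixture_path(name: str) -> Path:
    """Absolute path of a packaged fixture table."""
    return Path(__file__).parent / "fixtures" / name


def protocols_to_frame(protocols: Iterable[Protocol]) -> pd.DataFrame:
    """Tabulate protocols with their derived quantities."""
    rows = [
        {
            "name": p.name,
            "kvp": p.kvp,
            "current_mA": p.current,
            "pulse_width_ms": p.pulse_width,
            "trajectory": p.trajectory.value,
            "gantry_speed_deg_s": p.gantry_speed,
            "projections": projection_count(p),
            "mAs": tube_current_time_product(p),
            "scan_duration_s": p.scan_duration,
        }
        for p in protocols
    ]
    return pd.DataFrame(rows)
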