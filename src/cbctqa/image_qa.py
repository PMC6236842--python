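"""Image-quality metrics on HU volumes of a Catphan-style phantom.

Implements the six metrics used to compare cone-beam CT acquisition
protocols, computed directly from a 3-D Hounsfield-unit volume and a
geometric description of the phantom (:class:`PhantomLayout`):

* **noise** - SD of HU in a central cylinder of the uniformity module
  (diameter 40% of the module diameter);
* **uniformity** - max |peripheral ROI mean - central ROI mean| over four
  peripheral cylinders in the uniformity module;
* **HU constancy** - max |measured - expected| over the air (-1000 HU),
  LDPE (-100 HU) and acrylic (120 HU) sensitometry inserts;
* **low-contrast detectability** - smallest 1%-contrast (10 HU) insert
  diameter for which 4x the SD of background ROI means is <= 10 HU;
* **CNR** - |mean(ROI) - mean(BKG)| divided by a noise SD; and
* **MTF f50/f10** - spatial frequencies at 50% / 10% modulation, from the
  point-spread image of embedded high-density beads.

Geometry convention: volume axes are (slice z, row y, column x), all ROI
geometry is specified in phantom millimeters (never voxels), and a voxel
belongs to an ROI iff its *center* lies inside the cylinder, with the
z-interval half-open. This makes every metric deterministic and
resolution-consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    DetectionError,
    GeometryError,
    TooSmallRoiError,
)

# --------------------------------------------------------------------------
# volume container and I/O


@dataclass
class ImageVolume:
    """A 3-D HU volume with physical spacing.

    ``voxels`` is indexed (z, y, x); ``spacing`` and ``origin`` are (x, y, z)
    in mm, ``origin`` being the physical position of the center of voxel
    (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise GeometryError(f"expected a 3-D volume, got shape {self.voxels.shape}")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing components must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise GeometryError("volume contains non-finite HU values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def axis_coords(self, axis: Literal["x", "y", "z"]) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        i = "xyz".index(axis)
        n = self.voxels.shape[{"x": 2, "y": 1, "z": 0}[axis]]
        return self.origin[i] + self.spacing[i] * np.arange(n)

    def extent(self) -> tuple[tuple[float, float], ...]:
        """Physical (min, max) of the volume per axis, at voxel edges."""
        out = []
        for axis in ("x", "y", "z"):
            c = self.axis_coords(axis)
            h = self.spacing["xyz".index(axis)] / 2.0
            out.append((c[0] - h, c[-1] + h))
        return tuple(out)

    def copy(self) -> "ImageVolume":
        return replace(self, voxels=self.voxels.copy())


def read_nifti(path: "str | Path") -> ImageVolume:
    """Load a NIfTI volume as HU. Axes are reordered to (z, y, x)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)  # (x, y, z)
    zooms = img.header.get_zooms()[:3]
    return ImageVolume(
        voxels=np.transpose(data, (2, 1, 0)),
        spacing=(float(zooms[0]), float(zooms[1]), float(zooms[2])),
    )


def write_nifti(v: ImageVolume, path: "str | Path") -> None:
    import nibabel as nib

    affine = np.diag([v.spacing[0], v.spacing[1], v.spacing[2], 1.0])
    affine[:3, 3] = v.origin
    nib.save(nib.Nifti1Image(np.transpose(v.voxels, (2, 1, 0)), affine), str(path))


def read_dicom_series(paths: Sequence["str | Path"]) -> ImageVolume:
    """Load an axial DICOM series as HU, applying rescale slope/intercept."""
    import pydicom

    slices = sorted(
        (pydicom.dcmread(str(p)) for p in paths),
        key=lambda d: float(d.ImagePositionPatient[2]),
    )
    first = slices[0]
    hu = np.stack(
        [
            d.pixel_array.astype(np.float64) * float(getattr(d, "RescaleSlope", 1.0))
            + float(getattr(d, "RescaleIntercept", 0.0))
            for d in slices
        ]
    )
    dz = (
        float(slices[1].ImagePositionPatient[2]) - float(first.ImagePositionPatient[2])
        if len(slices) > 1
        else float(getattr(first, "SliceThickness", 1.0))
    )
    px = [float(x) for x in first.PixelSpacing]  # (row, col) mm
    pos = [float(x) for x in first.ImagePositionPatient]
    return ImageVolume(
        voxels=hu, spacing=(px[1], px[0], abs(dz)), origin=(pos[0], pos[1], pos[2])
    )


# --------------------------------------------------------------------------
# ROI machinery


@dataclass(frozen=True)
class RoiCylinder:
    """A z-aligned cylindrical ROI: center (x, y, z) mm, diameter and length mm."""

    center: tuple[float, float, float]
    diameter: float
    length: float

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.length <= 0:
            raise GeometryError("cylinder diameter and length must be > 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


def cylinder_mask(v: ImageVolume, roi: RoiCylinder) -> tuple[np.ndarray, tuple[slice, slice, slice]]:
    """Boolean mask (over a cropped bounding box) of voxel centers inside the ROI.

    Returns ``(mask, (zsl, ysl, xsl))`` so callers can index
    ``v.voxels[zsl, ysl, xsl][mask]``. The z-interval is half-open:
    ``cz - L/2 <= z < cz + L/2``.
    """
    cx, cy, cz = roi.center
    (xmin, xmax), (ymin, ymax), (zmin, zmax) = v.extent()
    if not (
        xmin <= cx - roi.radius and cx + roi.radius <= xmax
        and ymin <= cy - roi.radius and cy + roi.radius <= ymax
        and zmin <= cz - roi.length / 2 and cz + roi.length / 2 <= zmax
    ):
        raise GeometryError(
            f"ROI {roi} extends outside the volume extent {v.extent()}"
        )
    xs, ys, zs = v.axis_coords("x"), v.axis_coords("y"), v.axis_coords("z")
    xsl = _crop(xs, cx - roi.radius, cx + roi.radius)
    ysl = _crop(ys, cy - roi.radius, cy + roi.radius)
    zsl = _crop(zs, cz - roi.length / 2, cz + roi.length / 2)
    zz = zs[zsl][:, None, None]
    yy = ys[ysl][None, :, None]
    xx = xs[xsl][None, None, :]
    mask = (
        ((xx - cx) ** 2 + (yy - cy) ** 2 <= roi.radius**2)
        & (zz >= cz - roi.length / 2)
        & (zz < cz + roi.length / 2)
    )
    return mask, (zsl, ysl, xsl)


def _crop(coords: np.ndarray, lo: float, hi: float) -> slice:
    idx = np.nonzero((coords >= lo - 1e-9) & (coords <= hi + 1e-9))[0]
    if idx.size == 0:
        return slice(0, 0)
    return slice(int(idx[0]), int(idx[-1]) + 1)


def roi_stats(v: ImageVolume, roi: RoiCylinder, min_voxels: int = 10) -> tuple[float, float, int]:
    """(mean HU, SD HU, voxel count) over voxel centers inside the cylinder.

    SD is the population standard deviation (ddof 0) of the selected voxels.
    """
    mask, sls = cylinder_mask(v, roi)
    values = v.voxels[sls][mask]
    if values.size < min_voxels:
        raise TooSmallRoiError(
            f"ROI selects {values.size} voxels (< {min_voxels}); "
            "enlarge the ROI or refine the grid"
        )
    return float(values.mean()), float(values.std()), int(values.size)


# --------------------------------------------------------------------------
# phantom layout


@dataclass(frozen=True)
class SensitometryInsert:
    name: str
    center: tuple[float, float, float]
    diameter: float
    expected_hu: float


@dataclass(frozen=True)
class LowContrastInsert:
    diameter: float
    center: tuple[float, float, float]
    contrast_hu: float = 10.0  # 1% contrast


@dataclass(frozen=True)
class PhantomLayout:
    """Geometric description of a Catphan-style phantom in phantom mm.

    Module z-centers follow the physical phantom: CTP404 (sensitometry),
    CTP528 (resolution beads), CTP515 (low contrast), CTP486 (uniformity).
    The phantom axis is x = y = 0.
    """

    module_centers: dict[str, float]
    module_diameter: float = 150.0
    module_length: float = 20.0
    phantom_diameter: float = 200.0
    sensitometry_inserts: tuple[SensitometryInsert, ...] = ()
    low_contrast_inserts: tuple[LowContrastInsert, ...] = ()
    bead_positions: tuple[tuple[float, float, float], ...] = ()
    # uniformity ROI geometry: peripheral cylinders at 12/3/6/9 o'clock at
    # 80% of the module radius, diameter 10% of the module diameter
    uniformity_radius_frac: float = 0.8
    uniformity_roi_diameter_frac: float = 0.1
    uniformity_roi_length: float = 10.0
    noise_roi_diameter_frac: float = 0.4
    noise_roi_length: float = 10.0
    # low-contrast-detectability ROI placement: two rows of circles in
    # background at ring_radius -/+ (d + clearance), midway between inserts
    lcd_rois_per_row: int = 8
    lcd_row_clearance: float = 2.0
    lcd_roi_length: float = 6.0
    lc_ring_radius: float = 50.0
    cnr_roi_length: float = 16.0

    # ---- derived ROI constructors -------------------------------------

    def _module_z(self, key: str) -> float:
        try:
            return self.module_centers[key]
        except KeyError:
            raise GeometryError(f"layout has no {key} module") from None

    def noise_roi(self) -> RoiCylinder:
        return RoiCylinder(
            center=(0.0, 0.0, self._module_z("CTP486")),
            diameter=self.noise_roi_diameter_frac * self.module_diameter,
            length=self.noise_roi_length,
        )

    def uniformity_rois(self) -> tuple[RoiCylinder, list[RoiCylinder]]:
        z = self._module_z("CTP486")
        d = self.uniformity_roi_diameter_frac * self.module_diameter
        r = self.uniformity_radius_frac * self.module_diameter / 2.0
        central = RoiCylinder(center=(0.0, 0.0, z), diameter=d, length=self.uniformity_roi_length)
        peripherals = [
            RoiCylinder(center=(r * math.cos(a), r * math.sin(a), z), diameter=d,
                        length=self.uniformity_roi_length)
            for a in (math.pi / 2, 0.0, -math.pi / 2, math.pi)  # 12, 3, 6, 9 o'clock
        ]
        return central, peripherals

    def sensitometry_rois(self) -> list[tuple[SensitometryInsert, RoiCylinder]]:
        # measure over 60% of the insert diameter to stay clear of the
        # partial-volume rim
        return [
            (ins, RoiCylinder(center=ins.center, diameter=0.6 * ins.diameter,
                              length=self.uniformity_roi_length))
            for ins in self.sensitometry_inserts
        ]

    def lcd_diameters(self) -> list[float]:
        return sorted(ins.diameter for ins in self.low_contrast_inserts)

    def lcd_background_rois(self, diameter: float) -> list[RoiCylinder]:
        """Two rows of background circle ROIs of the given diameter.

        Rows sit at the insert ring radius minus/plus the ROI diameter plus a
        clearance margin, at angles midway between the ring inserts, so every
        ROI samples pure background.
        """
        z = self._module_z("CTP515")
        rois = []
        offset = diameter + self.lcd_row_clearance
        step = 2 * math.pi / self.lcd_rois_per_row
        for row_r in (self.lc_ring_radius - offset, self.lc_ring_radius + offset):
            for k in range(self.lcd_rois_per_row):
                a = (k + 0.5) * step
                rois.append(
                    RoiCylinder(
                        center=(row_r * math.cos(a), row_r * math.sin(a), z),
                        diameter=diameter,
                        length=self.lcd_roi_length,
                    )
                )
        self._check_background(rois, diameter)
        return rois

    def _check_background(self, rois: list[RoiCylinder], diameter: float) -> None:
        for roi in rois:
            x, y, _ = roi.center
            if math.hypot(x, y) + roi.radius > self.module_diameter / 2.0:
                raise GeometryError(
                    f"LCD background ROI at ({x:.1f}, {y:.1f}) leaves the module"
                )
            for ins in self.low_contrast_inserts:
                gap = (
                    math.hypot(x - ins.center[0], y - ins.center[1])
                    - roi.radius - ins.diameter / 2.0
                )
                if gap < self.lcd_row_clearance - 1e-9:
                    raise GeometryError(
                        f"LCD background ROI at ({x:.1f}, {y:.1f}) is {gap:.1f} mm "
                        f"from the {ins.diameter:g} mm insert (< "
                        f"{self.lcd_row_clearance} mm clearance)"
                    )

    def cnr_rois(self) -> tuple[RoiCylinder, RoiCylinder]:
        """(insert ROI, adjacent background ROI) for the 15 mm 1% insert."""
        big = max(self.low_contrast_inserts, key=lambda i: i.diameter, default=None)
        if big is None:
            raise GeometryError("layout has no low-contrast inserts")
        roi = RoiCylinder(center=big.center, diameter=big.diameter, length=self.cnr_roi_length)
        bkg_center = (big.center[0] + 2.0 * big.diameter, big.center[1], big.center[2])
        bkg = RoiCylinder(center=bkg_center, diameter=big.diameter, length=self.cnr_roi_length)
        return roi, bkg

    # ---- (de)serialization --------------------------------------------

    def to_dict(self) -> dict:
        """JSON-friendly representation (tuples become lists)."""
        import dataclasses

        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomLayout":
        d = dict(d)
        d["sensitometry_inserts"] = tuple(
            SensitometryInsert(name=s["name"], center=tuple(s["center"]),
                               diameter=s["diameter"], expected_hu=s["expected_hu"])
            for s in d.get("sensitometry_inserts", ())
        )
        d["low_contrast_inserts"] = tuple(
            LowContrastInsert(diameter=s["diameter"], center=tuple(s["center"]),
                              contrast_hu=s.get("contrast_hu", 10.0))
            for s in d.get("low_contrast_inserts", ())
        )
        d["bead_positions"] = tuple(tuple(b) for b in d.get("bead_positions", ()))
        return cls(**d)

    # ---- canonical builder --------------------------------------------

    @classmethod
    def catphan(
        cls,
        module_diameter: float = 150.0,
        module_length: float = 20.0,
        phantom_diameter: float = 200.0,
        z_start: float = 0.0,
    ) -> "PhantomLayout":
        """Default Catphan-like layout: four modules stacked along z.

        Sensitometry inserts (air/LDPE/acrylic, 12 mm) sit on a 50 mm ring
        in the CTP404 module; eight 1%-contrast inserts of 2-9 mm on a 50 mm
        ring plus a central 15 mm insert in CTP515; two beads in CTP528.
        """
        zs = {
            "CTP404": z_start + 0.5 * module_length,
            "CTP528": z_start + 1.5 * module_length,
            "CTP515": z_start + 2.5 * module_length,
            "CTP486": z_start + 3.5 * module_length,
        }
        ring = 50.0
        sens = tuple(
            SensitometryInsert(
                name=name,
                center=(ring * math.cos(a), ring * math.sin(a), zs["CTP404"]),
                diameter=12.0,
                expected_hu=hu,
            )
            for name, hu, a in (
                ("air", -1000.0, math.pi / 2),
                ("ldpe", -100.0, math.pi * 7 / 6),
                ("acrylic", 120.0, -math.pi / 6),
            )
        )
        lc = tuple(
            LowContrastInsert(
                diameter=float(d),
                center=(ring * math.cos(k * math.pi / 4), ring * math.sin(k * math.pi / 4), zs["CTP515"]),
            )
            for k, d in enumerate(range(2, 10))
        ) + (LowContrastInsert(diameter=15.0, center=(0.0, 0.0, zs["CTP515"])),)
        beads = (
            (0.0, 25.0, zs["CTP528"]),
            (0.0, -25.0, zs["CTP528"]),
        )
        return cls(
            module_centers=zs,
            module_diameter=module_diameter,
            module_length=module_length,
            phantom_diameter=phantom_diameter,
            sensitometry_inserts=sens,
            low_contrast_inserts=lc,
            bead_positions=beads,
        )


# --------------------------------------------------------------------------
# result containers


@dataclass(frozen=True, order=True)
class LcdResult:
    """Low-contrast detectability as an ordered categorical.

    ``value_mm`` is the smallest detected insert diameter; when even the
    largest insert fails the 4xSD <= 10 HU rule, ``detected`` is False and
    the result prints as ">=15" (ordering places it above every detected
    value).
    """

    value_mm: float = field(compare=False)
    detected: bool = field(default=True, compare=False)

    # ">=d" (undetected) orders strictly above a detected d
    sort_index: tuple = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sort_index", (self.value_mm, 0 if self.detected else 1))

    def __str__(self) -> str:
        return f"{self.value_mm:g}" if self.detected else f">={self.value_mm:g}"


@dataclass(frozen=True)
class MtfEstimate:
    """MTF 50% / 10% frequencies in lp/cm, averaged over beads.

    When a crossing is not reached below the in-plane Nyquist frequency,
    the corresponding ``*_at_limit`` flag is set and the value reported is
    the Nyquist frequency itself.
    """

    f50: float
    f10: float
    f50_at_limit: bool = False
    f10_at_limit: bool = False
    nyquist: float = float("nan")


@dataclass(frozen=True)
class QaMetrics:
    """One volume's worth of image-quality metrics."""

    noise: float
    uniformity: float
    hu_constancy: float
    lcd: LcdResult
    cnr: float
    mtf: MtfEstimate


# --------------------------------------------------------------------------
# metrics


def noise_metric(v: ImageVolume, layout: PhantomLayout) -> float:
    """SD of HU in the central 40%-diameter cylinder of the uniformity module."""
    _, sd, _ = roi_stats(v, layout.noise_roi())
    return sd


def uniformity_metric(v: ImageVolume, layout: PhantomLayout) -> float:
    """max_n |mean(I_n) - mean(I_ctr)| over the four peripheral cylinders."""
    central, peripherals = layout.uniformity_rois()
    m_ctr, _, _ = roi_stats(v, central)
    return max(abs(roi_stats(v, p)[0] - m_ctr) for p in peripherals)


def hu_constancy_metric(v: ImageVolume, layout: PhantomLayout) -> float:
    """max |measured mean - expected HU| over air/LDPE/acrylic inserts."""
    pairs = layout.sensitometry_rois()
    if len(pairs) < 3:
        raise GeometryError(
            f"layout defines {len(pairs)} sensitometry inserts; need air, LDPE, acrylic"
        )
    return max(abs(roi_stats(v, roi)[0] - ins.expected_hu) for ins, roi in pairs)


def lcd_from_roi_mean_sds(
    sd_by_diameter: dict[float, float],
    factor: float = 4.0,
    threshold_hu: float = 10.0,
) -> LcdResult:
    """Apply the detection rule ``factor x SD <= threshold`` per diameter.

    A diameter is detected iff its background ROI-mean SD passes the rule.
    Scanning from the largest diameter down, the result is the smallest
    diameter of the contiguous detected run (an isolated pass below an
    undetected size is not trusted); if even the largest diameter fails,
    the ">= largest" sentinel is returned.
    """
    if not sd_by_diameter:
        raise ConfigurationError("no diameters to evaluate")
    diameters = sorted(sd_by_diameter)
    smallest: Optional[float] = None
    for d in reversed(diameters):
        if factor * sd_by_diameter[d] <= threshold_hu:
            smallest = d
        else:
            break
    if smallest is None:
        return LcdResult(value_mm=diameters[-1], detected=False)
    return LcdResult(value_mm=smallest, detected=True)


def low_contrast_detectability(
    v: ImageVolume,
    layout: PhantomLayout,
    factor: float = 4.0,
    threshold_hu: float = 10.0,
) -> LcdResult:
    """Smallest detected 1%-contrast insert diameter.

    For each insert diameter d, circle ROIs of diameter d are placed in
    background in two rows bracketing the insert ring; d is detected iff
    4x the SD of the per-ROI mean HUs is <= 10 HU (SD of the mean of a
    d-sized region is the noise that competes with a 10 HU object of that
    size).
    """
    if layout.lcd_rois_per_row < 3:
        raise ConfigurationError(
            f"{layout.lcd_rois_per_row} ROIs per row; need at least 3 for a stable SD"
        )
    sd_by_diameter: dict[float, float] = {}
    for d in layout.lcd_diameters():
        means = [roi_stats(v, roi, min_voxels=4)[0] for roi in layout.lcd_background_rois(d)]
        sd_by_diameter[d] = float(np.std(means, ddof=1))
    return lcd_from_roi_mean_sds(sd_by_diameter, factor=factor, threshold_hu=threshold_hu)


def cnr(
    v: ImageVolume,
    roi: RoiCylinder,
    bkg: RoiCylinder,
    denominator: Literal["background", "roi"] = "background",
) -> float:
    """Contrast-to-noise ratio between an insert ROI and a background ROI.

    ``denominator="background"`` divides |mean(I_ROI) - mean(I_BKG)| by the
    background SD (the textbook definition); ``denominator="roi"`` divides
    by the insert-ROI SD, the convention that reproduces published patient
    tables where CNR = |ROI - BKG| / N_ROI. Both are exposed because the
    two appear interchangeably in practice.
    """
    m_roi, sd_roi, _ = roi_stats(v, roi)
    m_bkg, sd_bkg, _ = roi_stats(v, bkg)
    denom = sd_bkg if denominator == "background" else sd_roi
    if denom <= 0:
        raise DegenerateDataError("CNR denominator SD is zero (constant ROI)")
    return abs(m_roi - m_bkg) / denom


def cnr_from_stats(
    roi_mean: float, bkg_mean: float, noise_sd: float
) -> float:
    """CNR from summary statistics: |roi_mean - bkg_mean| / noise_sd."""
    if noise_sd <= 0:
        raise DegenerateDataError("noise SD must be > 0")
    return abs(roi_mean - bkg_mean) / noise_sd


def mtf_from_beads(
    v: ImageVolume,
    layout: PhantomLayout,
    halfsize_xy: int = 16,
    halfsize_z: int = 4,
    pad_to: int = 256,
    detection_threshold_hu: float = 100.0,
    n_bins: int = 64,
) -> MtfEstimate:
    """MTF 50%/10% frequencies (lp/cm) from bead point-spread images.

    Per bead: extract a (2*halfsize_z+1) x (2*halfsize_xy+1)^2 neighborhood,
    subtract the median of the outermost in-plane boundary ring (local
    background), sum along z to an in-plane PSF, take the magnitude of the
    zero-padded 2-D spectrum, radially average in bins of width Nyquist /
    ``n_bins``, normalize to 1 at zero frequency, and locate the 0.5 and
    0.1 crossings by linear interpolation. Results are averaged over beads.
    """
    if not layout.bead_positions:
        raise GeometryError("layout defines no bead positions")
    dx, dy, _ = v.spacing
    if abs(dx - dy) > 1e-6:
        raise GeometryError("MTF estimation requires isotropic in-plane spacing")
    f50s, f10s, lim50, lim10 = [], [], [], []
    nyq = 0.5 / dx  # cycles/mm
    for bead in layout.bead_positions:
        psf = _bead_psf(v, bead, halfsize_xy, halfsize_z, detection_threshold_hu)
        freqs, mtf = _radial_mtf(psf, dx, pad_to, n_bins)
        for target, acc, flags in ((0.5, f50s, lim50), (0.1, f10s, lim10)):
            f = _first_crossing(freqs, mtf, target)
            if f is None:
                acc.append(nyq)
                flags.append(True)
            else:
                acc.append(f)
                flags.append(False)
    to_lp_cm = 10.0  # cycles/mm -> line pairs per cm
    return MtfEstimate(
        f50=float(np.mean(f50s)) * to_lp_cm,
        f10=float(np.mean(f10s)) * to_lp_cm,
        f50_at_limit=any(lim50),
        f10_at_limit=any(lim10),
        nyquist=nyq * to_lp_cm,
    )


def _bead_psf(
    v: ImageVolume,
    bead: tuple[float, float, float],
    halfsize_xy: int,
    halfsize_z: int,
    detection_threshold_hu: float,
) -> np.ndarray:
    xs, ys, zs = v.axis_coords("x"), v.axis_coords("y"), v.axis_coords("z")
    ix = int(np.argmin(np.abs(xs - bead[0])))
    iy = int(np.argmin(np.abs(ys - bead[1])))
    iz = int(np.argmin(np.abs(zs - bead[2])))
    nz, ny, nx = v.shape
    if not (
        halfsize_xy <= ix < nx - halfsize_xy
        and halfsize_xy <= iy < ny - halfsize_xy
        and halfsize_z <= iz < nz - halfsize_z
    ):
        raise GeometryError(f"bead neighborhood at {bead} extends outside the volume")
    cube = v.voxels[
        iz - halfsize_z : iz + halfsize_z + 1,
        iy - halfsize_xy : iy + halfsize_xy + 1,
        ix - halfsize_xy : ix + halfsize_xy + 1,
    ]
    # local background: mean over the in-plane annulus beyond 80% of the
    # window half-size (clear of any resolvable PSF), all slices. A wide
    # annulus keeps the background estimate precise enough that its error,
    # amplified by the window voxel count, stays within the noise floor
    # already removed from the spectrum.
    w = cube.shape[1]
    r2 = (np.arange(w) - halfsize_xy) ** 2
    annulus = r2[:, None] + r2[None, :] > (0.8 * halfsize_xy) ** 2
    background = float(cube[:, annulus].mean())
    net = cube - background
    if net.max() < detection_threshold_hu:
        raise DetectionError(
            f"no bead found near {bead}: peak {net.max():.1f} HU above background "
            f"is below the {detection_threshold_hu:.0f} HU detection threshold"
        )
    return net.sum(axis=0)  # project along z to the in-plane PSF


def _radial_mtf(
    psf: np.ndarray, dx: float, pad_to: int, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged MTF of an in-plane PSF.

    Averages the *power* spectrum in radial bins and subtracts the
    high-frequency plateau (mean power in the band above 90% Nyquist)
    before taking the square root: white noise in the PSF image adds an
    approximately flat power floor that would otherwise swamp the low-MTF
    crossings. On a clean PSF whose spectrum has decayed by 90% Nyquist the
    correction is a fraction of a percent.
    """
    n = max(pad_to, psf.shape[0])
    power = np.abs(np.fft.fft2(psf, s=(n, n))) ** 2
    dc = power[0, 0]
    if dc <= 0:
        raise DetectionError("bead PSF has non-positive integral; cannot normalize MTF")
    f1d = np.fft.fftfreq(n, d=dx)
    fr = np.hypot(f1d[:, None], f1d[None, :])
    nyq = 0.5 / dx
    width = nyq / n_bins
    bins = np.clip((fr / width).astype(int), 0, n_bins)
    sums = np.bincount(bins.ravel(), weights=power.ravel(), minlength=n_bins + 1)
    counts = np.bincount(bins.ravel(), minlength=n_bins + 1)
    with np.errstate(invalid="ignore"):
        radial = sums / counts
    freqs = (np.arange(n_bins) + 0.5) * width
    radial = radial[:n_bins]
    plateau_band = freqs >= 0.9 * nyq
    plateau = float(np.nanmean(radial[plateau_band])) if plateau_band.any() else 0.0
    # an unresolved PSF legitimately keeps power at Nyquist; only subtract a
    # plateau that is plausibly noise (well below the DC power)
    if plateau >= 0.25 * dc:
        plateau = 0.0
    radial = np.clip(radial - plateau, 0.0, None)
    dc = max(dc - plateau, np.finfo(float).tiny)
    # anchor the curve at exactly (0, 1): normalize by the DC component
    freqs = np.concatenate([[0.0], freqs])
    mtf = np.concatenate([[1.0], np.sqrt(radial / dc)])
    valid = np.isfinite(mtf)
    return freqs[valid], mtf[valid]


def _first_crossing(freqs: np.ndarray, mtf: np.ndarray, level: float) -> Optional[float]:
    below = np.nonzero(mtf < level)[0]
    if below.size == 0:
        return None
    j = int(below[0])
    if j == 0:
        return float(freqs[0])
    f0, f1 = freqs[j - 1], freqs[j]
    m0, m1 = mtf[j - 1], mtf[j]
    return float(f0 + (m0 - level) / (m0 - m1) * (f1 - f0))


def compute_qa_metrics(
    v: ImageVolume,
    layout: PhantomLayout,
    cnr_denominator: Literal["background", "roi"] = "background",
) -> QaMetrics:
    """All six metrics for one volume."""
    roi, bkg = layout.cnr_rois()
    return QaMetrics(
        noise=noise_metric(v, layout),
        uniformity=uniformity_metric(v, layout),
        hu_constancy=hu_constancy_metric(v, layout),
        lcd=low_contrast_detectability(v, layout),
        cnr=cnr(v, roi, bkg, denominator=cnr_denominator),
        mtf=mtf_from_beads(v, layout),
    )


def metrics_to_row(name: str, m: QaMetrics) -> dict:
    """Flatten metrics for a one-row-per-volume CSV."""
    return {
        "name": name,
        "noise_hu": m.noise,
        "uniformity_hu": m.uniformity,
        "hu_constancy_hu": m.hu_constancy,
        "lcd_mm": str(m.lcd),
        "cnr": m.cnr,
        "mtf_f50_lpcm": m.mtf.f50,
        "mtf_f10_lpcm": m.mtf.f10,
    }
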