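"""Density calibration, resampling and segmentation of CT-style volumes.

A :class:`DensityVolume` is the image substrate for the whole pipeline: a 3D
scalar voxel grid with isotropic spacing, tagged with its density units
(raw Hounsfield units or phantom-calibrated radiodensity in mgHA/cm**3).
Calibration rods scanned alongside the specimen define an affine HU ->
mgHA/cm**3 map; volumes are then down-sampled to a clinical-style resolution
and thresholded into a single connected bone+callus domain that can be meshed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

__all__ = [
    "DensityVolume",
    "PhantomCalibration",
    "BinaryMask",
    "fit_calibration",
    "apply_calibration",
    "downsample",
    "segment_bone",
    "close_and_wrap",
    "read_volume",
    "write_volume",
]

UNITS_HU = "HU"
UNITS_MGHA = "mgHA/cm3"


@dataclass
class DensityVolume:
    """3D scalar voxel grid with isotropic spacing.

    Parameters
    ----------
    data
        Scalar array, axis order (x, y, z) with z the long bone axis.
    spacing
        Isotropic voxel pitch in micrometres.
    units
        ``"HU"`` or ``"mgHA/cm3"``.
    origin
        Physical position of the corner of voxel (0,0,0) in millimetres.
    """

    data: np.ndarray
    spacing: float  # um, isotropic
    units: str = UNITS_MGHA
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("DensityVolume.data must be a 3D array")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("DensityVolume.data must be finite")
        if self.units not in (UNITS_HU, UNITS_MGHA):
            raise ValueError(f"unknown units tag {self.units!r}")

    @property
    def spacing_mm(self) -> float:
        return self.spacing / 1000.0

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing_mm**3


@dataclass
class PhantomCalibration:
    """Affine HU -> mgHA/cm**3 map fitted to calibration-rod readings."""

    slope: float  # (mgHA/cm3) / HU
    intercept: float  # mgHA/cm3
    rod_readings: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.rod_readings) < 2:
            raise ValueError("calibration requires at least 2 rod readings")
        if not (np.isfinite(self.slope) and self.slope > 0):
            raise ValueError("calibration slope must be finite and positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "rod_readings": [list(r) for r in self.rod_readings],
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "PhantomCalibration":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["slope"], d["intercept"], [tuple(r) for r in d["rod_readings"]])


@dataclass
class BinaryMask:
    """Boolean voxel mask sharing the grid of its source volume."""

    data: np.ndarray
    spacing: float  # um
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("BinaryMask.data must be a 3D array")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")

    @property
    def spacing_mm(self) -> float:
        return self.spacing / 1000.0


def fit_calibration(rod_readings) -> PhantomCalibration:
    """Ordinary least-squares line through (HU, mgHA/cm**3) rod readings."""
    rods = [(float(h), float(d)) for h, d in rod_readings]
    hu = np.array([r[0] for r in rods])
    rho = np.array([r[1] for r in rods])
    if np.unique(hu).size < 2:
        raise ValueError("calibration rods are degenerate (constant HU)")
    slope, intercept = np.polyfit(hu, rho, 1)
    return PhantomCalibration(float(slope), float(intercept), rods)


def apply_calibration(volume: DensityVolume, cal: PhantomCalibration) -> DensityVolume:
    """Convert an HU volume to calibrated radiodensity (mgHA/cm**3).

    Negative calibrated values are clamped to zero: the power-law
    density-modulus map requires non-negative density and air/marrow noise
    can dip below the calibration line.
    """
    if volume.units != UNITS_HU:
        raise ValueError("volume is already calibrated (units are not HU)")
    data = np.maximum(cal.slope * volume.data + cal.intercept, 0.0)
    return replace(volume, data=data, units=UNITS_MGHA)


def downsample(volume: DensityVolume, target_spacing: float = 400.0) -> DensityVolume:
    """Trilinear resampling onto a coarser isotropic grid.

    The native pitch (60.7 um for the scanner this emulates) is not an
    integer multiple of the 400 um clinical-style target, so interpolation
    at the new voxel centres is used rather than block averaging.
    """
    if target_spacing < volume.spacing:
        raise ValueError("upsampling requested: target spacing below native spacing")
    if target_spacing == volume.spacing:
        return replace(volume, data=volume.data.copy())
    ratio = target_spacing / volume.spacing
    new_shape = tuple(max(1, int(np.floor(s / ratio))) for s in volume.data.shape)
    # voxel-centre sampling: centre of new voxel i sits at (i+.5)*t in
    # physical units, i.e. index (i+.5)*ratio - .5 in the source grid
    grids = [ (np.arange(n) + 0.5) * ratio - 0.5 for n in new_shape ]
    coords = np.meshgrid(*grids, indexing="ij")
    data = ndimage.map_coordinates(
        volume.data, np.stack(coords), order=1, mode="nearest"
    )
    return replace(volume, data=data, spacing=float(target_spacing))


def segment_bone(volume: DensityVolume, threshold: float) -> BinaryMask:
    """Threshold a calibrated volume and keep the largest connected component."""
    if volume.units != UNITS_MGHA:
        raise ValueError("segmentation requires calibrated units (mgHA/cm3)")
    raw = volume.data >= threshold
    if not raw.any():
        raise ValueError(f"empty mask: threshold {threshold} above max density")
    labels = measure.label(raw, connectivity=1)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = labels == counts.argmax()
    return BinaryMask(keep, volume.spacing, provenance=f"threshold>={threshold}")


def _ball(radius_mm: float, spacing_mm: float) -> np.ndarray:
    r_vox = max(1, int(round(radius_mm / spacing_mm)))
    return morphology.ball(r_vox)


def close_and_wrap(
    mask: BinaryMask, gap_closing: float = 1.0, smallest_detail: float = 0.5
) -> BinaryMask:
    """Morphological surrogate for the surface-wrap step of commercial tools.

    Closes the mask with a ball of radius ``gap_closing`` (mm) then removes
    connected components smaller than a ``smallest_detail``-sized ball.
    Idempotent, and preserves voids wider than the closing distance.
    """
    if not mask.data.any():
        raise ValueError("cannot wrap an empty mask")
    selem = _ball(gap_closing, mask.spacing_mm)
    if any(s > d for s, d in zip(selem.shape, mask.data.shape)):
        raise ValueError("structuring element larger than the volume")
    # pad so the closing does not clip at the array border
    pad = selem.shape[0] // 2
    padded = np.pad(mask.data, pad)
    closed = ndimage.binary_closing(padded, structure=selem)
    closed = closed[pad:-pad, pad:-pad, pad:-pad]
    min_voxels = int(_ball(smallest_detail, mask.spacing_mm).sum())
    labels = measure.label(closed, connectivity=1)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = np.flatnonzero(counts >= min_voxels)
    cleaned = np.isin(labels, keep)
    if not cleaned.any():
        cleaned = closed  # never return an empty domain
    return BinaryMask(
        cleaned, mask.spacing, provenance=mask.provenance + "+wrap"
    )


# ----------------------------------------------------------------- file I/O

def write_volume(volume: DensityVolume, path) -> None:
    """Write a volume as NIfTI; units ride in the `descrip` header field."""
    import nibabel as nib

    affine = np.diag([volume.spacing_mm] * 3 + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
    img.header["descrip"] = f"units={volume.units}".encode()
    nib.save(img, str(path))


def read_volume(path) -> DensityVolume:
    import nibabel as nib

    img = nib.load(str(path))
    spacing_mm = float(img.affine[0, 0])
    descrip = bytes(img.header["descrip"].tobytes()).decode(errors="ignore")
    units = UNITS_MGHA
    if "units=" in descrip:
        tag = descrip.split("units=")[1].split("\x00")[0].strip()
        if tag:
            units = tag
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return DensityVolume(
        np.asarray(img.dataobj, dtype=np.float64),
        spacing=spacing_mm * 1000.0,
        units=units,
        origin=origin,
    )
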