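"""Synthetic bone phantoms, cohorts and simulated physical torsion tests.

No imaging or biomechanical data are distributed with healing-bone studies
of this kind, so every downstream stage is exercised on synthetic density
volumes that emulate the real inputs: a hollow-cylinder cortex (the tibial
diaphysis), a transverse osteotomy gap at mid-diaphysis (3 mm noncritical or
17 mm critical defect), and a fusiform external bridging callus whose
radiodensity is highest at its proximal/distal extents and lowest at the
fracture line. Simulated physical torsion tests drive the same finite
element pipeline with a chosen "true" material model and wrap the resulting
rigidity in a noisy linear torque-angle record, closing the loop between
virtual and (synthetic) physical measurements.

All randomness flows through one seeded generator per call, so cohorts and
measurement curves are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomech, imaging, pipeline
from .imaging import UNITS_MGHA, DensityVolume
from .materials import DualZoneModel

__all__ = [
    "PhantomSpec",
    "Specimen",
    "TorqueAngleCurve",
    "generate_intact_phantom",
    "generate_osteotomy_phantom",
    "generate_cohort",
    "simulate_physical_torsion",
    "simulate_cohort_measurements",
    "write_cohort",
    "read_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric and density parameters of a synthetic osteotomized bone.

    Lengths in mm, densities in mgHA/cm**3, voxel spacing in um. The default
    geometry is a desk-scale diaphysis segment; the defect models of
    interest use ``gap_width`` 3 (noncritical) or 17 (critical, grafted).
    """

    bone_length: float = 24.0
    outer_radius: float = 3.5
    cortical_thickness: float = 1.5
    gap_width: float = 3.0
    callus_max_radius: float = 5.5
    callus_axial_extent: float = 10.0
    cortical_density_mean: float = 1100.0
    cortical_density_sd: float = 40.0
    callus_peak_density: float = 800.0
    callus_gap_density: float = 300.0
    soft_background_density: float = 30.0
    voxel_spacing: float = 1000.0  # um
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.cortical_thickness < self.outer_radius:
            raise ValueError("cortical_thickness must be smaller than outer_radius")
        if not self.gap_width < self.bone_length:
            raise ValueError("gap_width must be smaller than bone_length")
        if self.callus_gap_density > self.callus_peak_density:
            raise ValueError("callus_gap_density cannot exceed callus_peak_density")
        for name in (
            "cortical_density_mean",
            "callus_peak_density",
            "callus_gap_density",
            "soft_background_density",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.cortical_density_sd < 0:
            raise ValueError("cortical_density_sd must be non-negative")
        if not self.voxel_spacing > 0:
            raise ValueError("voxel_spacing must be positive")


@dataclass
class Specimen:
    """One (synthetic) animal limb: a density volume plus test metadata."""

    id: str
    dataset_label: int  # experimental dataset 1, 2 or 3
    limb_state: str  # "intact" | "operated"
    volume: DensityVolume
    measured_gj: float | None = None  # N*m**2/degree, absent until simulated
    gauge_length: float | None = None  # mm
    spec: PhantomSpec | None = None
    _mesh_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.dataset_label not in (1, 2, 3):
            raise ValueError("dataset_label must be 1, 2 or 3")
        if self.limb_state not in ("intact", "operated"):
            raise ValueError("limb_state must be 'intact' or 'operated'")

    def mesh(self, threshold: float = pipeline.DEFAULT_SEGMENTATION_THRESHOLD, wrap: bool = False):
        """Segment + mesh the volume, memoized per (threshold, wrap)."""
        key = (float(threshold), bool(wrap))
        if key not in self._mesh_cache:
            self._mesh_cache[key] = pipeline.build_mesh(self.volume, threshold, wrap)
        return self._mesh_cache[key]

    def torsion_result(self, model: DualZoneModel, threshold: float = pipeline.DEFAULT_SEGMENTATION_THRESHOLD):
        """Virtual torsion test under ``model``, memoized per model+threshold."""
        key = (
            "vtr",
            float(threshold),
            model.law.a,
            model.law.b,
            model.law.density_units,
            model.e_sc,
            model.rho_cut,
            model.poisson,
        )
        if key not in self._mesh_cache:
            self._mesh_cache[key] = pipeline.virtual_torsion_test(self.mesh(threshold), model)
        return self._mesh_cache[key]


@dataclass
class TorqueAngleCurve:
    """A (simulated) physical torsion-test record."""

    angle: np.ndarray  # degrees, strictly increasing
    torque: np.ndarray  # N*m
    gauge_length: float  # mm

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=np.float64)
        self.torque = np.asarray(self.torque, dtype=np.float64)
        if self.angle.shape != self.torque.shape:
            raise ValueError("angle and torque arrays must have the same length")
        if np.any(np.diff(self.angle) <= 0):
            raise ValueError("angle samples must be strictly increasing")
        if not self.gauge_length > 0:
            raise ValueError("gauge_length must be positive")


# ------------------------------------------------------------ volume builders

def _grid(spec: PhantomSpec):
    """Voxel-centre coordinate grids; z is the bone's long axis."""
    h = spec.voxel_spacing / 1000.0  # mm
    margin = 2  # voxels of soft background around the callus
    n_xy = int(np.ceil(2.0 * spec.callus_max_radius / h)) + 2 * margin
    n_z = int(round(spec.bone_length / h))
    cx = cy = n_xy * h / 2.0
    x = (np.arange(n_xy) + 0.5) * h - cx
    y = (np.arange(n_xy) + 0.5) * h - cy
    z = (np.arange(n_z) + 0.5) * h
    r = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)  # (nx, ny)
    return h, r, z, (n_xy, n_xy, n_z)


def _add_noise(data, mask, sd, rng):
    if sd > 0 and mask.any():
        data[mask] += rng.normal(0.0, sd, size=int(mask.sum()))
    np.maximum(data, 0.0, out=data)


def generate_intact_phantom(spec: PhantomSpec) -> DensityVolume:
    """Hollow-cylinder cortex on a soft background (an intact diaphysis).

    Gaussian per-voxel noise (truncated at zero) with the cortical mean/sd
    is applied to cortex voxels; deterministic for a given ``rng_seed``.
    """
    if spec.gap_width > 0:
        raise ValueError(
            "intact phantom requested but gap_width > 0; use "
            "generate_osteotomy_phantom or set gap_width=0"
        )
    h, r, z, shape = _grid(spec)
    data = np.full(shape, spec.soft_background_density, dtype=np.float64)
    ri = spec.outer_radius - spec.cortical_thickness
    cortex_xy = (r >= ri) & (r <= spec.outer_radius)
    cortex = np.broadcast_to(cortex_xy[:, :, None], shape).copy()
    data[cortex] = spec.cortical_density_mean
    rng = np.random.default_rng(spec.rng_seed)
    _add_noise(data, cortex, spec.cortical_density_sd, rng)
    return DensityVolume(data, spec.voxel_spacing, UNITS_MGHA)


def callus_axial_profile(spec: PhantomSpec, dz: np.ndarray) -> np.ndarray:
    """Callus density vs signed distance from the fracture plane (mm).

    Linear grading from the gap value at the fracture line up to the peak
    value at each callus extremity — the simplest profile consistent with
    a callus that is most mineralized away from the fracture line.
    """
    frac = np.clip(2.0 * np.abs(dz) / spec.callus_axial_extent, 0.0, 1.0)
    return spec.callus_gap_density + (
        spec.callus_peak_density - spec.callus_gap_density
    ) * frac


def callus_outer_radius(spec: PhantomSpec, dz: np.ndarray) -> np.ndarray:
    """Fusiform (cosine-tapered) callus radius vs distance from the fracture."""
    inside = np.abs(dz) <= spec.callus_axial_extent / 2.0
    taper = np.cos(np.pi * dz / spec.callus_axial_extent)
    return np.where(
        inside,
        spec.outer_radius + (spec.callus_max_radius - spec.outer_radius) * taper,
        spec.outer_radius,
    )


def generate_osteotomy_phantom(spec: PhantomSpec) -> DensityVolume:
    """Osteotomized phantom: interrupted cortex, soft gap plug, graded callus.

    The cortex is removed over a transverse gap centred at mid-diaphysis and
    replaced by tissue at the (soft) gap density; a fusiform external callus
    bridges the gap with an axial density profile that is lowest at the
    fracture line and peaks at the callus extents.
    """
    if not spec.gap_width > 0:
        raise ValueError("osteotomy phantom requires gap_width > 0")
    if spec.callus_axial_extent < spec.gap_width:
        raise ValueError("callus_axial_extent must cover at least the gap width")
    h, r, z, shape = _grid(spec)
    data = np.full(shape, spec.soft_background_density, dtype=np.float64)
    ri = spec.outer_radius - spec.cortical_thickness
    z_mid = spec.bone_length / 2.0
    dz = z - z_mid  # (nz,)
    in_gap = np.abs(dz) < spec.gap_width / 2.0  # (nz,)

    annulus_xy = (r >= ri) & (r <= spec.outer_radius)
    cortex = annulus_xy[:, :, None] & ~in_gap[None, None, :]
    data[cortex] = spec.cortical_density_mean

    # soft-tissue plug where the cortex was removed
    plug = annulus_xy[:, :, None] & in_gap[None, None, :]
    data[plug] = spec.callus_gap_density

    # external fusiform callus, axially graded
    r_callus = callus_outer_radius(spec, dz)  # (nz,)
    callus = (r[:, :, None] > spec.outer_radius) & (r[:, :, None] <= r_callus[None, None, :])
    profile = np.broadcast_to(callus_axial_profile(spec, dz)[None, None, :], shape)
    data[callus] = profile[callus]

    rng = np.random.default_rng(spec.rng_seed)
    tissue = cortex | plug | callus
    _add_noise(data, tissue, spec.cortical_density_sd, rng)
    return DensityVolume(data, spec.voxel_spacing, UNITS_MGHA)


# ------------------------------------------------------------------- cohorts

# geometric/density fields jittered per specimen by generate_cohort
_JITTERED_FIELDS = (
    "outer_radius",
    "cortical_thickness",
    "callus_max_radius",
    "cortical_density_mean",
    "callus_peak_density",
    "callus_gap_density",
)

#: defect width (mm) per experimental dataset: two 3-mm noncritical models
#: and one 17-mm critical (grafted) model
DATASET_GAP_MM = {1: 3.0, 2: 3.0, 3: 17.0}


def generate_cohort(
    n_per_dataset: tuple[int, int, int],
    spec_template: PhantomSpec,
    variation: float = 0.05,
    seed: int = 0,
) -> list[Specimen]:
    """Draw an operated cohort around a template phantom.

    ``n_per_dataset`` gives the specimen count for experimental datasets
    1-3; datasets 1 and 2 carry the template (3 mm class) gap and dataset 3
    the 17 mm critical defect. ``variation`` is the fractional standard
    deviation of multiplicative Gaussian jitter applied to geometry and
    density parameters. Reproducible by ``seed``.
    """
    if variation < 0:
        raise ValueError("variation must be non-negative")
    counts = tuple(int(n) for n in n_per_dataset)
    if len(counts) != 3 or any(n < 0 for n in counts) or sum(counts) < 1:
        raise ValueError("n_per_dataset must be three non-negative counts, total >= 1")
    rng = np.random.default_rng(seed)
    # extra callus reach beyond the gap, preserved across defect widths
    extent_margin = spec_template.callus_axial_extent - spec_template.gap_width
    specimens: list[Specimen] = []
    for label, n in zip((1, 2, 3), counts):
        gap = DATASET_GAP_MM[label] if label == 3 else spec_template.gap_width
        for k in range(n):
            params = {f: getattr(spec_template, f) for f in _JITTERED_FIELDS}
            if variation > 0:
                for f in params:
                    params[f] *= max(0.1, 1.0 + variation * rng.normal())
            params["cortical_thickness"] = min(
                params["cortical_thickness"], 0.8 * params["outer_radius"]
            )
            params["callus_max_radius"] = max(
                params["callus_max_radius"], 1.1 * params["outer_radius"]
            )
            params["callus_gap_density"] = min(
                params["callus_gap_density"], params["callus_peak_density"]
            )
            bone_length = spec_template.bone_length + max(0.0, gap - spec_template.gap_width)
            spec = PhantomSpec(
                bone_length=bone_length,
                gap_width=gap,
                callus_axial_extent=gap + extent_margin,
                cortical_density_sd=spec_template.cortical_density_sd,
                soft_background_density=spec_template.soft_background_density,
                voxel_spacing=spec_template.voxel_spacing,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
                **params,
            )
            specimens.append(
                Specimen(
                    id=f"D{label}-{k:02d}",
                    dataset_label=label,
                    limb_state="operated",
                    volume=generate_osteotomy_phantom(spec),
                    gauge_length=None,
                    spec=spec,
                )
            )
    return specimens


# ------------------------------------------------- simulated physical testing

def simulate_physical_torsion(
    specimen: Specimen,
    true_model: DualZoneModel,
    noise_cv: float = 0.0,
    seed: int = 0,
    threshold: float = pipeline.DEFAULT_SEGMENTATION_THRESHOLD,
    max_torque: float = 12.0,
    n_samples: int = 121,
) -> TorqueAngleCurve:
    """Synthesize a linear torque-angle record from a virtual torsion test.

    The specimen's FE rigidity under ``true_model`` defines the true slope;
    multiplicative Gaussian noise (coefficient of variation ``noise_cv``)
    perturbs the measured rigidity as a whole, mirroring how physical-test
    errors scale with specimen stiffness. The curve extends past the upper
    bound of the 6-10 N*m regression window.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    result = specimen.torsion_result(true_model, threshold)
    gauge_mm = result.gauge_length_m * 1000.0
    specimen.gauge_length = gauge_mm
    rng = np.random.default_rng(seed)
    rigidity = result.vtr * (1.0 + noise_cv * rng.normal())  # N*m**2/deg
    slope = rigidity / result.gauge_length_m  # N*m per degree
    max_angle = max_torque / slope
    angle = np.linspace(0.0, max_angle, n_samples)[1:]
    return TorqueAngleCurve(angle=angle, torque=slope * angle, gauge_length=gauge_mm)


def simulate_cohort_measurements(
    specimens: list[Specimen],
    true_model: DualZoneModel,
    noise_cv: float = 0.02,
    seed: int = 0,
    threshold: float = pipeline.DEFAULT_SEGMENTATION_THRESHOLD,
) -> list[TorqueAngleCurve]:
    """Simulate the physical test for a whole cohort and set ``measured_gj``.

    Each specimen gets an independent child seed; the measured rigidity is
    extracted from its curve through the same 6-10 N*m regression used for
    real torque-angle records.
    """
    curves = []
    child_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=len(specimens))
    for specimen, s in zip(specimens, child_seeds):
        curve = simulate_physical_torsion(
            specimen, true_model, noise_cv=noise_cv, seed=int(s), threshold=threshold
        )
        specimen.measured_gj = biomech.compute_gj(curve).gj
        curves.append(curve)
    return curves


# ------------------------------------------------------------------ disk I/O

def write_cohort(specimens, out_dir, curves=None) -> Path:
    """Write volumes (NIfTI), curves (CSV) and a manifest CSV; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sp in enumerate(specimens):
        vol_path = out / f"{sp.id}.nii"
        imaging.write_volume(sp.volume, vol_path)
        curve_path = ""
        if curves is not None and curves[i] is not None:
            curve_path = str(out / f"{sp.id}_curve.csv")
            pd.DataFrame(
                {"angle_deg": curves[i].angle, "torque_Nm": curves[i].torque}
            ).to_csv(curve_path, index=False)
        rows.append(
            {
                "id": sp.id,
                "dataset_label": sp.dataset_label,
                "limb_state": sp.limb_state,
                "gauge_length_mm": sp.gauge_length,
                "volume_path": str(vol_path),
                "curve_path": curve_path,
                "measured_gj": sp.measured_gj,
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path) -> list[Specimen]:
    df = pd.read_csv(manifest_path)
    specimens = []
    for _, row in df.iterrows():
        specimens.append(
            Specimen(
                id=str(row["id"]),
                dataset_label=int(row["dataset_label"]),
                limb_state=str(row["limb_state"]),
                volume=imaging.read_volume(row["volume_path"]),
                measured_gj=None if pd.isna(row["measured_gj"]) else float(row["measured_gj"]),
                gauge_length=None if pd.isna(row["gauge_length_mm"]) else float(row["gauge_length_mm"]),
            )
        )
    return specimens
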