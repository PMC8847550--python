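"""Image-to-rigidity glue: segmentation -> voxel mesh -> virtual torsion test."""

from __future__ import annotations

from . import fe, imaging, materials, meshing

__all__ = [
    "DEFAULT_SEGMENTATION_THRESHOLD",
    "build_mesh",
    "virtual_torsion_test",
]

#: Default calibrated-density threshold (mgHA/cm**3) separating bone+callus
#: from soft background. Chosen between the soft-tissue background and the
#: lowest callus densities of the synthetic phantoms; real scans expose it
#: as a required configuration value.
DEFAULT_SEGMENTATION_THRESHOLD = 150.0


def build_mesh(
    volume: imaging.DensityVolume,
    threshold: float = DEFAULT_SEGMENTATION_THRESHOLD,
    wrap: bool = False,
) -> meshing.FEMesh:
    """Segment a calibrated volume and convert it to a hex voxel mesh.

    ``wrap=True`` additionally applies the morphological close-and-wrap
    step. The default pipeline relies on threshold + largest-component
    segmentation alone, which keeps every meshed voxel at or above the
    threshold density.
    """
    mask = imaging.segment_bone(volume, threshold)
    if wrap:
        mask = imaging.close_and_wrap(mask)
    return meshing.voxels_to_hex_mesh(mask, volume)


def virtual_torsion_test(
    mesh: meshing.FEMesh,
    model: materials.DualZoneModel,
    solver_tol: float = 1e-8,
) -> fe.TorsionResult:
    """Assign the material model and run the 1-degree virtual torsion test."""
    return fe.solve_torsion(materials.assign_materials(mesh, model), solver_tol=solver_tol)
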