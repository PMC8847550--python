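"""Voxel-to-hexahedron meshing and VTK unstructured-grid I/O.

One trilinear 8-node hexahedron is emitted per segmented voxel, with the
voxel's calibrated radiodensity carried as cell data — the standard micro-FE
construction. Node coordinates are in millimetres. Meshes round-trip through
ASCII ``.vtu`` files (VTK XML unstructured grid) with the cell-data arrays
``density_mgHA_cm3``, ``E_MPa`` and ``vm_strain``.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, replace

import numpy as np
from skimage import measure

from .imaging import BinaryMask, DensityVolume

__all__ = ["FEMesh", "voxels_to_hex_mesh", "write_vtu", "read_vtu"]

VTK_HEXAHEDRON = 12

# corner offsets in VTK hexahedron order (bottom face CCW, then top face)
_CORNERS = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 0, 1],
        [1, 1, 1],
        [0, 1, 1],
    ],
    dtype=np.int64,
)


@dataclass
class FEMesh:
    """Hexahedral mesh with per-element density and (optionally) modulus."""

    node_coords: np.ndarray  # (n_nodes, 3), mm
    elements: np.ndarray  # (n_elements, 8) int node indices, VTK order
    element_density: np.ndarray | None = None  # mgHA/cm3
    element_modulus: np.ndarray | None = None  # MPa
    poisson: float | None = None
    spacing_mm: float | None = None  # voxel pitch for voxel meshes

    def __post_init__(self) -> None:
        self.node_coords = np.asarray(self.node_coords, dtype=np.float64)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.node_coords.ndim != 2 or self.node_coords.shape[1] != 3:
            raise ValueError("node_coords must be (n, 3)")
        if self.elements.ndim != 2 or self.elements.shape[1] != 8:
            raise ValueError("elements must be (m, 8) hexahedra")
        if self.elements.size:
            if self.elements.min() < 0 or self.elements.max() >= len(self.node_coords):
                raise ValueError("element connectivity references missing nodes")
        if self.element_density is not None:
            self.element_density = np.asarray(self.element_density, dtype=np.float64)
            if len(self.element_density) != len(self.elements):
                raise ValueError("element_density length != number of elements")
            if np.any(self.element_density < 0):
                raise ValueError("element densities must be non-negative")
        if self.element_modulus is not None:
            self.element_modulus = np.asarray(self.element_modulus, dtype=np.float64)
            if len(self.element_modulus) != len(self.elements):
                raise ValueError("element_modulus length != number of elements")

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def with_materials(self, modulus: np.ndarray, poisson: float) -> "FEMesh":
        return replace(self, element_modulus=np.asarray(modulus, float), poisson=poisson)

    def total_volume_mm3(self) -> float:
        if self.spacing_mm is None:
            raise ValueError("total_volume_mm3 requires a voxel mesh with spacing")
        return self.n_elements * self.spacing_mm**3


def voxels_to_hex_mesh(mask: BinaryMask, volume: DensityVolume) -> FEMesh:
    """Build one hex element per true voxel, sharing deduplicated nodes.

    The mask and volume must share the voxel grid; the mask must form a
    single node-connected component (a disconnected mask would make the
    torsion boundary-value problem singular).
    """
    if mask.data.shape != volume.data.shape:
        raise ValueError("mask and volume do not share a grid")
    if mask.spacing != volume.spacing:
        raise ValueError("mask and volume spacing differ")
    if not mask.data.any():
        raise ValueError("empty mask")
    n_comp = measure.label(mask.data, connectivity=3).max()
    if n_comp != 1:
        raise ValueError(
            f"mask has {n_comp} connected components; the torsion problem "
            "requires a single connected domain"
        )

    idx = np.argwhere(mask.data)  # (m, 3) voxel indices
    shape = mask.data.shape
    ny1, nz1 = shape[1] + 1, shape[2] + 1

    # lattice node ids for the 8 corners of every voxel
    corners = idx[:, None, :] + _CORNERS[None, :, :]  # (m, 8, 3)
    lin = (corners[..., 0] * ny1 + corners[..., 1]) * nz1 + corners[..., 2]
    used, elements = np.unique(lin, return_inverse=True)
    elements = elements.reshape(len(idx), 8)

    k = used % nz1
    j = (used // nz1) % ny1
    i = used // (nz1 * ny1)
    h = volume.spacing_mm
    coords = np.stack([i, j, k], axis=1).astype(np.float64) * h
    coords += np.asarray(volume.origin, dtype=np.float64)

    density = volume.data[mask.data.nonzero()]
    return FEMesh(
        node_coords=coords,
        elements=elements,
        element_density=np.maximum(density, 0.0),
        spacing_mm=h,
    )


# ------------------------------------------------------------------ VTU I/O
#
# Minimal ASCII VTK-XML unstructured-grid support (hexahedra only), written
# directly because the pipeline only ever needs this one cell type and a
# handful of float cell-data arrays.


def _data_array(parent, name, arr, n_components=None):
    da = ET.SubElement(parent, "DataArray")
    arr = np.asarray(arr)
    da.set("type", "Int64" if np.issubdtype(arr.dtype, np.integer) else "Float64")
    if name:
        da.set("Name", name)
    if n_components:
        da.set("NumberOfComponents", str(n_components))
    da.set("format", "ascii")
    flat = arr.ravel()
    if np.issubdtype(arr.dtype, np.integer):
        da.text = " ".join(str(v) for v in flat)
    else:
        da.text = " ".join(repr(float(v)) for v in flat)
    return da


def write_vtu(mesh: FEMesh, path, cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write a mesh (plus optional extra cell-data arrays) as ASCII .vtu."""
    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(
        grid,
        "Piece",
        NumberOfPoints=str(mesh.n_nodes),
        NumberOfCells=str(mesh.n_elements),
    )
    pts = ET.SubElement(piece, "Points")
    _data_array(pts, "Points", mesh.node_coords, n_components=3)
    cells = ET.SubElement(piece, "Cells")
    _data_array(cells, "connectivity", mesh.elements.astype(np.int64))
    _data_array(
        cells, "offsets", (np.arange(1, mesh.n_elements + 1) * 8).astype(np.int64)
    )
    _data_array(
        cells, "types", np.full(mesh.n_elements, VTK_HEXAHEDRON, dtype=np.int64)
    )
    cdata = ET.SubElement(piece, "CellData")
    arrays: dict[str, np.ndarray] = {}
    if mesh.element_density is not None:
        arrays["density_mgHA_cm3"] = mesh.element_density
    if mesh.element_modulus is not None:
        arrays["E_MPa"] = mesh.element_modulus
    if cell_data:
        arrays.update(cell_data)
    for name, arr in arrays.items():
        _data_array(cdata, name, np.asarray(arr, dtype=np.float64))
    ET.ElementTree(root).write(str(path), xml_declaration=True)


def _parse_array(da: ET.Element) -> np.ndarray:
    text = da.text or ""
    dtype = np.int64 if da.get("type", "").startswith("Int") else np.float64
    return np.array(text.split(), dtype=np.float64).astype(dtype)


def read_vtu(path) -> FEMesh:
    """Read an ASCII .vtu written by :func:`write_vtu` (hexahedra only)."""
    tree = ET.parse(str(path))
    piece = tree.getroot().find("./UnstructuredGrid/Piece")
    if piece is None:
        raise ValueError("malformed .vtu: no UnstructuredGrid/Piece")
    pts_da = piece.find("./Points/DataArray")
    coords = _parse_array(pts_da).reshape(-1, 3)
    cell_arrays = {
        da.get("Name"): da for da in piece.findall("./Cells/DataArray")
    }
    types = _parse_array(cell_arrays["types"])
    if np.any(types != VTK_HEXAHEDRON):
        bad = sorted(set(int(t) for t in types if t != VTK_HEXAHEDRON))
        raise ValueError(f"unsupported cell types {bad}: only hexahedra (12)")
    conn = _parse_array(cell_arrays["connectivity"]).astype(np.int64).reshape(-1, 8)
    density = modulus = None
    cdata = piece.find("./CellData")
    if cdata is not None:
        for da in cdata.findall("./DataArray"):
            if da.get("Name") == "density_mgHA_cm3":
                density = _parse_array(da)
            elif da.get("Name") == "E_MPa":
                modulus = _parse_array(da)
    return FEMesh(
        node_coords=coords,
        elements=conn,
        element_density=density,
        element_modulus=modulus,
    )
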