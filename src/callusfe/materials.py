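"""Density-modulus material laws and elementwise property assignment.

Two constitutive models are provided:

* the single-zone law ``E = a * rho**b``, with the ovine cortical-bone
  calibration a = 10225, b = 1.0 (a applying to density expressed in
  gHA/cm**3, i.e. E[MPa] = 10.225 * rho[mgHA/cm**3]), and
* the dual-zone (piecewise) callus law, which assigns a constant soft-callus
  modulus ``E_sc`` wherever the calibrated radiodensity falls below a cutoff
  ``rho_cut`` and the bone scaling law at or above it.

The dual-zone law degenerates exactly to the single-zone law at
``rho_cut = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MaterialLaw",
    "DualZoneModel",
    "OVINE_LAW",
    "E_SC_CANDIDATES_MPA",
    "modulus_single",
    "modulus_dual",
    "assign_materials",
]

#: Candidate soft-callus moduli spanning the literature range for fibrous
#: and cartilaginous repair tissue, on a logarithmic grid (MPa).
E_SC_CANDIDATES_MPA = (0.5, 5.0, 50.0, 500.0)

#: Floor modulus (MPa) for zero-density elements inside the meshed domain;
#: keeps the stiffness matrix positive definite, four orders of magnitude
#: below the smallest candidate E_sc so it cannot influence results.
MODULUS_FLOOR_MPA = 0.01


@dataclass(frozen=True)
class MaterialLaw:
    """Power law E = a * rho**b mapping radiodensity to Young's modulus.

    ``density_units`` names the units in which rho must be expressed before
    applying (a, b); densities handled by the pipeline are in mgHA/cm**3 and
    are converted internally.
    """

    a: float  # MPa per (density_units)**b
    b: float  # dimensionless exponent
    density_units: str = "gHA/cm3"

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("law coefficient a must be positive")
        if not self.b > 0:
            raise ValueError("law exponent b must be positive")
        if self.density_units not in ("gHA/cm3", "mgHA/cm3"):
            raise ValueError(f"unsupported density units {self.density_units!r}")

    def density_scale(self) -> float:
        """Factor converting mgHA/cm**3 into the law's native units."""
        return 1e-3 if self.density_units == "gHA/cm3" else 1.0


#: Ovine cortical-bone calibration: E = 10225 * rho**1.0 with rho in gHA/cm**3
#: (equivalently 10.225 MPa per mgHA/cm**3), giving ~10-20 GPa at cortical
#: densities.
OVINE_LAW = MaterialLaw(a=10225.0, b=1.0, density_units="gHA/cm3")


@dataclass(frozen=True)
class DualZoneModel:
    """Piecewise callus law: E_sc below rho_cut, bone scaling law at/above it."""

    law: MaterialLaw = OVINE_LAW
    e_sc: float = 50.0  # MPa
    rho_cut: float = 0.0  # mgHA/cm3
    poisson: float = 0.3

    def __post_init__(self) -> None:
        if not self.e_sc > 0:
            raise ValueError("E_sc must be positive")
        if self.rho_cut < 0:
            raise ValueError("rho_cut must be non-negative")
        if not 0.0 < self.poisson < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")

    def single_zone(self) -> "DualZoneModel":
        return replace(self, rho_cut=0.0)


def modulus_single(rho_qct, law: MaterialLaw = OVINE_LAW):
    """Single-zone modulus E = a * rho**b, rho in mgHA/cm**3, E in MPa."""
    rho = np.asarray(rho_qct, dtype=np.float64)
    if np.any(rho < 0):
        raise ValueError("density must be non-negative")
    e = law.a * (rho * law.density_scale()) ** law.b
    return float(e) if np.isscalar(rho_qct) else e


def modulus_dual(rho_qct, model: DualZoneModel):
    """Dual-zone modulus; the boundary rho == rho_cut takes the bone branch."""
    rho = np.asarray(rho_qct, dtype=np.float64)
    e_bone = modulus_single(rho, model.law)
    e = np.where(rho < model.rho_cut, model.e_sc, e_bone)
    return float(e) if np.isscalar(rho_qct) else e


def assign_materials(mesh, model: DualZoneModel):
    """Set elementwise moduli on a mesh from its element densities.

    Bone-branch elements get ``max(E_law, floor)`` so near-zero-density
    voxels inside the wrapped domain cannot make the system singular; the
    floor is far below every candidate E_sc. Returns a new mesh; the input
    is not modified.
    """
    if mesh.element_density is None:
        raise ValueError("mesh has no element_density field")
    rho = np.asarray(mesh.element_density, dtype=np.float64)
    e_bone = np.maximum(modulus_single(rho, model.law), MODULUS_FLOOR_MPA)
    e = np.where(rho < model.rho_cut, model.e_sc, e_bone)
    return mesh.with_materials(e, model.poisson)
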