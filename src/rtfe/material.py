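"""Density → elasticity mapping and the per-voxel material model.

Mineralised tissue is mapped onto a discrete ladder of isotropic Young's
moduli: densities from 395 to 720 mg HA/cm³ in 25 mg HA/cm³ steps map
linearly onto 4.045–12.170 GPa (14 levels). Everything below the bone
threshold is soft tissue at 0.003 GPa, and the medullary cavity at the
loaded end of the mesh is capped with a stiff 20 GPa plate so that soft
tissue on the top slice does not create spurious edge compliance.

Internally the package works in mm / MPa / N (so stress × area gives N
directly); moduli are expressed in GPa at the interfaces of this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from skimage.morphology import convex_hull_image

from .errors import InvalidInputError, InvalidSpecError
from .volio import DensityVolume

#: Integer role labels stored per voxel.
ROLE_SOFT = 0
ROLE_BONE = 1
ROLE_CAP = 2

ROLE_NAMES = {ROLE_SOFT: "soft", ROLE_BONE: "bone", ROLE_CAP: "cap"}


@dataclass(frozen=True)
class MaterialModel:
    """The multi-density material ladder plus soft-tissue and cap moduli.

    Densities are quantised downward onto the ladder (395–419.99 → level 0
    and so on); densities at or above ``rho_max`` clamp to the top level.
    The per-level increment is ``(E_max - E_min)/13`` = 0.625 GPa exactly.
    """

    rho_min: float = 395.0  # mg HA/cm³, lowest bone density level
    rho_max: float = 720.0  # mg HA/cm³, highest level (clamp above)
    rho_step: float = 25.0  # mg HA/cm³ ladder spacing
    e_min_gpa: float = 4.045  # GPa at rho_min
    e_max_gpa: float = 12.170  # GPa at rho_max
    e_soft_gpa: float = 0.003  # GPa for sub-threshold (soft) tissue
    e_cap_gpa: float = 20.0  # GPa for the marrow cap plate
    poisson: float = 0.3  # single Poisson ratio for all materials

    def __post_init__(self) -> None:
        n = (self.rho_max - self.rho_min) / self.rho_step
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise InvalidSpecError(
                "(rho_max - rho_min) must be a positive multiple of rho_step"
            )
        if not (self.e_soft_gpa < self.e_min_gpa < self.e_max_gpa < self.e_cap_gpa):
            raise InvalidSpecError("moduli must satisfy E_soft < E_min < E_max < E_cap")
        if not 0 < self.poisson < 0.5:
            raise InvalidSpecError(f"Poisson ratio must lie in (0, 0.5), got {self.poisson}")

    @property
    def n_steps(self) -> int:
        """Number of ladder intervals (levels = n_steps + 1)."""
        return round((self.rho_max - self.rho_min) / self.rho_step)

    @property
    def e_step_gpa(self) -> float:
        """Modulus increment per ladder level, GPa."""
        return (self.e_max_gpa - self.e_min_gpa) / self.n_steps

    def ladder_gpa(self) -> np.ndarray:
        """All bone modulus levels in GPa, ascending."""
        return self.e_min_gpa + self.e_step_gpa * np.arange(self.n_steps + 1)


def density_to_modulus(
    density: float | np.ndarray, model: MaterialModel | None = None
) -> tuple[np.ndarray | float, np.ndarray | int]:
    """Map density (mg HA/cm³) to Young's modulus (GPa) and role label.

    Scalar in → scalar out; arrays are mapped element-wise. Densities below
    the 395 mg HA/cm³ bone threshold are soft tissue; the rest are quantised
    down onto the 14-level ladder, clamping above 720 mg HA/cm³.
    """
    model = model or MaterialModel()
    rho = np.asarray(density, dtype=np.float64)
    if not np.isfinite(rho).all() or (rho < 0).any():
        raise InvalidInputError("densities must be finite and non-negative")
    level = np.floor((rho - model.rho_min) / model.rho_step).astype(np.int64)
    level = np.clip(level, 0, model.n_steps)
    modulus = model.e_min_gpa + model.e_step_gpa * level
    soft = rho < model.rho_min
    modulus = np.where(soft, model.e_soft_gpa, modulus)
    role = np.where(soft, ROLE_SOFT, ROLE_BONE)
    if np.isscalar(density) or np.ndim(density) == 0:
        return float(modulus), int(role)
    return modulus, role.astype(np.uint8)


@dataclass
class MaterialVolume:
    """Per-voxel Young's modulus (GPa) and role labels on the density grid."""

    modulus_gpa: np.ndarray
    role: np.ndarray  # uint8, ROLE_SOFT / ROLE_BONE / ROLE_CAP
    voxel_size: float  # mm
    poisson: float
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.modulus_gpa.shape)  # type: ignore[return-value]

    @property
    def modulus_mpa(self) -> np.ndarray:
        """Moduli in the internal mm/MPa/N unit system."""
        return self.modulus_gpa * 1000.0

    def bone_volume_mm3(self) -> float:
        """Bone voxel count × voxel volume; the BV used for BV/BV0 curves."""
        return float(np.count_nonzero(self.role == ROLE_BONE)) * self.voxel_size**3


def add_marrow_cap(matvol: MaterialVolume, model: MaterialModel | None = None,
                   both_ends: bool = False) -> MaterialVolume:
    """Cap the medullary cavity on the top (loaded) axial slice.

    Soft voxels on the top slice that lie inside the transverse convex hull
    of that slice's bone are relabelled ``cap`` at 20 GPa. Cap voxels are
    excluded from every strain-analysis mask. ``both_ends`` also caps the
    bottom slice.
    """
    model = model or MaterialModel()
    if matvol.shape[2] < 3:
        raise InvalidInputError("marrow cap requires at least 3 axial slices")
    slices = [-1, 0] if both_ends else [-1]
    for zs in slices:
        bone2d = matvol.role[:, :, zs] == ROLE_BONE
        if not bone2d.any():
            continue
        hull = convex_hull_image(bone2d)
        cap2d = hull & (matvol.role[:, :, zs] == ROLE_SOFT)
        matvol.role[:, :, zs][cap2d] = ROLE_CAP
        matvol.modulus_gpa[:, :, zs][cap2d] = model.e_cap_gpa
    matvol.metadata.setdefault("marrow_cap", {"both_ends": both_ends})
    return matvol


def build_material_volume(
    vol: DensityVolume, model: MaterialModel | None = None, cap: bool = True
) -> MaterialVolume:
    """Voxel-wise density→modulus mapping followed by marrow capping."""
    model = model or MaterialModel()
    modulus, role = density_to_modulus(vol.values, model)
    matvol = MaterialVolume(
        modulus_gpa=np.asarray(modulus, dtype=np.float64),
        role=np.asarray(role, dtype=np.uint8),
        voxel_size=vol.voxel_size,
        poisson=model.poisson,
        metadata={
            "material_model": {
                "rho_min": model.rho_min,
                "rho_max": model.rho_max,
                "rho_step": model.rho_step,
                "e_min_gpa": model.e_min_gpa,
                "e_max_gpa": model.e_max_gpa,
                "e_soft_gpa": model.e_soft_gpa,
                "e_cap_gpa": model.e_cap_gpa,
                "poisson": model.poisson,
            },
            **vol.metadata,
        },
    )
    if cap:
        add_marrow_cap(matvol, model)
    return matvol


def bone_mask(matvol: MaterialVolume) -> np.ndarray:
    """Boolean mask of bone voxels; soft tissue and the marrow cap are
    excluded from all strain analysis."""
    return matvol.role == ROLE_BONE
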