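"""Density-volume container, file I/O and image preprocessing.

A :class:`DensityVolume` holds a 3-D grid of volumetric bone mineral density
in mg HA/cm³ on an isotropic voxel grid. The internal axis convention is
``(x, y, z)`` with the **last axis axial**, i.e. the loading direction of the
femoral segment. File readers normalise external axis orders to this
convention.

Preprocessing mirrors the standard micro-CT micro-FE pipeline: crop to the
region between the fixation screws, trim registration-damaged end slices,
and Gaussian-filter the density field before material mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import SimpleITK as sitk
import tifffile
from scipy import ndimage

from .errors import (
    FormatError,
    InvalidInputError,
    InvalidSpecError,
    InvalidTrimError,
    OutOfBoundsError,
    UnsupportedGeometryError,
)

#: Relative tolerance used when deciding whether voxel spacing is isotropic.
_ISOTROPY_RTOL = 1e-4


@dataclass
class DensityVolume:
    """3-D mineral-density image (mg HA/cm³) with isotropic voxel size.

    Parameters
    ----------
    values
        Density array, shape ``(nx, ny, nz)``; the last axis is the axial
        (loading) direction.
    voxel_size
        Isotropic voxel edge length in mm.
    metadata
        Free-form provenance: scan settings, time-point label, registration
        flag, preprocessing history.
    """

    values: np.ndarray
    voxel_size: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise InvalidInputError(
                f"density volume must be 3-D, got ndim={self.values.ndim}"
            )
        if self.values.shape[2] < 2:
            raise InvalidInputError("axial slice count must be >= 2")
        if not np.isfinite(self.values).all():
            raise InvalidInputError("density values must be finite")
        if not self.voxel_size > 0:
            raise InvalidInputError(f"voxel size must be > 0, got {self.voxel_size}")
        # negative densities are clamped, not rejected: filtering / synthesis
        # may produce small negative excursions that are physically zero
        np.clip(self.values, 0.0, None, out=self.values)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]

    def with_values(self, values: np.ndarray, **meta: Any) -> "DensityVolume":
        """Return a copy carrying ``values`` and extra metadata entries."""
        md = dict(self.metadata)
        md.update(meta)
        return DensityVolume(np.asarray(values), self.voxel_size, md)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_SITK_SUFFIXES = {".mhd", ".mha", ".nii", ".gz"}


def _is_tiff(path: Path) -> bool:
    return path.suffix.lower() in {".tif", ".tiff"}


def write_volume(vol: DensityVolume, path: str | Path) -> Path:
    """Write a volume as MetaImage (.mhd/.mha), NIfTI (.nii/.nii.gz) or TIFF.

    The format is chosen from the file suffix. TIFF carries no spacing, so a
    JSON sidecar ``<path>.json`` records the voxel size and metadata.
    """
    path = Path(path)
    if _is_tiff(path):
        # tifffile expects (pages, rows, cols) = (z, y, x)
        tifffile.imwrite(path, np.ascontiguousarray(vol.values.T.astype(np.float32)))
        sidecar = {"voxel_size_mm": vol.voxel_size, "metadata": _json_safe(vol.metadata)}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
        return path
    img = sitk.GetImageFromArray(vol.values.T)  # sitk arrays are (z, y, x)
    img.SetSpacing((vol.voxel_size,) * 3)
    sitk.WriteImage(img, str(path))
    return path


def read_volume(
    path: str | Path,
    format_hint: str | None = None,
    voxel_size: float | None = None,
) -> DensityVolume:
    """Read a density volume from MetaImage, NIfTI or a TIFF stack.

    Voxel size comes from the file header; for TIFF it is read from the JSON
    sidecar written by :func:`write_volume`, or must be given explicitly.
    Anisotropic spacing is rejected because the voxel FE mesh requires cubic
    elements.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    hint = (format_hint or "").lower()
    if hint == "tiff" or (not hint and _is_tiff(path)):
        data = np.asarray(tifffile.imread(path), dtype=np.float64)
        meta: dict[str, Any] = {}
        if voxel_size is None:
            sidecar = path.with_suffix(path.suffix + ".json")
            if not sidecar.exists():
                raise FormatError(
                    f"TIFF stack {path} has no voxel size: pass voxel_size= or "
                    "provide the JSON sidecar"
                )
            payload = json.loads(sidecar.read_text())
            voxel_size = float(payload["voxel_size_mm"])
            meta = dict(payload.get("metadata", {}))
        return DensityVolume(data.T, voxel_size, meta)

    if hint not in ("", "mhd", "metaimage", "nifti", "nii"):
        raise FormatError(f"unknown format hint {format_hint!r}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # SimpleITK raises bare RuntimeError
        raise FormatError(f"could not parse {path} as an image volume: {exc}") from exc
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    if not np.allclose(spacing, spacing[0], rtol=_ISOTROPY_RTOL):
        raise UnsupportedGeometryError(
            f"voxel FE requires cubic voxels; {path} has spacing {tuple(spacing)}"
        )
    values = sitk.GetArrayFromImage(img).T  # (z,y,x) -> (x,y,z)
    return DensityVolume(np.asarray(values, dtype=np.float64), float(spacing[0]))


def _json_safe(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterSpec:
    """Gaussian filter parameters.

    ``sigma`` is the standard deviation in voxels; ``support`` the integer
    half-width at which the kernel is truncated (support = 1 gives a 3×3×3
    kernel). The truncated kernel is renormalised to unit sum, so constant
    fields are preserved exactly.
    """

    sigma: float = 1.2
    support: int = 1
    boundary: str = "reflect"  # scipy.ndimage mode for edge padding

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise InvalidSpecError(f"sigma must be > 0, got {self.sigma}")
        if int(self.support) != self.support or self.support < 1:
            raise InvalidSpecError(f"support must be an integer >= 1, got {self.support}")

    def kernel_1d(self) -> np.ndarray:
        """The normalised 1-D kernel over offsets -support..support."""
        x = np.arange(-self.support, self.support + 1, dtype=float)
        k = np.exp(-0.5 * (x / self.sigma) ** 2)
        return k / k.sum()


def crop_to_region(
    vol: DensityVolume, origin: tuple[int, int, int], shape: tuple[int, int, int]
) -> DensityVolume:
    """Crop to a box given by a 0-based ``origin`` corner and output ``shape``."""
    origin = tuple(int(o) for o in origin)
    shape = tuple(int(s) for s in shape)
    if any(s < 1 for s in shape):
        raise InvalidSpecError(f"crop shape must be positive, got {shape}")
    for o, s, n in zip(origin, shape, vol.shape):
        if o < 0 or o + s > n:
            raise OutOfBoundsError(
                f"crop origin={origin} shape={shape} exceeds volume shape {vol.shape}"
            )
    sl = tuple(slice(o, o + s) for o, s in zip(origin, shape))
    return vol.with_values(vol.values[sl], crop={"origin": origin, "shape": shape})


def trim_axial(vol: DensityVolume, n_top: int, n_bottom: int) -> DensityVolume:
    """Remove ``n_bottom`` slices from the start and ``n_top`` from the end of
    the axial axis (used to discard slices emptied by longitudinal
    registration)."""
    n_top, n_bottom = int(n_top), int(n_bottom)
    if n_top < 0 or n_bottom < 0:
        raise InvalidSpecError("trim counts must be non-negative")
    nz = vol.shape[2]
    if n_top + n_bottom >= nz:
        raise InvalidTrimError(
            f"trimming {n_bottom}+{n_top} slices consumes the {nz}-slice volume"
        )
    sl = slice(n_bottom, nz - n_top if n_top else None)
    return vol.with_values(vol.values[:, :, sl], trim={"top": n_top, "bottom": n_bottom})


def gaussian_filter(vol: DensityVolume, spec: FilterSpec | None = None) -> DensityVolume:
    """Smooth the density field with a truncated, renormalised Gaussian.

    Default parameters (σ = 1.2 voxels, support 1) reproduce the standard
    micro-CT preprocessing for this pipeline family; σ is in voxel units.
    """
    spec = spec or FilterSpec()
    # truncate at exactly `support` voxels: radius = int(truncate*sigma + 0.5)
    truncate = (spec.support + 0.49) / spec.sigma
    out = ndimage.gaussian_filter(
        vol.values, sigma=spec.sigma, truncate=truncate, mode=spec.boundary
    )
    return vol.with_values(
        out, gaussian={"sigma": spec.sigma, "support": spec.support}
    )
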