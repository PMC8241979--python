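"""Synthetic osteotomized-femur phantoms and longitudinal healing series.

These phantoms stand in for in vivo micro-CT scans of a femoral segment
between the fixation screws of an external fixator: a hollow cylindrical
cortex along the axial (z) axis, a transverse osteotomy gap, and a
mineralizing callus bridging the gap through thin struts. Densities are
generated directly in mg HA/cm³ (the scanner grayscale→density calibration
is scanner-specific and deliberately bypassed) with additive Gaussian noise
truncated at zero.

The desk-scale default grid is 48×48×60 voxels at 65.625 µm — the same
physical extent as a full 300×300×210 scan at 10.5 µm, coarsened 6.25×, so
that resultant forces and the ~10 N loading regime keep their physical
scale. Full-resolution specs are supported via :func:`full_scale_spec`.

All generators are deterministic: identical spec + seed gives a
bit-identical volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .errors import GenerationFailureError, InvalidSpecError
from .volio import DensityVolume

#: Bone threshold of the material ladder; phantom densities are placed
#: relative to this value (background well below, cortex/callus above).
BONE_THRESHOLD = 395.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, densities and noise of one osteotomy phantom.

    Lengths are in voxels; densities in mg HA/cm³. ``gap_width`` counts the
    axial slices with no cortex. Struts are cylindrical rods bridging the
    gap, their centres placed on the mid-wall circle at deterministic
    angular positions perturbed by seeded jitter.
    """

    shape: tuple[int, int, int] = (48, 48, 60)
    voxel_size: float = 0.065625  # mm; 10.5 µm × (300/48) keeps physical extent
    cortex_radius: float = 15.0  # outer radius, voxels
    cortex_wall: float = 4.0  # radial wall thickness, voxels
    gap_width: int = 8  # axial slices of the osteotomy
    cortex_density: float = 700.0
    callus_density: float = 600.0
    strut_count: int = 3
    strut_radius: float = 2.0  # voxels
    background_density: float = 100.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        nx, ny, nz = self.shape
        if min(self.shape) < 2:
            raise InvalidSpecError(f"grid shape must be >= 2 per axis, got {self.shape}")
        if not self.voxel_size > 0:
            raise InvalidSpecError("voxel size must be > 0")
        if not 0 < self.cortex_wall <= self.cortex_radius:
            raise InvalidSpecError("need 0 < wall thickness <= outer radius")
        if 2 * self.cortex_radius >= min(nx, ny):
            raise InvalidSpecError("cortex diameter must fit inside the transverse grid")
        if not 0 < self.gap_width < nz:
            raise InvalidSpecError("gap width must be positive and smaller than the axial extent")
        if self.strut_count < 0:
            raise InvalidSpecError("strut count must be >= 0")
        if self.strut_count and self.strut_radius >= self.cortex_radius:
            raise InvalidSpecError("strut radius must be smaller than the cortex radius")
        if self.strut_count and self.strut_radius <= 0:
            raise InvalidSpecError("strut radius must be > 0")
        for name, rho in (("cortex", self.cortex_density), ("callus", self.callus_density)):
            if rho < BONE_THRESHOLD:
                raise InvalidSpecError(
                    f"{name} density {rho} must be at or above the {BONE_THRESHOLD} "
                    "mg HA/cm³ bone threshold"
                )
        if not 0 <= self.background_density < BONE_THRESHOLD:
            raise InvalidSpecError("background density must be below the bone threshold")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise SD must be >= 0")


def full_scale_spec(**overrides) -> PhantomSpec:
    """A 300×300×210 spec at 10.5 µm with proportionally scaled geometry."""
    s = 300 / 48
    base = dict(
        shape=(300, 300, 210),
        voxel_size=0.0105,
        cortex_radius=15.0 * s,
        cortex_wall=4.0 * s,
        gap_width=round(8 * 210 / 60),
        strut_radius=2.0 * s,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@dataclass
class PhantomResult:
    """A generated phantom: density volume plus ground-truth masks.

    ``cortex_mask``, ``callus_mask`` and the implied background are a
    disjoint cover of the grid; ``gap_mask`` marks the osteotomy region
    (cylinder footprint over the gap slices) and may overlap the callus.
    """

    volume: DensityVolume
    cortex_mask: np.ndarray
    callus_mask: np.ndarray
    gap_mask: np.ndarray
    spec: PhantomSpec
    solution: object | None = None  # FESolution attached by generation-time checks

    @property
    def bone_mask(self) -> np.ndarray:
        """Ground-truth bone voxels (cortex plus callus)."""
        return self.cortex_mask | self.callus_mask

    @property
    def background_mask(self) -> np.ndarray:
        return ~self.bone_mask


def make_homogeneous_block(
    shape: tuple[int, int, int], density: float, voxel_size: float
) -> DensityVolume:
    """A constant-density block; the oracle fixture for the FE solver."""
    if any(int(s) < 2 for s in shape):
        raise InvalidSpecError(f"block shape must be >= 2 per axis, got {shape}")
    if not voxel_size > 0:
        raise InvalidSpecError("voxel size must be > 0")
    if density < 0:
        raise InvalidSpecError("density must be >= 0")
    values = np.full(tuple(int(s) for s in shape), float(density))
    return DensityVolume(values, voxel_size, {"phantom": "homogeneous-block"})


def _transverse_radius(shape: tuple[int, int, int]):
    nx, ny, _ = shape
    x, y = np.meshgrid(
        np.arange(nx) - (nx - 1) / 2, np.arange(ny) - (ny - 1) / 2, indexing="ij"
    )
    return x, y, np.hypot(x, y)


def _gap_slices(spec: PhantomSpec) -> slice:
    nz = spec.shape[2]
    z0 = (nz - spec.gap_width) // 2
    return slice(z0, z0 + spec.gap_width)


def _strut_centres(spec: PhantomSpec, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Deterministic angular placement on the mid-wall circle with seeded
    jitter, so cohorts are varied yet reproducible."""
    r_mid = spec.cortex_radius - spec.cortex_wall / 2
    jitter = rng.uniform(-0.25, 0.25, size=spec.strut_count)  # radians
    angles = 2 * np.pi * np.arange(spec.strut_count) / max(spec.strut_count, 1) + jitter
    return [(r_mid * np.cos(a), r_mid * np.sin(a)) for a in angles]


def _build_masks(
    spec: PhantomSpec,
    strut_radius: float | None = None,
    wall_inner_shift: float = 0.0,
    shell_fill: float = 0.0,
    periosteal_growth: float = 0.0,
):
    """Coverage fields and masks for one time point.

    ``wall_inner_shift`` grows the cortex inner radius (resorptive
    thinning); ``shell_fill`` in [0, 1] adds a bridging callus shell of that
    fraction of the wall thickness across the gap (formative bridging);
    ``periosteal_growth`` adds that many voxels of periosteal callus around
    the outer cortex surface along the whole segment (formative woven-bone
    apposition, the main driver of rising axial stiffness).
    """
    nx, ny, nz = spec.shape
    x, y, r = _transverse_radius(spec.shape)
    r_out = spec.cortex_radius
    r_in = r_out - spec.cortex_wall + wall_inner_shift
    if r_in >= r_out:
        raise InvalidSpecError("resorption rate empties the cortex wall entirely")
    gap = _gap_slices(spec)

    # partial-volume rendering: each primitive contributes a coverage field
    # (signed boundary distance mapped through a one-voxel linear ramp), so
    # sub-voxel geometry changes move density — and hence stiffness —
    # continuously instead of flipping whole voxels
    def _cov(dist_inside):
        return np.clip(dist_inside + 0.5, 0.0, 1.0)

    cov_ring = _cov(np.minimum(r_out - r, r - r_in))
    cov_cortex = np.repeat(cov_ring[:, :, None], nz, axis=2)
    cov_cortex[:, :, gap] = 0.0

    cov_callus = np.zeros(spec.shape)
    sr = spec.strut_radius if strut_radius is None else strut_radius
    if spec.strut_count and sr > 0:
        rng = np.random.default_rng([spec.seed, 1])
        strut2d = np.zeros((nx, ny))
        for cx, cy in _strut_centres(spec, rng):
            d = sr - np.hypot(x - cx, y - cy)
            strut2d = np.maximum(strut2d, _cov(d))
        cov_callus[:, :, gap] = strut2d[:, :, None]
    if shell_fill > 0:
        fill = min(shell_fill, 1.0)
        shell2d = _cov(np.minimum(r_out - r, r - (r_out - fill * spec.cortex_wall)))
        cov_callus[:, :, gap] = np.maximum(cov_callus[:, :, gap], shell2d[:, :, None])
    if periosteal_growth > 0:
        if 2 * (r_out + periosteal_growth) >= min(nx, ny):
            raise InvalidSpecError("periosteal callus outgrows the transverse grid")
        peri2d = _cov(np.minimum(r - r_out, r_out + periosteal_growth - r))
        cov_callus = np.maximum(cov_callus, peri2d[:, :, None])

    gap_mask = np.zeros(spec.shape, dtype=bool)
    gap_mask[:, :, gap] = (r < r_out)[:, :, None]
    return cov_cortex, cov_callus, gap_mask


def _render(
    spec: PhantomSpec,
    fields,
    callus_density: float | None = None,
    noise_stream: int = 0,
) -> PhantomResult:
    """Render density from coverage fields and derive ground-truth masks.

    Ground truth is defined on the noise-free rendering: a voxel is bone
    exactly when its rendered density reaches the 395 mg HA/cm³ ladder
    threshold, attributed to whichever tissue (cortex or callus)
    contributes more. This keeps ground-truth masks consistent with the
    material mapping on noiseless volumes.
    """
    cov_cortex, cov_callus, gap_mask = fields
    rho_callus = spec.callus_density if callus_density is None else callus_density
    bg = spec.background_density
    contrib_cortex = cov_cortex * (spec.cortex_density - bg)
    contrib_callus = cov_callus * (rho_callus - bg)
    clean = bg + np.maximum(contrib_cortex, contrib_callus)
    bone = clean >= BONE_THRESHOLD
    cortex = bone & (contrib_cortex >= contrib_callus)
    callus = bone & ~cortex

    values = clean
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, 2, noise_stream])
        values = values + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    np.clip(values, 0.0, None, out=values)
    vol = DensityVolume(
        values,
        spec.voxel_size,
        {"phantom": "osteotomy", "seed": spec.seed, "registered": True},
    )
    return PhantomResult(vol, cortex, callus, gap_mask, spec)


def make_osteotomy_phantom(spec: PhantomSpec | None = None) -> PhantomResult:
    """Generate one osteotomized-femur phantom with ground-truth masks."""
    spec = spec or PhantomSpec()
    return _render(spec, _build_masks(spec))


@dataclass(frozen=True)
class HealingSeriesSpec:
    """A longitudinal series of phantoms in a shared registration frame.

    ``formation`` mode emulates a loaded-group-like trajectory: struts
    thicken week by week and a bridging callus shell grows into a contiguous
    wall, while the callus mineralizes (density rises). ``resorption`` mode
    emulates a control-group-like decline: the cortex wall thins and struts
    shrink. Rates are per week (one time point per week).
    """

    base: PhantomSpec = field(default_factory=PhantomSpec)
    n_timepoints: int = 5
    mode: Literal["formation", "resorption"] = "formation"
    strut_rate: float = 0.5  # voxels/week of strut radius change
    shell_rate: float = 0.2  # fraction of wall thickness bridged/resorbed per week
    periosteal_rate: float = 0.4  # voxels/week of periosteal callus apposition (formation)
    initial_shell_fill: float = 0.0  # bridging-shell fraction already present at week 0
    thinning_rate: float = 0.35  # voxels/week of cortex inner-radius growth
    mineralization_rate: float = 20.0  # mg HA/cm³ per week of callus density
    fresh_noise: bool = True  # draw a new noise field per time point (new scan)

    def __post_init__(self) -> None:
        if self.n_timepoints < 2:
            raise InvalidSpecError("a healing series needs at least 2 time points")
        if self.mode not in ("formation", "resorption"):
            raise InvalidSpecError(f"unknown mode {self.mode!r}")
        if min(self.strut_rate, self.shell_rate, self.thinning_rate) < 0:
            raise InvalidSpecError("rates must be >= 0")
        if not 0 <= self.initial_shell_fill <= 1:
            raise InvalidSpecError("initial shell fill must lie in [0, 1]")
        if self.periosteal_rate < 0:
            raise InvalidSpecError("rates must be >= 0")
        if self.mode == "formation":
            grown = self.base.cortex_radius + self.periosteal_rate * (self.n_timepoints - 1)
            if 2 * grown >= min(self.base.shape[0], self.base.shape[1]):
                raise InvalidSpecError(
                    "periosteal growth rate outgrows the transverse grid over the series"
                )
        if self.mode == "resorption":
            shift = self.thinning_rate * (self.n_timepoints - 1)
            if shift >= self.base.cortex_wall:
                raise InvalidSpecError(
                    "thinning rate would empty the cortex wall before the last "
                    "time point"
                )


def make_healing_series(series: HealingSeriesSpec) -> list[PhantomResult]:
    """Generate the ordered longitudinal series (week 0 first).

    Formation mode guarantees a non-decreasing ground-truth bone voxel
    count; resorption mode a non-increasing one (geometry masks nest).
    """
    spec = series.base
    out: list[PhantomResult] = []
    for t in range(series.n_timepoints):
        if series.mode == "formation":
            fields = _build_masks(
                spec,
                strut_radius=spec.strut_radius + series.strut_rate * t,
                shell_fill=min(series.initial_shell_fill + series.shell_rate * t, 1.0),
                periosteal_growth=series.periosteal_rate * t,
            )
            rho_callus = min(
                spec.callus_density + series.mineralization_rate * t,
                spec.cortex_density,
            )
        else:
            fields = _build_masks(
                spec,
                strut_radius=max(spec.strut_radius - series.strut_rate * t, 0.0),
                wall_inner_shift=series.thinning_rate * t,
                shell_fill=max(series.initial_shell_fill - series.shell_rate * t, 0.0),
            )
            rho_callus = spec.callus_density
        res = _render(
            spec, fields,
            callus_density=rho_callus,
            noise_stream=t if series.fresh_noise else 0,
        )
        res.volume.metadata["week"] = t
        out.append(res)
    return out


def make_overloaded_strut_phantom(
    spec: PhantomSpec | None = None,
    reference_load: float = 10.0,
    threshold_ue: float = 10_000.0,
    min_count: int = 51,
) -> PhantomResult:
    """A phantom whose single thin strut is overloaded at the reference load.

    The callus bridges the gap through one thin rod, so the full axial force
    funnels through a few voxels. At generation time the standard pipeline
    (Gaussian filter → material mapping → micro-FE → linear force scaling)
    is run to verify that more than 50 bone voxels meet or exceed
    10,000 µε at ``reference_load`` newtons; otherwise generation fails.

    The returned result carries the verification in ``volume.metadata``
    under ``"overload_check"`` (reference load, over-threshold count) and
    the FE solution as ``result.solution`` for reuse.
    """
    from .material import bone_mask, build_material_volume
    from .microfe import effective_strain_field, solve_material_volume
    from .volio import gaussian_filter

    if spec is None:
        spec = PhantomSpec(strut_count=1, strut_radius=2.0, seed=7)
    if spec.strut_count != 1:
        spec = replace(spec, strut_count=1)
    res = make_osteotomy_phantom(spec)

    filtered = gaussian_filter(res.volume)
    matvol = build_material_volume(filtered)
    solution = solve_material_volume(matvol)
    dist = effective_strain_field(solution, bone_mask(matvol))
    scale = reference_load / dist.f_resultant
    count = int(np.count_nonzero(dist.strains_ue * scale >= threshold_ue))
    if count < min_count:
        raise GenerationFailureError(
            f"only {count} bone voxels reach {threshold_ue:.0f} µε at "
            f"{reference_load} N (need >= {min_count}); widen the gap or thin "
            "the strut"
        )
    res.volume.metadata["overload_check"] = {
        "reference_load_n": reference_load,
        "threshold_ue": threshold_ue,
        "over_threshold_count": count,
    }
    res.solution = solution  # type: ignore[attr-defined]
    return res
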