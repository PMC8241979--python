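# Methods

This package implements an image-based pipeline for individualised
mechanical loading of healing bone: from a 3-D mineral-density volume it
computes the tissue-scale effective-strain distribution by voxel
micro-finite-element (micro-FE) analysis, selects the applied force whose
rescaled strain distribution best matches a reference target, and screens
the selected force against refracture risk. A synthetic phantom generator
stands in for in vivo micro-CT data so that every stage is testable
offline.

## Image model and preprocessing

A `DensityVolume` is a 3-D array of volumetric bone mineral density
(mg HA/cm³) on an isotropic grid; the last axis is the axial (loading)
direction. Readers (MetaImage, NIfTI, TIFF stack) normalise to this
convention and reject anisotropic spacing, because the voxel mesh requires
cubic elements.

Preprocessing comprises cropping to the analysis region, trimming
registration-damaged end slices (the canonical full-scale frame is
300×300×210 voxels at 10.5 µm, trimmed by 15 slices top and bottom to 180),
and Gaussian filtering with σ = 1.2 voxels. "Support" is interpreted as
the integer kernel half-width: support = 1 gives a 3×3×3 kernel, truncated
and renormalised to unit sum, so constant fields are preserved exactly.
σ is taken in voxel units, the convention of this scanner/pipeline family.
Boundary handling is mirror (reflect) padding, chosen to avoid darkening at
the volume faces; it is configurable. Longitudinal registration is **not**
implemented: the pipeline consumes pre-registered volumes and records a
registration flag in metadata.

## Material model

Densities from 395 to 720 mg HA/cm³ in 25 mg HA/cm³ steps map onto a
14-level ladder of isotropic Young's moduli from 4.045 to 12.170 GPa.
The per-level increment is (12.170 − 4.045)/13 = 0.625 GPa exactly; the
endpoints are treated as authoritative. Quantisation is floor-based
(395–419.99 → level 0, …) and densities at or above 720 clamp to the top
level; both choices are configurable because the rounding rule of the
original pipeline is not documented. Sub-threshold voxels are soft tissue
at 0.003 GPa. The marrow cavity on the top (loaded) slice is capped with a
20 GPa plate: soft voxels inside the transverse convex hull of that
slice's bone are relabelled `cap`, preventing spurious edge compliance
from soft tissue lying on the loaded face. Cap placement on the top slice
only is the default (a flag caps both ends). Every voxel has exactly one
role in {bone, soft, cap}; all strain analysis uses the bone mask only.

Poisson's ratio is a single global constant, default ν = 0.3 — the
standard value in this micro-FE literature; it is not part of the density
ladder. Internally the package works in mm / MPa / N so that stress ×
area yields newtons directly; moduli are expressed in GPa at interfaces.

## Micro-FE solver

Each voxel becomes an 8-node trilinear hexahedral element with 2×2×2
Gauss quadrature. Because all elements are cubes of edge h sharing one ν,
the element matrix is E·h·K_unit(ν) for a single cached unit matrix, and
the global matrix is accumulated directly into the 27-neighbour node
stencil (one 3×3 block per node pair) and stored in block-sparse (BSR)
form — no generic COO sort/sum is needed.

Boundary conditions: the top slice receives a compressive axial
displacement of 1% of the axial length (transverse components free by
default; the scaling step uses only axial reactions, so either choice is
self-consistent); the bottom slice is fully fixed. A `roller` bottom
variant (axial fixity plus minimal rigid-body pins) exists solely for
validation: under it a homogeneous block is in uniform uniaxial stress, so
every element must report exactly 10,000 µε at 1% compression and the
resultant force must equal E·δ·A. The full-fix default has no closed form
(edge effects near the faces).

Soft-tissue elements are retained in the mesh at 0.003 GPa rather than
deleted; this is why the marrow cap exists, and it keeps meshes with an
unbridged gap solvable (a connectivity check labels such meshes
"mechanically disconnected" and attaches a warning rather than failing).

The constrained SPD system is solved by conjugate gradients with Jacobi
(diagonal) preconditioning, applied through a projection operator so the
free-free block is never extracted. Defaults: relative residual 10⁻⁶,
iteration cap 10·√(unknowns) with a floor of 500, overridable. A direct
sparse-LU path exists for small validation grids; on ≤6³ grids the CG and
direct solutions agree to better than 10⁻⁸ relative error. Per element the
strain energy density is U = ½ uᵀK_e u / h³ (centroid-averaged over Gauss
points — one value per voxel matches voxel-level counting) and the
**effective strain** is

    ε_eff = √(2U/E),

a scalar energy-equivalent strain that equals the axial strain magnitude
in uniform uniaxial stress. The resultant force F_resultant is the sum of
axial nodal reactions over the top surface; top and bottom reaction sums
balance to within the solver tolerance. Because the model is linear, the
strain field at an applied force F is the simulated field times
F/F_resultant — the pipeline's central scaling identity,
ε_actual = (F_applied/F_resultant)·ε_simulation.

Memory note: the assembled stencil takes ≈ 27·9·8 bytes per node. The
desk-scale grids used throughout (48×48×60 and below) assemble in well
under 1 GB; a full 300×300×210 frame would need an out-of-core or
matrix-free treatment that is out of scope here.

## Load adaptation

The mechanical environment is the multiset of ε_eff over bone voxels. A
`TargetDistribution` is any reference strain sample rescaled so its median
is exactly 700 µε (the default target median). The matched force minimises
the two-sample Kolmogorov–Smirnov statistic between the force-rescaled
environment and the target, using one-dimensional Nelder–Mead started at
the median-matching force F₀ = F_resultant·median(target)/median(dist)
with initial simplex {F₀, 1.05·F₀}. D is piecewise constant in the scale
factor for finite samples, so convergence is defined by absolute
tolerances (0.01 N on F, 10⁻⁴ on D, 200-evaluation cap), not gradient
criteria. Non-convergence and shape-mismatch floors (D ≥ 0.25 at the
optimum) flag the plan instead of raising. A discrete *load menu*
alternative ranks a user-supplied grid of actuator forces by the same
statistic (ties go to the smaller force); an option snaps the matched
force to such a menu before the guard.

The **fracture guard** counts bone voxels whose rescaled strain is at or
above 10,000 µε (= 1% strain). While the count is ≥ 50 voxels, the force
is reduced by 2 N and the count re-evaluated; every (force, count) pair is
recorded. Two readings of the loop's boundary behaviour were possible at
exactly 50 voxels; the conservative one (downscale while count ≥ 50) is
used, and the threshold comparison is ≥, not >. Linear rescaling makes the
per-iteration recount exact, so no re-solve is needed. If the force would
cross zero with the criterion still violated the plan is flagged
`guard_failed` — an explicit "do not load" recommendation, never a silent
clamp. The size of the largest 26-connected over-threshold component is
reported as a diagnostic (clustered voxels sit in thin struts) but does
not change the stopping rule, which is count-based.

An in vivo reference distribution (derived from an individual with good
healing progression) is not something this package can supply, so the
target is a required input. It ships two substitutes: `default_target()`, a synthetic
log-normal (σ = 0.55) sample rescaled to median 700 µε — right-skewed and
unimodal like well-healed strain histograms — and
`cohort.donor_target()`, which generates a well-healed donor phantom and
uses its computed mechanical environment.

## Synthetic phantoms

The phantom is a hollow cylindrical cortex along z with a transverse
osteotomy gap, bridged by cylindrical callus struts placed on the mid-wall
circle at deterministic angles with seeded jitter. Densities are generated
directly in mg HA/cm³ (scanner grayscale→density calibration is
scanner-specific and bypassed); additive Gaussian noise truncated at zero
is the simplest model consistent with filtered micro-CT appearance.
Identical spec + seed is bit-identical by construction.

Primitives are rendered with **partial-volume (anti-aliased) edges**: each
region contributes a coverage field obtained by passing its signed
boundary distance through a one-voxel linear ramp, and the density is the
background plus the largest coverage-weighted contrast. Sub-voxel
geometry changes therefore move density — and hence stiffness —
continuously, as in real micro-CT, instead of flipping whole voxels;
binary rasterisation made series stiffness jump discontinuously.
Ground-truth masks are defined on the noise-free rendering: a voxel is
bone exactly when its rendered density reaches the 395 mg HA/cm³
threshold, attributed to whichever tissue contributes more, which keeps
ground truth consistent with the material mapping on noiseless volumes.
One consequence is physical: features much thinner than a voxel (a wall
thinned below ~1.5 voxels, a sub-voxel strut) are erased by partial
volume plus the Gaussian filter, exactly as they would be in a scan.

**Scale.** The desk-scale default grid is 48×48×60 voxels at 65.625 µm —
the full-scale 300×300×210 field of view at 10.5 µm coarsened 6.25×, i.e.
the *same physical femoral segment*, coarser voxels. Preserving physical
extent keeps resultant forces at tens of newtons and matched loads near
10 N, so the fixed 2 N guard decrement remains meaningful; shrinking the
physical cross-section instead would push forces to ~0.3 N and make the
guard step cross zero immediately. `full_scale_spec()` returns the
10.5 µm frame for full-resolution work.

Healing series share a registration frame and evolve deterministically:

- *formation-like* (loaded-group-like): strut radii grow, a bridging
  callus shell spreads across the gap (fraction of the wall per week,
  optionally starting already bridged — the adaptation phase begins post
  bridging), the callus mineralises toward cortical density, and
  periosteal callus is added around the outer cortex along the whole
  segment. Periosteal apposition is what raises axial stiffness and
  drives the falling constant-load medians / rising adaptive loads; gap
  bridging alone mostly changes gap compliance, not the wall cross-section
  that dominates the median.
- *resorption-like* (control-group-like): the cortex wall thins from the
  medullary side (and struts/shell may shrink), raising constant-load
  strains week over week. The standard cohorts keep the bridging shell
  intact while thinning the wall: losing the bridge mid-series collapses
  the axial stiffness discontinuously (resultant forces drop an order of
  magnitude), which models refracture rather than gradual resorption and
  breaks the monotone strain trend.

Masks nest between consecutive time points, so ground-truth bone voxel
counts are monotone by construction (non-decreasing for formation,
non-increasing for resorption). Rates that would empty the cortex within
the series are rejected at spec validation.

The *overloaded-strut phantom* bridges the gap with a single thin rod so
the whole axial force funnels through a few voxels. Generation runs the
full pipeline and verifies that more than 50 bone voxels meet or exceed
10,000 µε at the documented 10 N reference load, failing loudly otherwise;
the FE solution is attached to the result for reuse.

What the phantoms do **not** emulate: trabecular microarchitecture,
partial-volume and beam-hardening artefacts, soft-tissue contrast,
registration error, and biological feedback between loading and geometry.
Passing tests therefore demonstrate correctness of the computational
chain and the qualitative cohort phenomena (variance reduction, load
directionality), not quantitative agreement with any in vivo dataset —
reproducing measured weekly in vivo medians would require the underlying
scans.

## Cohort comparison and statistics

Per mechanical environment the summary statistic is the median effective
strain; cohort cells (group × week) are summarised as mean ± sample SD
(n−1 denominator; SD is an explicit undefined marker for single-animal
cells). Histograms use 250 left-closed bins over 0–15,000 µε with an
explicit overflow bucket, so counts always sum to the sample size. Bone
volume is voxel count × voxel volume, normalised to week 0 (BV/BV0).

`cohort.simulate_cohort` runs both scenarios from one solve per volume:
constant 10 N versus matched-and-guarded adaptive force.
`cohort.demo_cohort` builds a six-animal cohort (three formation-like,
three resorption-like) with per-animal geometric variance (cortex radius,
wall thickness, gap width, strut count/radius, densities, periosteal
rate), reflecting the >10% geometric spread typical of osteotomy models;
three animals per group keeps the group SD estimate stable. Cohort runs
use a 32×32×40 grid — again the same physical extent, coarser voxels — so
the 35 solves of the standard comparison complete in minutes on one CPU.

## Numerical choices and limitations

- CG tolerance 10⁻⁶ (relative residual) bounds the equilibrium error of
  the reaction sums at the same order; validation tests tighten it.
- Effective strains are clipped at zero before the square root to guard
  against round-off-negative quadratic forms.
- Sub-voxel geometric features (strut radii or shell thicknesses below
  one voxel) rasterise discontinuously; healing-series rates are chosen
  to keep features near or above voxel scale at the default grids.
- The KS statistic is computed by `scipy.stats.ks_2samp`; Nelder–Mead by
  `scipy.optimize.minimize`. Tests verify both against brute-force
  ECDF/grid-search oracles.
- The fracture-risk rule is a conservative screening metric, not a
  validated failure assessment; threshold, voxel limit and decrement are
  parameters.
- Only uniaxial compression is modelled: no shear/bending/torsion menus,
  no fixator hardware, no contact, and no geometric or material
  nonlinearity. Habitual (self-induced) loading is not considered.
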