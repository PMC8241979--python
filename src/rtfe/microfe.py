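"""Voxel-based linear-elastic micro-FE.

Every voxel of the material volume becomes one 8-node trilinear hexahedral
element, so the mesh is taken directly from the image. A compressive axial
displacement (default 1% of the axial length) is prescribed on the top
slice, the bottom slice is fixed, and the resulting sparse SPD system is
solved with Jacobi-preconditioned conjugate gradients.

Outputs per element are the strain energy density U and the effective
strain

    eps_eff = sqrt(2 U / E),

a scalar strain measure that equals the axial strain magnitude in a uniform
uniaxial-stress state. The resultant force is the sum of axial nodal
reactions over the top surface; because the model is linear, the strain
field at any applied force F is the simulated field times F / F_resultant.

Unit system: mm / MPa / N. Strains are dimensionless internally and
reported in microstrain (×10⁶) at the interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Any

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import LinearOperator, cg, spsolve

from .errors import EmptyDistributionError, InvalidInputError, InvalidSpecError, SolverFailureError
from .material import ROLE_SOFT, MaterialVolume

# local node order: lexicographic in (x, y, z) corner offsets
_CORNERS = np.array(
    [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
     [0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1]],
    dtype=np.int64,
)


@dataclass(frozen=True)
class BCSpec:
    """Displacement boundary conditions for the axial compression test.

    ``delta_fraction`` is the prescribed compressive displacement of the top
    slice as a fraction of the axial domain length (default 1%). The bottom
    slice is either fully fixed (the in vivo configuration) or held on an
    axial roller with minimal rigid-body pins (``roller``), which admits the
    closed-form uniform uniaxial-stress solution used for validation.
    """

    delta_fraction: float = 0.01
    bottom_mode: str = "full-fix"  # or "roller"
    top_transverse: str = "free"  # or "fixed"

    def __post_init__(self) -> None:
        if not 0 <= self.delta_fraction < 0.1:
            raise InvalidSpecError(
                f"delta_fraction must lie in [0, 0.1), got {self.delta_fraction}"
            )
        if self.bottom_mode not in ("full-fix", "roller"):
            raise InvalidSpecError(f"unknown bottom_mode {self.bottom_mode!r}")
        if self.top_transverse not in ("free", "fixed"):
            raise InvalidSpecError(f"unknown top_transverse {self.top_transverse!r}")


@dataclass
class FEProblem:
    """Assembled-problem description: element moduli (MPa) on the voxel grid,
    Poisson ratio, voxel edge length h (mm), boundary conditions and solver
    controls."""

    moduli_mpa: np.ndarray  # (nx, ny, nz) element Young's moduli, MPa
    poisson: float
    h: float  # voxel edge length, mm
    bc: BCSpec = field(default_factory=BCSpec)
    tol: float = 1e-6  # relative residual tolerance for CG
    maxiter: int | None = None  # default: 10 * sqrt(n_unknowns), floor 500
    role: np.ndarray | None = None  # optional voxel roles for connectivity check

    def __post_init__(self) -> None:
        self.moduli_mpa = np.asarray(self.moduli_mpa, dtype=np.float64)
        if self.moduli_mpa.ndim != 3:
            raise InvalidInputError("element moduli must form a 3-D grid")
        if not (self.moduli_mpa > 0).all():
            raise InvalidInputError("all element moduli must be > 0")
        if not self.h > 0:
            raise InvalidInputError(f"voxel edge length must be > 0, got {self.h}")
        if not 0 < self.poisson < 0.5:
            raise InvalidInputError(f"Poisson ratio must lie in (0, 0.5)")


@dataclass
class FESolution:
    """Solver output on the problem's grid."""

    displacement: np.ndarray  # (nnx, nny, nnz, 3) nodal displacements, mm
    strain_energy_density: np.ndarray  # (nx, ny, nz) per element, MPa
    effective_strain: np.ndarray  # (nx, ny, nz) per element, microstrain
    f_resultant: float  # N, |sum of top-surface axial reactions|
    f_top: float  # signed sum of top axial reactions, N
    f_bottom: float  # signed sum of bottom axial reactions, N
    iterations: int
    residual: float  # final relative residual
    warnings: list[str] = field(default_factory=list)

    @property
    def equilibrium_error(self) -> float:
        """|f_top + f_bottom| relative to |f_resultant| (0 for zero load)."""
        if self.f_resultant == 0:
            return abs(self.f_top + self.f_bottom)
        return abs(self.f_top + self.f_bottom) / abs(self.f_resultant)


@dataclass
class StrainDistribution:
    """The mechanical environment: effective strains (microstrain) over bone
    voxels at a stated applied force."""

    strains_ue: np.ndarray  # microstrain, one value per masked voxel
    f_resultant: float  # N, from the unit simulation
    f_applied: float  # N, force at which strains_ue holds
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.strains_ue = np.asarray(self.strains_ue, dtype=np.float64)
        if self.strains_ue.ndim != 1 or self.strains_ue.size == 0:
            raise EmptyDistributionError("strain distribution must be a non-empty 1-D sample")
        if (self.strains_ue < 0).any():
            raise InvalidInputError("effective strains are non-negative by definition")

    @property
    def median_ue(self) -> float:
        return float(np.median(self.strains_ue))

    def __len__(self) -> int:
        return int(self.strains_ue.size)


# ---------------------------------------------------------------------------
# Element stiffness
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _unit_stiffness(nu: float) -> np.ndarray:
    """24×24 stiffness of a unit cube (h = 1) at E = 1 and Poisson ratio nu,
    2×2×2 Gauss quadrature. K(E, nu, h) = E * h * K_unit(nu)."""
    lam = nu / ((1 + nu) * (1 - 2 * nu))
    mu = 1.0 / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = np.eye(3) * mu

    gp = np.array([-1, 1]) / np.sqrt(3.0)
    K = np.zeros((24, 24))
    sign = 2 * _CORNERS - 1  # corner signs in natural coordinates
    for xi in gp:
        for eta in gp:
            for zeta in gp:
                # dN/d(natural coords), shape (8, 3)
                dN = np.empty((8, 3))
                for n, (sx, sy, sz) in enumerate(sign):
                    dN[n, 0] = sx * (1 + sy * eta) * (1 + sz * zeta) / 8
                    dN[n, 1] = (1 + sx * xi) * sy * (1 + sz * zeta) / 8
                    dN[n, 2] = (1 + sx * xi) * (1 + sy * eta) * sz / 8
                dNdx = dN * 2.0  # jacobian of unit cube: x = (xi+1)/2
                B = np.zeros((6, 24))
                for n in range(8):
                    c = 3 * n
                    B[0, c] = dNdx[n, 0]
                    B[1, c + 1] = dNdx[n, 1]
                    B[2, c + 2] = dNdx[n, 2]
                    B[3, c] = dNdx[n, 1]
                    B[3, c + 1] = dNdx[n, 0]
                    B[4, c + 1] = dNdx[n, 2]
                    B[4, c + 2] = dNdx[n, 1]
                    B[5, c] = dNdx[n, 2]
                    B[5, c + 2] = dNdx[n, 0]
                K += B.T @ D @ B * (1 / 8)  # det J = 1/8, weight 1
    return 0.5 * (K + K.T)


def element_stiffness(e_mpa: float, nu: float, h: float) -> np.ndarray:
    """Stiffness matrix (N/mm per DOF) of one cubic voxel element.

    The matrix is symmetric positive semi-definite with a 6-dimensional
    rigid-body null space, and scales linearly in both E and h.
    """
    if not e_mpa > 0 or not h > 0:
        raise InvalidInputError("element stiffness requires E > 0 and h > 0")
    if not 0 < nu < 0.5:
        raise InvalidInputError("Poisson ratio must lie in (0, 0.5)")
    return e_mpa * h * _unit_stiffness(float(nu))


# ---------------------------------------------------------------------------
# Assembly and solve
# ---------------------------------------------------------------------------


def _element_dofs(shape: tuple[int, int, int]) -> np.ndarray:
    """(n_elem, 24) global DOF indices, elements in C order of the grid."""
    nx, ny, nz = shape
    nnx, nny = nx + 1, ny + 1
    ex, ey, ez = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    base = ex.ravel()[:, None] + _CORNERS[None, :, 0]
    base = base + (ey.ravel()[:, None] + _CORNERS[None, :, 1]) * nnx
    base = base + (ez.ravel()[:, None] + _CORNERS[None, :, 2]) * nnx * nny
    dofs = (3 * base[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)
    return dofs.astype(np.int32)


def _node_ids(shape: tuple[int, int, int]) -> np.ndarray:
    """(nnx, nny, nnz) array of global node indices (x fastest)."""
    nx, ny, nz = shape
    nnx, nny, nnz = nx + 1, ny + 1, nz + 1
    ix, iy, iz = np.meshgrid(
        np.arange(nnx), np.arange(nny), np.arange(nnz), indexing="ij"
    )
    return ix + nnx * (iy + nny * iz)


def _build_constraints(problem: FEProblem):
    """Return (fixed_dof_mask, prescribed_values) as flat arrays of length n_dof."""
    nx, ny, nz = problem.moduli_mpa.shape
    ids = _node_ids((nx, ny, nz))
    n_nodes = (nx + 1) * (ny + 1) * (nz + 1)
    fixed = np.zeros((n_nodes, 3), dtype=bool)
    vals = np.zeros((n_nodes, 3))
    top = ids[:, :, -1].ravel()
    bottom = ids[:, :, 0].ravel()
    delta = problem.bc.delta_fraction * nz * problem.h

    fixed[top, 2] = True
    vals[top, 2] = -delta  # compressive
    if problem.bc.top_transverse == "fixed":
        fixed[top, 0] = True
        fixed[top, 1] = True
    if problem.bc.bottom_mode == "full-fix":
        fixed[bottom, :] = True
    else:  # roller: axial only, plus minimal rigid-body pins
        fixed[bottom, 2] = True
        corner = ids[0, 0, 0]
        fixed[corner, 0] = True
        fixed[corner, 1] = True
        xcorner = ids[-1, 0, 0]  # blocks rotation about z
        fixed[xcorner, 1] = True
    return fixed.ravel(), vals.ravel()


def _check_load_path(problem: FEProblem) -> list[str]:
    """Flag meshes where no stiff (non-soft) component connects top to bottom."""
    if problem.role is None:
        return []
    stiff = problem.role != ROLE_SOFT
    if not stiff.any():
        return ["no stiff elements in mesh; load carried entirely by soft tissue"]
    labels, _ = ndimage.label(stiff)
    spans = set(np.unique(labels[:, :, 0])) & set(np.unique(labels[:, :, -1]))
    spans.discard(0)
    if not spans:
        return [
            "mechanically disconnected: no bone/cap component spans top to bottom; "
            "load is carried through soft tissue"
        ]
    return []


def assemble_stiffness(problem: FEProblem) -> sparse.bsr_matrix:
    """Assemble the global sparse stiffness matrix (no constraints applied).

    The voxel mesh couples each node to at most 27 neighbouring nodes, so the
    matrix is accumulated directly into that block stencil (one 3×3 block per
    node pair) and returned in BSR form, avoiding the sort-and-sum of a
    generic COO assembly.
    """
    nx, ny, nz = problem.moduli_mpa.shape
    nnx, nny, nnz = nx + 1, ny + 1, nz + 1
    n_nodes = nnx * nny * nnz
    k_unit = _unit_stiffness(float(problem.poisson))
    eh = problem.moduli_mpa * problem.h  # per-element scale

    # 27 node-offset vectors, sorted by flat node-index increment so that
    # per-row block columns come out ascending (valid BSR ordering)
    offsets = np.array(
        [(dx, dy, dz) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)],
        dtype=np.int64,
    )
    rank = {tuple(d): o for o, d in enumerate(offsets)}

    # stencil blocks accumulated in node-major layout (z, y, x, offset, 3, 3),
    # which flattens directly to the x-fastest node ordering
    w = np.zeros((nnz, nny, nnx, 27, 3, 3))
    eh_t = np.ascontiguousarray(eh.transpose(2, 1, 0))  # (nz, ny, nx)
    for i in range(8):
        ci = _CORNERS[i]
        sl_i = (
            slice(ci[2], ci[2] + nz),
            slice(ci[1], ci[1] + ny),
            slice(ci[0], ci[0] + nx),
        )
        for j in range(8):
            o = rank[tuple(_CORNERS[j] - ci)]
            block = k_unit[3 * i : 3 * i + 3, 3 * j : 3 * j + 3]
            w[(*sl_i, o)] += eh_t[..., None, None] * block[None, None, None]

    # validity of each neighbour offset per node, in flat node order
    ix, iy, iz = np.meshgrid(
        np.arange(nnx), np.arange(nny), np.arange(nnz), indexing="ij"
    )
    ix = np.ascontiguousarray(ix.transpose(2, 1, 0)).reshape(n_nodes, 1)
    iy = np.ascontiguousarray(iy.transpose(2, 1, 0)).reshape(n_nodes, 1)
    iz = np.ascontiguousarray(iz.transpose(2, 1, 0)).reshape(n_nodes, 1)
    dx, dy, dz = offsets[:, 0], offsets[:, 1], offsets[:, 2]
    valid = (
        (ix + dx >= 0) & (ix + dx < nnx)
        & (iy + dy >= 0) & (iy + dy < nny)
        & (iz + dz >= 0) & (iz + dz < nnz)
    )  # (n_nodes, 27)
    node = ix + nnx * (iy + nny * iz)
    cols = node + (dx + nnx * (dy + nny * dz))

    data = w.reshape(n_nodes, 27, 3, 3)[valid]  # node-major, column-sorted
    indices = cols[valid].astype(np.int32)
    indptr = np.concatenate(([0], np.cumsum(valid.sum(axis=1), dtype=np.int64)))
    return sparse.bsr_matrix(
        (data, indices, indptr), shape=(3 * n_nodes, 3 * n_nodes), blocksize=(3, 3)
    )


def assemble_and_solve(problem: FEProblem, method: str = "cg") -> FESolution:
    """Solve the constrained axial-compression problem.

    ``method`` is ``"cg"`` (Jacobi-preconditioned conjugate gradients, the
    default) or ``"direct"`` (sparse LU, for small validation grids).
    """
    shape = problem.moduli_mpa.shape
    warnings = _check_load_path(problem)
    K = assemble_stiffness(problem)
    fixed, vals = _build_constraints(problem)
    free = ~fixed
    u = vals.copy()

    iterations = 0
    residual = 0.0
    if problem.bc.delta_fraction > 0:
        b = K @ u  # u currently holds the prescribed values
        b *= -1.0
        b[fixed] = 0.0
        if method == "direct":
            K_ff = K.tocsr()[free][:, free]
            u[free] += spsolve(K_ff.tocsc(), b[free])
        elif method == "cg":
            # solve on the full DOF vector with constrained entries projected
            # out; iterates keep exact zeros on fixed DOFs, so this is CG on
            # the free-free block without extracting it
            diag = K.diagonal()
            diag[fixed] = 1.0

            def _amul(x):
                y = K @ x
                y[fixed] = 0.0
                return y

            A = LinearOperator(K.shape, matvec=_amul)
            M = LinearOperator(K.shape, matvec=lambda x: x / diag)
            n_unk = int(free.sum())
            maxiter = problem.maxiter or max(500, int(10 * np.sqrt(n_unk)))
            bnorm = np.linalg.norm(b)
            count = [0]

            def _cb(xk):
                count[0] += 1

            du, info = cg(A, b, rtol=problem.tol, maxiter=maxiter, M=M, callback=_cb)
            iterations = count[0]
            residual = float(np.linalg.norm(b - _amul(du)) / bnorm)
            if info > 0:
                raise SolverFailureError(
                    f"CG did not converge within {maxiter} iterations "
                    f"(relative residual {residual:.3e})",
                    residual_history=[residual],
                )
            u += du
        else:
            raise InvalidInputError(f"unknown solve method {method!r}")

    # reactions at constrained DOFs
    r = K @ u
    nx, ny, nz = shape
    nnx, nny, nnz = nx + 1, ny + 1, nz + 1
    r3 = r.reshape(nnz, nny, nnx, 3).transpose(2, 1, 0, 3)
    f_top = float(r3[:, :, -1, 2].sum())
    f_bottom = float(r3[:, :, 0, 2].sum())
    f_resultant = abs(f_top)

    # per-element strain energy density and effective strain
    edof = _element_dofs(shape)
    k_unit = _unit_stiffness(float(problem.poisson))
    u_e = u[edof]  # (n_elem, 24)
    quad = np.einsum("ei,ij,ej->e", u_e, k_unit, u_e)  # = u K_unit u >= 0
    np.clip(quad, 0.0, None, out=quad)
    h = problem.h
    # U = 0.5 * u K_e u / h^3 with K_e = E h K_unit  ->  U = 0.5 E quad / h^2
    sed = 0.5 * problem.moduli_mpa * quad.reshape(shape) / h**2
    # eps_eff = sqrt(2 U / E) = sqrt(quad) / h, reported in microstrain
    eff = np.sqrt(quad).reshape(shape) / h * 1e6

    return FESolution(
        displacement=u.reshape(nnz, nny, nnx, 3).transpose(2, 1, 0, 3),
        strain_energy_density=sed,
        effective_strain=eff,
        f_resultant=f_resultant,
        f_top=f_top,
        f_bottom=f_bottom,
        iterations=iterations,
        residual=residual,
        warnings=warnings,
    )


def solve_material_volume(
    matvol: MaterialVolume, bc: BCSpec | None = None, **kwargs
) -> FESolution:
    """Convenience wrapper: build an :class:`FEProblem` from a material volume
    (moduli converted to MPa, roles attached for the load-path check) and
    solve it."""
    problem = FEProblem(
        moduli_mpa=matvol.modulus_mpa,
        poisson=matvol.poisson,
        h=matvol.voxel_size,
        bc=bc or BCSpec(),
        role=matvol.role,
        **kwargs,
    )
    return assemble_and_solve(problem)


def effective_strain_field(
    solution: FESolution, mask: np.ndarray, provenance: dict[str, Any] | None = None
) -> StrainDistribution:
    """Extract the mechanical environment: effective strains over masked
    (bone) voxels at the simulation's own resultant force."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != solution.effective_strain.shape:
        raise InvalidInputError(
            f"mask shape {mask.shape} does not match grid {solution.effective_strain.shape}"
        )
    if not mask.any():
        raise EmptyDistributionError("empty mask: no voxels to analyse")
    return StrainDistribution(
        strains_ue=solution.effective_strain[mask],
        f_resultant=solution.f_resultant,
        f_applied=solution.f_resultant,
        provenance=dict(provenance or {}),
    )
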