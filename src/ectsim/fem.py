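"""Quasi-static volume-conductor FEM with adaptive scalp conductivity.

Solves the Laplace problem div(sigma grad V) = 0 on a labeled hexahedral
mesh with element-wise conductivity.  The driven electrode injects the
applied current as a uniform current density over its outer gel faces
(Neumann load); the ground electrode's outer faces are held at V = 0
(Dirichlet).  Terminal impedance is the area-weighted mean potential over
the driven faces divided by the applied current.

The adaptive solve is an under-relaxed Picard (fixed-point) iteration:
superficial-scalp elements start at the transfer-function floor
conductivity, and after each linear solve each one is updated toward
sigma_SS(|E|) of its element-centered field.  Picard with relaxation 0.5 is
used rather than a Newton scheme because the transfer function is piecewise
linear with a jump at the threshold, where a derivative is undefined.  The
iteration stops when both the relative impedance change and the maximum
relative conductivity change fall below the adaptive tolerance.

Elements are first-order (trilinear) axis-aligned hexahedra with
element-constant conductivity and field; the linear systems are solved with
diagonally preconditioned conjugate gradients (or optionally a sparse
direct factorization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .conductivity import ScalpParams, TissueTable, TransferFunctionParams, sigma_ss
from .phantom import LabeledMesh

__all__ = [
    "BoundaryCondition",
    "SolverSettings",
    "LinearSolveResult",
    "AdaptiveSolveResult",
    "LinearSolveError",
    "assemble_stiffness",
    "solve_linear",
    "solve_adaptive",
    "cut_plane_current",
    "assign_fixed_conductivities",
    "STATIC_CURRENT",
    "DYNAMIC_CURRENT",
]

STATIC_CURRENT = 2e-6  # A, device static-impedance test amplitude
DYNAMIC_CURRENT = 0.9  # A, ECT stimulus amplitude

# conductivity floor applied to any element (air voxels), S/m
SIGMA_FLOOR = 1e-15


class LinearSolveError(RuntimeError):
    pass


@dataclass(frozen=True)
class BoundaryCondition:
    """Applied terminal current (A) and optional terminal-set override."""

    applied_current: float
    swap_terminals: bool = False

    def __post_init__(self) -> None:
        if not self.applied_current > 0:
            raise ValueError("applied_current must be > 0")

    def terminals(self, mesh: LabeledMesh):
        if self.swap_terminals:
            return mesh.ground_faces, mesh.driven_faces
        return mesh.driven_faces, mesh.ground_faces


@dataclass(frozen=True)
class SolverSettings:
    """Numerical controls for the linear and adaptive solves."""

    linear_tolerance: float = 1e-3  # relative residual for CG
    adaptive_tolerance: float = 1e-3  # relative impedance / sigma change
    max_adaptive_iterations: int = 1000
    relaxation: float = 0.5  # Picard under-relaxation factor
    linear_solver: str = "cg"  # "cg" or "direct"
    max_linear_iterations: int = 50000
    blend_width: float = 0.0  # optional transfer-function blend, V/m

    def __post_init__(self) -> None:
        if not 0 < self.linear_tolerance < 1:
            raise ValueError("linear_tolerance must be in (0, 1)")
        if not 0 < self.adaptive_tolerance < 1:
            raise ValueError("adaptive_tolerance must be in (0, 1)")
        if self.max_adaptive_iterations < 1:
            raise ValueError("max_adaptive_iterations must be >= 1")
        if not 0 < self.relaxation <= 1:
            raise ValueError("relaxation must be in (0, 1]")
        if self.linear_solver not in ("cg", "direct"):
            raise ValueError("linear_solver must be 'cg' or 'direct'")


@dataclass(frozen=True)
class LinearSolveResult:
    potentials: np.ndarray  # (N,) V
    field_vectors: np.ndarray  # (M, 3) V/m, element centers
    fields: np.ndarray  # (M,) V/m magnitudes
    impedance: float  # ohm


@dataclass(frozen=True)
class AdaptiveSolveResult:
    potentials: np.ndarray
    fields: np.ndarray
    conductivities: np.ndarray  # (M,) S/m at convergence
    impedance: float
    iterations: int
    converged: bool
    trace: list  # per-iteration (impedance, max relative sigma change)


@lru_cache(maxsize=64)
def _box_stiffness(dx: float, dy: float, dz: float) -> np.ndarray:
    """Unit-conductivity 8x8 stiffness of an axis-aligned trilinear hex."""
    signs = np.array(
        [
            [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
            [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
        ],
        dtype=float,
    )
    g = 1.0 / np.sqrt(3.0)
    pts = np.array([[i, j, k] for i in (-g, g) for j in (-g, g) for k in (-g, g)])
    half = np.array([dx, dy, dz]) / 2.0
    detj = half.prod()
    k_mat = np.zeros((8, 8))
    for xi, eta, zeta in pts:
        # dN/dxi etc. of N_i = (1/8)(1+s_x xi)(1+s_y eta)(1+s_z zeta)
        grads = np.empty((8, 3))
        for i, (sx, sy, sz) in enumerate(signs):
            grads[i] = (
                sx * (1 + sy * eta) * (1 + sz * zeta) / 8.0,
                sy * (1 + sx * xi) * (1 + sz * zeta) / 8.0,
                sz * (1 + sx * xi) * (1 + sy * eta) / 8.0,
            )
        grads = grads / half  # physical gradients
        k_mat += detj * grads @ grads.T
    return k_mat


def assemble_stiffness(
    mesh: LabeledMesh, conductivities: np.ndarray
) -> sp.csr_matrix:
    """Assemble the global conductance matrix (double precision throughout,
    tolerating the ~14-decade conductivity range when air is present)."""
    sigma = np.maximum(np.asarray(conductivities, dtype=float), SIGMA_FLOOR)
    if len(sigma) != mesh.n_elements:
        raise ValueError("one conductivity per element is required")
    sizes = np.round(mesh.element_sizes(), 12)
    n = len(mesh.nodes)
    rows, cols, data = [], [], []
    uniq, inverse = np.unique(sizes, axis=0, return_inverse=True)
    for gi, (dx, dy, dz) in enumerate(uniq):
        sel = np.nonzero(inverse == gi)[0]
        kref = _box_stiffness(float(dx), float(dy), float(dz))
        els = mesh.elements[sel]
        block = sigma[sel][:, None, None] * kref[None, :, :]
        rows.append(np.repeat(els, 8, axis=1).ravel())
        cols.append(np.tile(els, (1, 8)).ravel())
        data.append(block.ravel())
    mat = sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return mat.tocsr()


def _element_fields(mesh: LabeledMesh, potentials: np.ndarray) -> np.ndarray:
    """E = -grad V at element centers of axis-aligned trilinear hexes."""
    v = potentials[mesh.elements]  # (M, 8)
    s = mesh.element_sizes()
    ex = -((v[:, 1] - v[:, 0]) + (v[:, 2] - v[:, 3])
           + (v[:, 5] - v[:, 4]) + (v[:, 6] - v[:, 7])) / (4.0 * s[:, 0])
    ey = -((v[:, 3] - v[:, 0]) + (v[:, 2] - v[:, 1])
           + (v[:, 7] - v[:, 4]) + (v[:, 6] - v[:, 5])) / (4.0 * s[:, 1])
    ez = -((v[:, 4] - v[:, 0]) + (v[:, 5] - v[:, 1])
           + (v[:, 6] - v[:, 2]) + (v[:, 7] - v[:, 3])) / (4.0 * s[:, 2])
    return np.column_stack([ex, ey, ez])


def solve_linear(
    mesh: LabeledMesh,
    conductivities: np.ndarray,
    bc: BoundaryCondition,
    settings: SolverSettings | None = None,
    initial_guess: np.ndarray | None = None,
) -> LinearSolveResult:
    """One linear Laplace solve with fixed element conductivities.

    Total current is injected uniformly (per unit area) over the driven
    terminal faces; ground faces are clamped to 0 V.  Impedance is the
    area-weighted mean driven-face potential over the applied current.
    """
    settings = settings or SolverSettings()
    driven_faces, ground_faces = bc.terminals(mesh)
    k_mat = assemble_stiffness(mesh, conductivities)
    n = len(mesh.nodes)

    areas = mesh.face_areas(driven_faces)
    total_area = areas.sum()
    b = np.zeros(n)
    per_face = bc.applied_current * areas / total_area
    np.add.at(b, driven_faces.ravel(), np.repeat(per_face / 4.0, 4))

    ground_nodes = np.unique(ground_faces)
    free = np.ones(n, dtype=bool)
    free[ground_nodes] = False
    k_ff = k_mat[free][:, free].tocsr()
    b_f = b[free]

    if settings.linear_solver == "direct":
        x = spla.splu(k_ff.tocsc()).solve(b_f)
    else:
        diag = k_ff.diagonal()
        if np.any(diag <= 0):
            raise LinearSolveError("singular system: nonpositive diagonal")
        precond = sp.diags(1.0 / diag)
        x0 = initial_guess[free] if initial_guess is not None else None
        x, info = spla.cg(
            k_ff,
            b_f,
            x0=x0,
            rtol=settings.linear_tolerance,
            atol=0.0,
            maxiter=settings.max_linear_iterations,
            M=precond,
        )
        if info != 0:
            res = np.linalg.norm(k_ff @ x - b_f) / np.linalg.norm(b_f)
            raise LinearSolveError(
                f"conjugate gradients did not reach tolerance "
                f"{settings.linear_tolerance} in {settings.max_linear_iterations} "
                f"iterations (relative residual {res:.3e})"
            )

    potentials = np.zeros(n)
    potentials[free] = x
    vectors = _element_fields(mesh, potentials)
    fields = np.linalg.norm(vectors, axis=1)
    v_face = potentials[driven_faces].mean(axis=1)
    v_terminal = float(np.sum(v_face * areas) / total_area)
    impedance = v_terminal / bc.applied_current
    return LinearSolveResult(
        potentials=potentials,
        field_vectors=vectors,
        fields=fields,
        impedance=impedance,
    )


def cut_plane_current(
    mesh: LabeledMesh,
    conductivities: np.ndarray,
    potentials: np.ndarray,
    z_cut: float,
) -> float:
    """Net discrete current (A) crossing the horizontal plane z = z_cut.

    Computed from the assembled conductance matrix as the total current
    entering the node set above the plane, which by discrete conservation
    equals the current crossing the plane.  ``z_cut`` must fall strictly
    between node planes.
    """
    k_mat = assemble_stiffness(mesh, conductivities)
    above = mesh.nodes[:, 2] > z_cut
    return float((k_mat @ potentials)[above].sum())


def assign_fixed_conductivities(
    mesh: LabeledMesh,
    tissues: TissueTable,
    scalp: ScalpParams,
    superficial_value: float | np.ndarray | None = None,
) -> np.ndarray:
    """Per-element conductivities: tissue table for fixed compartments,
    sigma_DS for deep scalp, and ``superficial_value`` (default: the
    transfer-function floor) for superficial scalp."""
    labels = mesh.labels
    sigma = np.empty(mesh.n_elements)
    for lab_id, name in enumerate(mesh.tissue_names):
        sel = mesh.tissue_ids == lab_id
        if not sel.any():
            continue
        if name == "deep_scalp":
            sigma[sel] = scalp.deep_scalp_conductivity
        elif name == "superficial_scalp":
            sigma[sel] = scalp.transfer_function.floor_conductivity
        else:
            sigma[sel] = tissues[name]
    ss = labels == "superficial_scalp"
    if superficial_value is not None:
        sigma[ss] = superficial_value
    return sigma


def solve_adaptive(
    mesh: LabeledMesh,
    tissues: TissueTable,
    scalp: ScalpParams,
    tf: TransferFunctionParams | None = None,
    bc: BoundaryCondition | None = None,
    settings: SolverSettings | None = None,
) -> AdaptiveSolveResult:
    """Fixed-point solve with field-dependent superficial-scalp conductivity.

    Non-convergence within the iteration cap is reported through the
    ``converged`` flag (with the full trace), not as an exception.
    """
    tf = tf or scalp.transfer_function
    bc = bc or BoundaryCondition(applied_current=DYNAMIC_CURRENT)
    settings = settings or SolverSettings()
    ss_mask = mesh.labels == "superficial_scalp"
    if not ss_mask.any():
        raise ValueError("mesh contains no superficial-scalp elements")

    sigma = assign_fixed_conductivities(mesh, tissues, scalp)
    sigma[ss_mask] = tf.floor_conductivity
    trace: list = []
    prev_impedance = None
    converged = False
    result = None
    sigma_used = sigma
    iteration = 0
    for iteration in range(1, settings.max_adaptive_iterations + 1):
        sigma_used = sigma.copy()
        # warm-start each Picard step from the previous potentials
        guess = result.potentials if result is not None else None
        result = solve_linear(mesh, sigma, bc, settings, initial_guess=guess)
        sigma_new = sigma_ss(
            result.fields[ss_mask], tf, scalp, blend_width=settings.blend_width
        )
        sigma_prev_ss = sigma[ss_mask]
        omega = settings.relaxation
        sigma_next = (1.0 - omega) * sigma_prev_ss + omega * sigma_new
        max_rel_sigma = float(
            np.max(np.abs(sigma_next - sigma_prev_ss) / sigma_prev_ss)
        )
        sigma[ss_mask] = sigma_next
        if prev_impedance is None:
            rel_z = np.inf
        else:
            rel_z = abs(result.impedance - prev_impedance) / abs(prev_impedance)
        trace.append((result.impedance, max_rel_sigma))
        prev_impedance = result.impedance
        if rel_z < settings.adaptive_tolerance and (
            max_rel_sigma < settings.adaptive_tolerance
        ):
            converged = True
            break

    return AdaptiveSolveResult(
        potentials=result.potentials,
        fields=result.fields,
        conductivities=sigma_used,
        impedance=result.impedance,
        iterations=iteration,
        converged=converged,
        trace=trace,
    )
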