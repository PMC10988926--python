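"""Synthetic multilayer head phantoms for the volume-conductor solver.

Stand-ins for subject MRI-derived head meshes: structured hexahedral
geometries with labeled tissue compartments (superficial scalp, deep scalp,
skull, CSF/meninges, gray matter, white matter) and two rectangular
electrode-gel pads on the outer surface.

Two shapes are provided:

* ``layered_slab`` (default) - a flat stack of tissue layers with both
  electrode pads on the top face, mimicking a bifrontal montage on the
  forehead.  The slab isolates the series scalp/skull current path the
  adaptive model parameterizes and admits an analytic series-resistance
  oracle when driven with full-face electrodes.
* ``concentric_shells`` - voxelized concentric spheres with two
  diametrically opposed electrode caps, for curvature effects.

Air is not meshed: at 1e-15 S/m it carries no current, so the conductive
domain simply ends at the outer surface.

Meshes are written as legacy-ASCII VTK unstructured grids (hexahedron cells
with an integer ``tissue_id`` cell-data field) plus a JSON sidecar
(``<file>.json``) carrying the id-to-label map and the two terminal face
sets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "PhantomSpec",
    "LabeledMesh",
    "CANONICAL_LAYER_ORDER",
    "KNOWN_LABELS",
    "ELECTRODE_WIDTH",
    "ELECTRODE_HEIGHT",
    "GEL_THICKNESS",
    "default_slab_spec",
    "default_shell_spec",
    "build_phantom",
    "build_column",
    "tissue_volumes",
    "write_mesh",
    "read_mesh",
]

# outside-in compartment order for layer definitions
CANONICAL_LAYER_ORDER = (
    "superficial_scalp",
    "deep_scalp",
    "skull",
    "csf",
    "gray_matter",
    "white_matter",
)
KNOWN_LABELS = frozenset(CANONICAL_LAYER_ORDER) | {"gel", "air"}

# adhesive pad electrode geometry: 4.2 x 4.9 cm pads, ~1.7 mm gel
ELECTRODE_WIDTH = 0.042
ELECTRODE_HEIGHT = 0.049
GEL_THICKNESS = 0.0017


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom geometry specification (all lengths in meters).

    ``layers`` lists (tissue label, thickness) outside-in for the slab, or
    (tissue label, outer radius) outside-in for the shells.  ``patches``
    gives the two electrode rectangles as (x0, y0, width, height) on the
    slab top face; shells place spherical caps of half-angle
    ``cap_angle_deg`` on the +x and -x poles instead.  ``element_size``
    sets the through-thickness (slab) or voxel (shells) resolution and must
    resolve the thinnest layer with at least two elements;
    ``in_plane_size`` sets the slab's lateral resolution (defaults to
    ``element_size``).
    """

    shape: str = "layered_slab"
    layers: tuple = (
        ("superficial_scalp", 0.0035),
        ("deep_scalp", 0.0035),
        ("skull", 0.007),
        ("csf", 0.003),
        ("gray_matter", 0.010),
        ("white_matter", 0.010),
    )
    slab_size: tuple = (0.14, 0.063)
    patches: tuple = (
        (0.014, 0.007, ELECTRODE_WIDTH, ELECTRODE_HEIGHT),
        (0.084, 0.007, ELECTRODE_WIDTH, ELECTRODE_HEIGHT),
    )
    gel_thickness: float = GEL_THICKNESS
    element_size: float = 0.0015
    in_plane_size: float | None = 0.007
    cap_angle_deg: float = 40.0

    def __post_init__(self) -> None:
        if self.shape not in ("layered_slab", "concentric_shells"):
            raise ValueError(f"unknown phantom shape '{self.shape}'")
        labels = [lab for lab, _ in self.layers]
        order = [lab for lab in CANONICAL_LAYER_ORDER if lab in labels]
        if labels != order or len(set(labels)) != len(labels):
            raise ValueError(
                "layers must be listed outside-in following "
                f"{CANONICAL_LAYER_ORDER}"
            )
        thicknesses = self._thicknesses()
        if any(t <= 0 for t in thicknesses):
            raise ValueError("layer thicknesses/radii must be strictly increasing inward" if self.shape == "concentric_shells" else "layer thicknesses must be positive")
        thinnest = min(thicknesses)
        if self.element_size > thinnest / 2 * (1 + 1e-9):
            raise ValueError(
                f"element_size {self.element_size} larger than half the "
                f"thinnest layer ({thinnest / 2:.4g} m)"
            )
        if self.shape == "layered_slab":
            lx, ly = self.slab_size
            if len(self.patches) != 2:
                raise ValueError("exactly two electrode patches are required")
            for x0, y0, w, h in self.patches:
                if x0 < 0 or y0 < 0 or x0 + w > lx or y0 + h > ly:
                    raise ValueError("electrode patch extends off the slab surface")
            (ax, ay, aw, ah), (bx, by, bw, bh) = self.patches
            if ax < bx + bw and bx < ax + aw and ay < by + bh and by < ay + ah:
                raise ValueError("electrode patches overlap")

    def _thicknesses(self) -> list:
        if self.shape == "layered_slab":
            return [t for _, t in self.layers]
        radii = [r for _, r in self.layers]  # descending outer radii
        outer = radii
        inner = radii[1:] + [0.0]
        return [o - i for o, i in zip(outer, inner)]

    @property
    def plane_size(self) -> float:
        return self.in_plane_size or self.element_size


@dataclass
class LabeledMesh:
    """Hexahedral mesh with per-element tissue labels and terminal faces.

    ``elements`` uses VTK hexahedron node ordering; ``driven_faces`` and
    ``ground_faces`` are (n, 4) node-index quads on the outer gel (or
    terminal) surfaces.
    """

    nodes: np.ndarray  # (N, 3) float, meters
    elements: np.ndarray  # (M, 8) int
    tissue_ids: np.ndarray  # (M,) int
    tissue_names: list  # id -> label
    driven_faces: np.ndarray  # (F, 4) int
    ground_faces: np.ndarray  # (G, 4) int

    def __post_init__(self) -> None:
        if len(self.tissue_ids) != len(self.elements):
            raise ValueError("every element must carry a tissue label")
        if len(self.driven_faces) == 0 or len(self.ground_faces) == 0:
            raise ValueError("terminal face sets must be non-empty")
        driven_nodes = set(np.unique(self.driven_faces))
        if driven_nodes & set(np.unique(self.ground_faces)):
            raise ValueError("terminal sets must be disjoint")

    @property
    def labels(self) -> np.ndarray:
        return np.asarray(self.tissue_names)[self.tissue_ids]

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_sizes(self) -> np.ndarray:
        """(M, 3) axis-aligned element edge lengths (dx, dy, dz)."""
        n = self.nodes
        e = self.elements
        dx = n[e[:, 1], 0] - n[e[:, 0], 0]
        dy = n[e[:, 3], 1] - n[e[:, 0], 1]
        dz = n[e[:, 4], 2] - n[e[:, 0], 2]
        return np.column_stack([dx, dy, dz])

    def element_volumes(self) -> np.ndarray:
        return np.prod(self.element_sizes(), axis=1)

    def face_areas(self, faces: np.ndarray) -> np.ndarray:
        """Areas of axis-aligned quad faces."""
        p = self.nodes[faces]  # (F, 4, 3)
        d1 = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
        d2 = np.linalg.norm(p[:, 3] - p[:, 0], axis=1)
        return d1 * d2

    def assert_connected(self) -> None:
        """Verify the mesh is one face-connected conductive component."""
        faces: dict = {}
        rows, cols = [], []
        for ei, el in enumerate(self.elements):
            for quad in _hex_faces(el):
                key = tuple(sorted(quad))
                other = faces.pop(key, None)
                if other is None:
                    faces[key] = ei
                else:
                    rows.append(other)
                    cols.append(ei)
        m = self.n_elements
        adj = coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(m, m)
        )
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp != 1:
            raise ValueError(f"mesh has {n_comp} disconnected components")


def _hex_faces(el: np.ndarray):
    """Six quad faces of a VTK-ordered hexahedron."""
    return (
        (el[0], el[1], el[2], el[3]),
        (el[4], el[5], el[6], el[7]),
        (el[0], el[1], el[5], el[4]),
        (el[3], el[2], el[6], el[7]),
        (el[0], el[3], el[7], el[4]),
        (el[1], el[2], el[6], el[5]),
    )


def _subdivide(thickness: float, element_size: float) -> int:
    return max(2, int(math.ceil(thickness / element_size - 1e-9)))


def _grid_mesh(
    xs: np.ndarray,
    ys: np.ndarray,
    zs: np.ndarray,
    label_grid: np.ndarray,
    tissue_names: list,
    driven_cells: list,
    ground_cells: list,
    face_dir_fn=None,
):
    """Assemble a LabeledMesh from a structured grid.

    ``label_grid`` is (nx, ny, nz) int with -1 marking absent cells;
    ``driven_cells``/``ground_cells`` list (i, j, k) voxel indices whose
    outer face (direction from ``face_dir_fn``, default +z) forms a
    terminal.
    """
    nx, ny, nz = label_grid.shape
    used = label_grid >= 0
    node_id = -np.ones((nx + 1, ny + 1, nz + 1), dtype=np.int64)
    ci, cj, ck = np.nonzero(used)
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                node_id[ci + di, cj + dj, ck + dk] = 0
    flat = node_id.ravel()
    idx = np.nonzero(flat == 0)[0]
    flat[idx] = np.arange(len(idx))
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    coords = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    nodes = coords[idx]

    def nid(i, j, k):
        return node_id[i, j, k]

    elements = np.column_stack(
        [
            nid(ci, cj, ck),
            nid(ci + 1, cj, ck),
            nid(ci + 1, cj + 1, ck),
            nid(ci, cj + 1, ck),
            nid(ci, cj, ck + 1),
            nid(ci + 1, cj, ck + 1),
            nid(ci + 1, cj + 1, ck + 1),
            nid(ci, cj + 1, ck + 1),
        ]
    )
    tissue_ids = label_grid[ci, cj, ck]

    def face_quads(cells):
        quads = []
        for (i, j, k) in cells:
            d = face_dir_fn((i, j, k)) if face_dir_fn else (0, 0, 1)
            if d == (0, 0, 1):
                q = (
                    nid(i, j, k + 1), nid(i + 1, j, k + 1),
                    nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                )
            elif d == (0, 0, -1):
                q = (nid(i, j, k), nid(i + 1, j, k),
                     nid(i + 1, j + 1, k), nid(i, j + 1, k))
            elif d == (1, 0, 0):
                q = (nid(i + 1, j, k), nid(i + 1, j + 1, k),
                     nid(i + 1, j + 1, k + 1), nid(i + 1, j, k + 1))
            elif d == (-1, 0, 0):
                q = (nid(i, j, k), nid(i, j + 1, k),
                     nid(i, j + 1, k + 1), nid(i, j, k + 1))
            elif d == (0, 1, 0):
                q = (nid(i, j + 1, k), nid(i + 1, j + 1, k),
                     nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1))
            else:
                q = (nid(i, j, k), nid(i + 1, j, k),
                     nid(i + 1, j, k + 1), nid(i, j, k + 1))
            quads.append(q)
        return np.asarray(quads, dtype=np.int64)

    return LabeledMesh(
        nodes=nodes,
        elements=elements,
        tissue_ids=tissue_ids.astype(np.int64),
        tissue_names=list(tissue_names),
        driven_faces=face_quads(driven_cells),
        ground_faces=face_quads(ground_cells),
    )


def default_slab_spec(**overrides) -> PhantomSpec:
    """Default layered-slab phantom: 14 x 6.3 cm forehead patch, scalp 7 mm
    (bisected into superficial/deep), skull 7 mm, CSF 3 mm, gray and white
    matter 10 mm each, two full-size pad electrodes, 1.5 mm through-plane
    and 7 mm in-plane resolution."""
    return PhantomSpec(**{"shape": "layered_slab", **overrides})


def default_shell_spec(**overrides) -> PhantomSpec:
    """Concentric-shell phantom (reduced-scale sphere, outer radii in m).

    Electrodes are idealized as polar caps directly on the outer
    superficial-scalp surface; the slab phantom carries the explicit gel
    volume model.
    """
    defaults = dict(
        shape="concentric_shells",
        layers=(
            ("superficial_scalp", 0.060),
            ("deep_scalp", 0.054),
            ("skull", 0.048),
            ("csf", 0.040),
            ("gray_matter", 0.034),
            ("white_matter", 0.026),
        ),
        element_size=0.003,
        in_plane_size=None,
    )
    return PhantomSpec(**{**defaults, **overrides})


def _build_slab(spec: PhantomSpec) -> LabeledMesh:
    lx, ly = spec.slab_size
    ip = spec.plane_size
    nx = max(2, int(round(lx / ip)))
    ny = max(2, int(round(ly / ip)))
    xs = np.linspace(0.0, lx, nx + 1)
    ys = np.linspace(0.0, ly, ny + 1)

    # z levels bottom-up: reverse the outside-in layer list
    zs = [0.0]
    layer_of_cell: list = []
    names = [lab for lab, _ in spec.layers]
    for lab, t in reversed(spec.layers):
        nzl = _subdivide(t, spec.element_size)
        z0 = zs[-1]
        zs.extend(z0 + t * (np.arange(1, nzl + 1) / nzl))
        layer_of_cell.extend([names.index(lab)] * nzl)
    n_tissue_cells = len(layer_of_cell)
    gel_id = len(names)
    names = names + ["gel"]
    ngz = _subdivide(spec.gel_thickness, spec.element_size)
    z0 = zs[-1]
    zs.extend(z0 + spec.gel_thickness * (np.arange(1, ngz + 1) / ngz))
    zs = np.asarray(zs)
    nz = n_tissue_cells + ngz

    label_grid = -np.ones((nx, ny, nz), dtype=np.int64)
    for k, lab_id in enumerate(layer_of_cell):
        label_grid[:, :, k] = lab_id

    # electrode gel columns above the patch footprints (snapped to the grid)
    xc = 0.5 * (xs[:-1] + xs[1:])
    yc = 0.5 * (ys[:-1] + ys[1:])
    patch_masks = []
    for x0, y0, w, h in spec.patches:
        mask = np.outer(
            (xc > x0) & (xc < x0 + w), (yc > y0) & (yc < y0 + h)
        )
        if not mask.any():
            raise ValueError("electrode patch does not cover any surface cell")
        patch_masks.append(mask)
    for mask in patch_masks:
        ii, jj = np.nonzero(mask)
        for k in range(n_tissue_cells, nz):
            label_grid[ii, jj, k] = gel_id

    top = nz - 1
    driven_cells = [(i, j, top) for i, j in zip(*np.nonzero(patch_masks[0]))]
    ground_cells = [(i, j, top) for i, j in zip(*np.nonzero(patch_masks[1]))]
    mesh = _grid_mesh(xs, ys, zs, label_grid, names, driven_cells, ground_cells)
    return mesh


def _build_shells(spec: PhantomSpec) -> LabeledMesh:
    h = spec.element_size
    r_out = spec.layers[0][1]
    n_half = int(math.ceil(r_out / h)) + 1
    n = 2 * n_half
    axis = (np.arange(n) - n_half + 0.5) * h
    grid = np.linspace(-n_half * h, n_half * h, n + 1)
    cx, cy, cz = np.meshgrid(axis, axis, axis, indexing="ij")
    r = np.sqrt(cx**2 + cy**2 + cz**2)

    names = [lab for lab, _ in spec.layers]
    radii = [rad for _, rad in spec.layers]
    label_grid = -np.ones(r.shape, dtype=np.int64)
    inner = radii[1:] + [0.0]
    for lab_id, (ro, ri) in enumerate(zip(radii, inner)):
        label_grid[(r <= ro) & (r > ri)] = lab_id

    # terminal caps: outward boundary faces of superficial-scalp voxels
    # whose centers lie within the cap half-angle of the +/- x poles
    cos_cap = math.cos(math.radians(spec.cap_angle_deg))
    dirs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    driven_cells, ground_cells, cell_dir = [], [], {}
    si, sj, sk = np.nonzero(label_grid == 0)
    for i, j, k in zip(si, sj, sk):
        center = np.array([cx[i, j, k], cy[i, j, k], cz[i, j, k]])
        if abs(center[0]) / np.linalg.norm(center) < cos_cap:
            continue
        best, best_dot = None, 0.0
        for d in dirs:
            ni, nj, nk = i + d[0], j + d[1], k + d[2]
            outside = (
                ni < 0 or nj < 0 or nk < 0 or ni >= n or nj >= n or nk >= n
                or label_grid[ni, nj, nk] < 0
            )
            if outside:
                dot = float(np.dot(d, center))
                if dot > best_dot:
                    best, best_dot = d, dot
        if best is not None:
            cell_dir[(i, j, k)] = best
            (driven_cells if center[0] > 0 else ground_cells).append((i, j, k))

    mesh = _grid_mesh(
        grid, grid, grid, label_grid, names,
        driven_cells, ground_cells,
        face_dir_fn=lambda c: cell_dir[c],
    )
    return mesh


def build_phantom(spec: PhantomSpec, check_connected: bool = True) -> LabeledMesh:
    """Construct the labeled hexahedral mesh for a phantom specification."""
    if spec.shape == "layered_slab":
        mesh = _build_slab(spec)
    else:
        mesh = _build_shells(spec)
    if check_connected:
        mesh.assert_connected()
    return mesh


def build_column(
    layers,
    cross_section: tuple = (0.01, 0.01),
    element_size: float = 0.001,
    n_xy: int = 2,
) -> LabeledMesh:
    """Single-column stack with full-face electrodes on top and bottom.

    The simplest oracle geometry: uniform current enters the whole top face
    and exits the whole bottom face, so the impedance is exactly the series
    sum ``sum_i L_i / (sigma_i * Area)``.  ``layers`` lists (label,
    thickness) top-down.
    """
    lx, ly = cross_section
    xs = np.linspace(0.0, lx, n_xy + 1)
    ys = np.linspace(0.0, ly, n_xy + 1)
    names = [lab for lab, _ in layers]
    zs = [0.0]
    layer_of_cell: list = []
    for lab, t in reversed(list(layers)):
        nzl = _subdivide(t, element_size)
        z0 = zs[-1]
        zs.extend(z0 + t * (np.arange(1, nzl + 1) / nzl))
        layer_of_cell.extend([names.index(lab)] * nzl)
    zs = np.asarray(zs)
    nz = len(layer_of_cell)
    label_grid = -np.ones((n_xy, n_xy, nz), dtype=np.int64)
    for k, lab_id in enumerate(layer_of_cell):
        label_grid[:, :, k] = lab_id
    cells = [(i, j) for i in range(n_xy) for j in range(n_xy)]
    driven = [(i, j, nz - 1) for i, j in cells]
    ground = [(i, j, 0) for i, j in cells]
    dir_of = {c: ((0, 0, 1) if c[2] == nz - 1 else (0, 0, -1)) for c in driven + ground}
    return _grid_mesh(
        xs, ys, zs, label_grid, names, driven, ground,
        face_dir_fn=lambda c: dir_of[c],
    )


def tissue_volumes(mesh: LabeledMesh) -> dict:
    """Total meshed volume per tissue label, m^3."""
    vols = mesh.element_volumes()
    out: dict = {}
    for lab_id, name in enumerate(mesh.tissue_names):
        sel = mesh.tissue_ids == lab_id
        if sel.any():
            out[name] = float(vols[sel].sum())
    return out


# ---------------------------------------------------------------------------
# VTK legacy ASCII I/O with JSON sidecar


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_mesh(mesh: LabeledMesh, path: str | Path) -> None:
    """Write a legacy-ASCII VTK unstructured grid plus a JSON sidecar with
    the tissue-id -> label map and terminal face sets."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("ectsim labeled head phantom\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(mesh.nodes)} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.17g")
        m = mesh.n_elements
        fh.write(f"CELLS {m} {m * 9}\n")
        cells = np.column_stack([np.full(m, 8, dtype=np.int64), mesh.elements])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {m}\n")
        np.savetxt(fh, np.full(m, 12, dtype=np.int64), fmt="%d")
        fh.write(f"CELL_DATA {m}\nSCALARS tissue_id int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, mesh.tissue_ids, fmt="%d")
    sidecar = {
        "tissue_labels": {str(i): name for i, name in enumerate(mesh.tissue_names)},
        "driven_faces": mesh.driven_faces.tolist(),
        "ground_faces": mesh.ground_faces.tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))


def read_mesh(path: str | Path) -> LabeledMesh:
    """Read a mesh written by :func:`write_mesh`.

    Raises if any cell lacks a tissue id or if the sidecar maps ids to
    labels outside the known tissue set.
    """
    path = Path(path)
    tokens = path.read_text().split("\n")
    it = iter(tokens)

    def seek(prefix: str) -> str:
        for line in it:
            if line.startswith(prefix):
                return line
        raise ValueError(f"{path}: missing '{prefix}' section")

    pts_line = seek("POINTS")
    n_pts = int(pts_line.split()[1])
    flat: list = []
    while len(flat) < 3 * n_pts:
        flat.extend(float(v) for v in next(it).split())
    nodes = np.asarray(flat).reshape(n_pts, 3)

    cells_line = seek("CELLS")
    n_cells = int(cells_line.split()[1])
    flat = []
    while len(flat) < 9 * n_cells:
        flat.extend(int(v) for v in next(it).split())
    cells = np.asarray(flat, dtype=np.int64).reshape(n_cells, 9)
    if not np.all(cells[:, 0] == 8):
        raise ValueError(f"{path}: only hexahedron cells are supported")
    elements = cells[:, 1:]

    try:
        seek("CELL_DATA")
        seek("SCALARS tissue_id")
        seek("LOOKUP_TABLE")
    except ValueError as exc:
        raise ValueError(f"{path}: cells lack tissue_id labels") from exc
    flat = []
    for line in it:
        flat.extend(int(v) for v in line.split())
    if len(flat) < n_cells:
        raise ValueError(
            f"{path}: {n_cells - len(flat)} cell(s) lack a tissue_id label"
        )
    tissue_ids = np.asarray(flat[:n_cells], dtype=np.int64)

    sidecar = json.loads(_sidecar_path(path).read_text())
    id_map = {int(k): v for k, v in sidecar["tissue_labels"].items()}
    names = [id_map[i] for i in sorted(id_map)]
    unknown = sorted(set(names) - KNOWN_LABELS)
    if unknown:
        raise ValueError(f"{path}: unknown tissue label(s): {', '.join(unknown)}")
    return LabeledMesh(
        nodes=nodes,
        elements=elements,
        tissue_ids=tissue_ids,
        tissue_names=names,
        driven_faces=np.asarray(sidecar["driven_faces"], dtype=np.int64),
        ground_faces=np.asarray(sidecar["ground_faces"], dtype=np.int64),
    )
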