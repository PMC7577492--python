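"""Deterministic structured quadrilateral meshing of the model geometry.

The cell is meshed as concentric structured rings sharing a single
circumferential division count (so all cell parts are tied through shared
nodes): a butterfly (square core + four transfinite transition blocks) for
the nucleus interior, annular layers for the nuclear membrane, cytoplasm
and cell membrane.  Each tissue block is a tensor-product grid graded
toward the pore wall and the entrance.  Node numbering follows sorted
geometric construction order, so identical configurations produce
byte-identical meshes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from squeezefem.config import GeometryParams, MeshSpec
from squeezefem.geometry import PART_IDS, Regions, build_geometry


class MeshError(RuntimeError):
    pass


@dataclass
class Mesh:
    nodes: np.ndarray  # (N, 2) float64, um
    elements: np.ndarray  # (E, 4) int32, positively oriented
    part: np.ndarray  # (E,) int16 into geometry.PART_NAMES
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    rings: dict[str, np.ndarray] = field(default_factory=dict)  # ordered node-id loops
    contact_master_segments: np.ndarray | None = None  # (M, 2) node ids, CCW around tissue
    ring_thetas: np.ndarray | None = None  # reference angles of circumferential divisions
    cell_center: tuple[float, float] = (0.0, 0.0)
    regions: Regions | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_areas(self) -> np.ndarray:
        x = self.nodes[self.elements]  # (E,4,2)
        x0, x1, x2, x3 = x[:, 0], x[:, 1], x[:, 2], x[:, 3]
        cross = lambda a, b: a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
        return 0.5 * (cross(x1 - x0, x2 - x0) + cross(x2 - x0, x3 - x0))

    def part_areas(self) -> dict[str, float]:
        areas = self.element_areas()
        out = {}
        for name, pid in PART_IDS.items():
            out[name] = float(areas[self.part == pid].sum())
        return out

    def element_quality(self) -> np.ndarray:
        """Per-element min/max edge-length ratio."""
        x = self.nodes[self.elements]
        edges = np.stack(
            [x[:, (i + 1) % 4] - x[:, i] for i in range(4)], axis=1
        )  # (E,4,2)
        lengths = np.linalg.norm(edges, axis=2)
        return lengths.min(axis=1) / lengths.max(axis=1)


class _NodeRegistry:
    """Deduplicating node store keyed by rounded coordinates."""

    def __init__(self, tol: float = 1e-9):
        self.scale = 1.0 / tol
        self._ids: dict[tuple[int, int], int] = {}
        self.coords: list[tuple[float, float]] = []

    def add(self, x: float, y: float) -> int:
        key = (round(x * self.scale), round(y * self.scale))
        nid = self._ids.get(key)
        if nid is None:
            nid = len(self.coords)
            self._ids[key] = nid
            self.coords.append((x, y))
        return nid

    def array(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=np.float64)


def _grid_quads(ids: np.ndarray) -> list[list[int]]:
    """Quads from an (nu+1, nv+1) array of node ids."""
    quads = []
    nu, nv = ids.shape[0] - 1, ids.shape[1] - 1
    for i in range(nu):
        for j in range(nv):
            quads.append([ids[i, j], ids[i + 1, j], ids[i + 1, j + 1], ids[i, j + 1]])
    return quads


def _butterfly_disk(reg: _NodeRegistry, cx: float, cy: float, r: float,
                    n_theta: int, n_side: int, n_rad: int) -> list[list[int]]:
    """Structured quad mesh of a disk: square core + 4 transfinite blocks.

    The disk boundary carries exactly ``n_theta`` uniformly spaced nodes
    (starting at +x), shared with the surrounding annulus.
    """
    assert n_theta == 4 * n_side
    s = 0.5 * r  # half-width of the core square
    quads: list[list[int]] = []

    # core square grid
    us = np.linspace(-1.0, 1.0, n_side + 1)
    core = np.empty((n_side + 1, n_side + 1), dtype=np.int64)
    for i, u in enumerate(us):
        for j, v in enumerate(us):
            core[i, j] = reg.add(cx + s * u, cy + s * v)
    quads += _grid_quads(core)

    # transition blocks; quadrant q spans boundary angles (2q-1)*45 .. (2q+1)*45 deg
    for q in range(4):
        k0 = q * n_side - n_side // 2  # global theta index at the quadrant start
        inner = np.empty((n_side + 1, 2))
        for i, u in enumerate(us):
            if q == 0:
                inner[i] = (s, s * u)
            elif q == 1:
                inner[i] = (-s * u, s)
            elif q == 2:
                inner[i] = (-s, -s * u)
            else:
                inner[i] = (s * u, -s)
        ids = np.empty((n_side + 1, n_rad + 1), dtype=np.int64)
        for i in range(n_side + 1):
            th = 2.0 * np.pi * ((k0 + i) % n_theta) / n_theta
            outer = np.array([r * np.cos(th), r * np.sin(th)])
            for j in range(n_rad + 1):
                w = j / n_rad
                p = (1.0 - w) * inner[i] + w * outer
                ids[i, j] = reg.add(cx + p[0], cy + p[1])
        quads += _grid_quads(ids)
    return quads


def _annulus(reg: _NodeRegistry, cx: float, cy: float, radii: np.ndarray,
             n_theta: int) -> list[list[int]]:
    """Structured annulus with given radial node positions."""
    nr = len(radii)
    ids = np.empty((nr, n_theta), dtype=np.int64)
    for j, r in enumerate(radii):
        for k in range(n_theta):
            th = 2.0 * np.pi * k / n_theta
            ids[j, k] = reg.add(cx + r * np.cos(th), cy + r * np.sin(th))
    quads = []
    for j in range(nr - 1):
        for k in range(n_theta):
            k1 = (k + 1) % n_theta
            quads.append([ids[j, k], ids[j + 1, k], ids[j + 1, k1], ids[j, k1]])
    return quads


def _sinh_spacing(length: float, n: int, beta: float) -> np.ndarray:
    """Monotone grading on [0, length], fine near 0."""
    xi = np.linspace(0.0, 1.0, n + 1)
    return length * np.sinh(beta * xi) / np.sinh(beta)


def _ring_ids(reg: _NodeRegistry, cx: float, cy: float, r: float, n_theta: int) -> np.ndarray:
    ids = np.empty(n_theta, dtype=np.int64)
    for k in range(n_theta):
        th = 2.0 * np.pi * k / n_theta
        ids[k] = reg.add(cx + r * np.cos(th), cy + r * np.sin(th))
    return ids


def generate_mesh(regions: Regions, spec: MeshSpec) -> Mesh:
    """Generate the conforming quadrilateral mesh for the full model.

    Cell parts share nodes at their interfaces (tied); the cell/tissue
    interface is meshed independently (contact pair).  Raises
    :class:`MeshError` on degenerate input or quality failure.
    """
    eff = spec.resolve()
    g = regions.params
    cx, cy = regions.cell_center
    r = regions.radii
    n_theta = eff["n_circumferential"]
    n_side = n_theta // 4
    core_div = eff["core_divisions"]
    if core_div != n_side:
        # the butterfly requires core divisions = n_theta/4; honour n_theta
        core_div = n_side
    n_mem = eff["membrane_layers"]
    n_cyt = eff["cytoplasm_layers"]

    reg = _NodeRegistry()
    quads: list[list[int]] = []
    parts: list[int] = []

    def add_part(qs: list[list[int]], name: str) -> None:
        quads.extend(qs)
        parts.extend([PART_IDS[name]] * len(qs))

    # --- cell ---
    add_part(
        _butterfly_disk(reg, cx, cy, r["nucleus_inner"], n_theta, n_side, eff["core_radial_layers"]),
        "nucleus",
    )
    add_part(
        _annulus(reg, cx, cy, np.linspace(r["nucleus_inner"], r["nucleus_outer"], n_mem + 1), n_theta),
        "nuclear_membrane",
    )
    add_part(
        _annulus(reg, cx, cy, np.linspace(r["nucleus_outer"], r["cell_inner"], n_cyt + 1), n_theta),
        "cytoplasm",
    )
    add_part(
        _annulus(reg, cx, cy, np.linspace(r["cell_inner"], r["cell_outer"], n_mem + 1), n_theta),
        "cell_membrane",
    )

    # ordered rings (theta order, starting at +x)
    rings = {
        "nuclear_membrane_inner_ring": _ring_ids(reg, cx, cy, r["nucleus_inner"], n_theta),
        "nuclear_membrane_outer_ring": _ring_ids(reg, cx, cy, r["nucleus_outer"], n_theta),
        "cell_inner_ring": _ring_ids(reg, cx, cy, r["cell_inner"], n_theta),
        "cell_outer_ring": _ring_ids(reg, cx, cy, r["cell_outer"], n_theta),
    }

    # --- tissues ---
    nx, ny = eff["tissue_nx"], eff["tissue_ny"]
    gap = g.pore_diameter / 2.0
    xs = _sinh_spacing(g.tissue_block_width, nx, beta=2.5)
    ys = _sinh_spacing(g.tissue_block_height, ny, beta=3.2)

    tissue_ids = {}
    for name, sign in (("tissue1", 1.0), ("tissue2", -1.0)):
        ids = np.empty((nx + 1, ny + 1), dtype=np.int64)
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                ids[i, j] = reg.add(x, sign * (gap + y))
        add_part(_grid_quads(ids), name)
        tissue_ids[name] = ids

    nodes = reg.array()
    elements = np.asarray(quads, dtype=np.int32)
    part = np.asarray(parts, dtype=np.int16)

    # enforce positive orientation
    x = nodes[elements]
    a = 0.5 * (
        (x[:, 1, 0] - x[:, 0, 0]) * (x[:, 2, 1] - x[:, 0, 1])
        - (x[:, 1, 1] - x[:, 0, 1]) * (x[:, 2, 0] - x[:, 0, 0])
        + (x[:, 2, 0] - x[:, 0, 0]) * (x[:, 3, 1] - x[:, 0, 1])
        - (x[:, 2, 1] - x[:, 0, 1]) * (x[:, 3, 0] - x[:, 0, 0])
    )
    flip = a < 0
    elements[flip] = elements[flip][:, ::-1]

    # corner Jacobian check
    if not _all_corners_positive(nodes, elements):
        raise MeshError("mesh contains elements with non-positive corner Jacobians")

    # --- node sets ---
    thetas = 2.0 * np.pi * np.arange(n_theta) / n_theta
    w, gp = g.tissue_block_width, gap
    t1, t2 = tissue_ids["tissue1"], tissue_ids["tissue2"]
    lateral = np.concatenate([t1[0, :], t1[-1, :], t2[0, :], t2[-1, :]])
    transverse = np.concatenate([t1[:, -1], t2[:, -1]])
    wall1 = t1[:, 0]  # upper wall, x ascending
    wall2 = t2[:, 0]
    arc = np.abs(np.angle(np.exp(1j * thetas))) <= np.pi / 4 + 1e-12
    node_sets = {
        "leading_edge": rings["cell_outer_ring"][arc],
        "tissue_outer_lateral": np.unique(lateral).astype(np.int64),
        "tissue_outer_transverse": np.unique(transverse).astype(np.int64),
        "nuclear_membrane_inner_ring": rings["nuclear_membrane_inner_ring"],
        "nuclear_membrane_outer_ring": rings["nuclear_membrane_outer_ring"],
        "pore_faces": np.unique(np.concatenate([wall1, wall2, t1[0, :], t2[0, :]])).astype(np.int64),
        "cell_outer_ring": rings["cell_outer_ring"],
        "tissue1_wall": wall1.astype(np.int64),
        "tissue2_wall": wall2.astype(np.int64),
    }

    # --- contact master segments: CCW around each tissue block so the
    # outward normal (t_y, -t_x) points into the channel / at the cell ---
    segs = []
    # upper block CCW: wall left->right is the bottom edge; left face top->bottom
    for i in range(len(wall1) - 1):  # wall y=+gap, traversed +x
        segs.append((t1[i, 0], t1[i + 1, 0]))
    for j in range(t1.shape[1] - 1, 0, -1):  # left face x=0, traversed -y
        segs.append((t1[0, j], t1[0, j - 1]))
    # lower block CCW: left face bottom->top (-x normal), wall right->left (+y normal)
    for j in range(1, t2.shape[1]):
        segs.append((t2[0, j - 1], t2[0, j]))
    for i in range(len(wall2) - 1, 0, -1):
        segs.append((t2[i, 0], t2[i - 1, 0]))
    contact_master = np.asarray(segs, dtype=np.int32)

    mesh = Mesh(
        nodes=nodes,
        elements=elements,
        part=part,
        node_sets=node_sets,
        rings=rings,
        contact_master_segments=contact_master,
        ring_thetas=thetas,
        cell_center=(cx, cy),
        regions=regions,
    )

    # quality gate
    q = mesh.element_quality()
    if q.min() < eff["min_quality"]:
        raise MeshError(
            f"rest-mesh quality {q.min():.4f} below threshold {eff['min_quality']}"
        )
    # area audit (1% tolerance)
    areas = mesh.part_areas()
    for name, ref in regions.analytic_areas.items():
        if abs(areas[name] - ref) > 0.01 * ref:
            raise MeshError(f"part {name} area {areas[name]:.4f} deviates >1% from {ref:.4f}")
    return mesh


def _all_corners_positive(nodes: np.ndarray, elements: np.ndarray) -> bool:
    x = nodes[elements]  # (E,4,2)
    ok = True
    for c in range(4):
        p0 = x[:, c]
        p1 = x[:, (c + 1) % 4]
        p3 = x[:, (c - 1) % 4]
        cr = (p1[:, 0] - p0[:, 0]) * (p3[:, 1] - p0[:, 1]) - (p1[:, 1] - p0[:, 1]) * (
            p3[:, 0] - p0[:, 0]
        )
        ok &= bool((cr > 0).all())
    return ok


def mesh_from_config(cfg) -> Mesh:
    """Convenience: geometry + mesh straight from a SimulationConfig."""
    return generate_mesh(build_geometry(cfg.geometry), cfg.mesh)


def write_vtk(mesh: Mesh, path, point_data: dict | None = None, cell_data: dict | None = None) -> None:
    """Write a legacy-ASCII VTK unstructured grid with part labels."""
    buf = io.StringIO()
    buf.write("# vtk DataFile Version 3.0\nsqueezefem mesh\nASCII\nDATASET UNSTRUCTURED_GRID\n")
    buf.write(f"POINTS {mesh.n_nodes} double\n")
    for x, y in mesh.nodes:
        buf.write(f"{x:.9g} {y:.9g} 0\n")
    ne = mesh.n_elements
    buf.write(f"CELLS {ne} {5 * ne}\n")
    for el in mesh.elements:
        buf.write(f"4 {el[0]} {el[1]} {el[2]} {el[3]}\n")
    buf.write(f"CELL_TYPES {ne}\n")
    buf.write("\n".join(["9"] * ne) + "\n")
    buf.write(f"CELL_DATA {ne}\nSCALARS part int 1\nLOOKUP_TABLE default\n")
    buf.write("\n".join(str(int(p)) for p in mesh.part) + "\n")
    if cell_data:
        for name, arr in cell_data.items():
            buf.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            buf.write("\n".join(f"{v:.9g}" for v in np.asarray(arr)) + "\n")
    if point_data:
        buf.write(f"POINT_DATA {mesh.n_nodes}\n")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 2:
                buf.write(f"VECTORS {name} double\n")
                for vx, vy in arr:
                    buf.write(f"{vx:.9g} {vy:.9g} 0\n")
            else:
                buf.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                buf.write("\n".join(f"{v:.9g}" for v in arr) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
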