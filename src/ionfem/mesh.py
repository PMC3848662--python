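"""Triangular meshes of the elliptical cell domain.

The computational domain is an ellipse (x/a)^2 + (y/b)^2 <= 1 representing a
biological cell; its boundary is the cell membrane.  Meshes are conforming P1
triangulations with node indices partitioned into membrane (boundary) nodes and
interior nodes.  Generation places boundary nodes at equal arc-length spacing
on the ellipse, fills the interior with staggered concentric elliptical rings
of points, and triangulates with a Delaunay triangulation (valid because the
domain is convex).  The construction is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "TriMesh",
    "MeshTopologyError",
    "generate_ellipse_mesh",
    "classify_boundary",
    "build_trimesh",
    "nearest_node",
    "read_msh",
    "write_msh",
    "read_node_ele",
    "write_node_ele",
]

#: relative tolerance for on-boundary membership tests
BOUNDARY_TOL = 1e-8


class MeshTopologyError(ValueError):
    """Raised when a triangulation is not a conforming 2-manifold with boundary."""


@dataclass
class TriMesh:
    """A conforming triangulation of a planar domain.

    Attributes
    ----------
    nodes : (m, 2) float array
        Node coordinates in simulation length units.
    triangles : (nel, 3) int array
        Node indices per element, counter-clockwise.
    boundary_nodes : int array
        Indices of nodes on the membrane (edges owned by a single element).
    interior_nodes : int array
        Complementary index set.
    h : float
        Mesh size: the maximum over elements of the longest edge length.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    boundary_nodes: np.ndarray = field(default=None)  # type: ignore[assignment]
    interior_nodes: np.ndarray = field(default=None)  # type: ignore[assignment]
    h: float = field(default=None)  # type: ignore[assignment]

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.triangles.shape[0]

    def signed_areas(self) -> np.ndarray:
        """Signed area of every triangle (positive for CCW orientation)."""
        p = self.nodes[self.triangles]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def area(self) -> float:
        """Total mesh area (shoelace sum over elements)."""
        return float(np.sum(self.signed_areas()))


def _edge_counts(triangles: np.ndarray) -> dict[tuple[int, int], int]:
    counts: dict[tuple[int, int], int] = {}
    for tri in triangles:
        for k in range(3):
            i, j = int(tri[k]), int(tri[(k + 1) % 3])
            key = (i, j) if i < j else (j, i)
            counts[key] = counts.get(key, 0) + 1
    return counts


def classify_boundary(
    nodes, triangles: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Partition node indices into boundary set Y0 and interior set Y.

    Accepts either a :class:`TriMesh` or explicit (nodes, triangles) arrays.
    A node is a boundary node iff it lies on an edge that belongs to exactly
    one triangle.  Raises :class:`MeshTopologyError` if any edge belongs to
    more than two triangles (non-conforming mesh).
    """
    if isinstance(nodes, TriMesh):
        nodes, triangles = nodes.nodes, nodes.triangles
    counts = _edge_counts(np.asarray(triangles))
    boundary: set[int] = set()
    for (i, j), c in counts.items():
        if c > 2:
            raise MeshTopologyError(
                f"edge ({i}, {j}) belongs to {c} triangles; mesh is non-conforming"
            )
        if c == 1:
            boundary.add(i)
            boundary.add(j)
    m = np.asarray(nodes).shape[0]
    y0 = np.array(sorted(boundary), dtype=np.int64)
    mask = np.ones(m, dtype=bool)
    mask[y0] = False
    y = np.nonzero(mask)[0]
    return y0, y


def _mesh_size(nodes: np.ndarray, triangles: np.ndarray) -> float:
    p = nodes[triangles]
    e0 = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
    e1 = np.linalg.norm(p[:, 2] - p[:, 1], axis=1)
    e2 = np.linalg.norm(p[:, 0] - p[:, 2], axis=1)
    return float(np.max(np.stack([e0, e1, e2])))


def build_trimesh(nodes: np.ndarray, triangles: np.ndarray) -> TriMesh:
    """Assemble a :class:`TriMesh` from raw arrays.

    Orients every triangle counter-clockwise, classifies boundary vs interior
    nodes and computes the mesh size h.
    """
    nodes = np.ascontiguousarray(np.asarray(nodes, dtype=float))
    triangles = np.ascontiguousarray(np.asarray(triangles, dtype=np.int64))
    if nodes.ndim != 2 or nodes.shape[1] != 2:
        raise ValueError("nodes must be an (m, 2) array")
    if triangles.ndim != 2 or triangles.shape[1] != 3:
        raise ValueError("triangles must be an (nel, 3) array")
    mesh = TriMesh(nodes=nodes, triangles=triangles)
    areas = mesh.signed_areas()
    flip = areas < 0
    if np.any(flip):
        triangles[flip] = triangles[flip][:, [0, 2, 1]]
        areas = mesh.signed_areas()
    if np.any(areas <= 0):
        raise MeshTopologyError("degenerate triangle with non-positive area")
    y0, y = classify_boundary(nodes, triangles)
    mesh.boundary_nodes = y0
    mesh.interior_nodes = y
    mesh.h = _mesh_size(nodes, triangles)
    return mesh


def _ellipse_arclength_angles(a: float, b: float, n: int, offset: float) -> np.ndarray:
    """Angles t such that (a cos t, b sin t) are equally spaced in arc length.

    ``offset`` shifts the starting point by a fraction of one spacing
    (used to stagger successive rings).
    """
    tt = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
    dt = tt[1] - tt[0]
    speed = np.hypot(a * np.sin(tt), b * np.cos(tt))
    s = np.concatenate([[0.0], np.cumsum(speed) * dt])
    total = s[-1]
    targets = (np.arange(n) + offset) / n * total
    grid = np.concatenate([tt, [2.0 * np.pi]])
    return np.interp(targets % total, s, grid)


def generate_ellipse_mesh(a: float, b: float, h_target: float) -> TriMesh:
    """Deterministic triangulation of the ellipse with semi-axes a, b.

    Boundary nodes are placed exactly on the ellipse at arc-length spacing
    about 0.8*h_target; interior nodes on staggered concentric rings; the
    resulting Delaunay mesh satisfies h <= 1.25*h_target and contains the
    center (0, 0) as a node (probe anchor).
    """
    if a <= 0 or b <= 0 or h_target <= 0:
        raise ValueError("a, b and h_target must be positive")
    if h_target >= min(a, b):
        raise ValueError("h_target must be smaller than min(a, b)")
    spacing = 0.8 * h_target
    nr = max(2, int(np.ceil(max(a, b) / spacing)))
    pts = [(0.0, 0.0)]
    n_outer = None
    for j in range(1, nr + 1):
        t = j / nr
        ra, rb = t * a, t * b
        # Ramanujan perimeter approximation, adequate for point counting
        hsq = ((ra - rb) / (ra + rb)) ** 2
        per = np.pi * (ra + rb) * (1 + 3 * hsq / (10 + np.sqrt(4 - 3 * hsq)))
        n = max(6, int(np.ceil(per / spacing)))
        offset = 0.5 * (j % 2)
        ang = _ellipse_arclength_angles(ra, rb, n, offset)
        ring = np.column_stack([ra * np.cos(ang), rb * np.sin(ang)])
        if j == nr:
            n_outer = n
            # boundary nodes exactly on the ellipse, no stagger (deterministic)
            ang = _ellipse_arclength_angles(a, b, n, 0.0)
            ring = np.column_stack([a * np.cos(ang), b * np.sin(ang)])
        pts.append(ring)
    points = np.vstack([np.atleast_2d(pts[0])] + pts[1:])
    # snap tiny coordinates to zero for reproducible text round trips
    points[np.abs(points) < 1e-14] = 0.0
    tri = Delaunay(points)
    mesh = build_trimesh(points, tri.simplices)
    assert n_outer is not None
    return mesh


def nearest_node(mesh: TriMesh, point) -> int:
    """Index of the mesh node nearest to ``point``; ties broken by lowest index."""
    d = np.linalg.norm(mesh.nodes - np.asarray(point, dtype=float), axis=1)
    return int(np.argmin(d))  # argmin returns the first (lowest) index on ties


# ---------------------------------------------------------------------------
# File formats: Gmsh MSH 2.2 ASCII and a plain two-file node/element format
# ---------------------------------------------------------------------------


def write_msh(mesh: TriMesh, path) -> None:
    """Write the mesh in Gmsh MSH 2.2 ASCII format (triangles only)."""
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{mesh.n_nodes}\n")
        for i, (x, y) in enumerate(mesh.nodes, start=1):
            fh.write(f"{i} {float(x)!r} {float(y)!r} 0\n")
        fh.write("$EndNodes\n")
        fh.write(f"$Elements\n{mesh.n_elements}\n")
        for k, (n1, n2, n3) in enumerate(mesh.triangles + 1, start=1):
            fh.write(f"{k} 2 2 0 1 {n1} {n2} {n3}\n")
        fh.write("$EndElements\n")


def read_msh(path) -> TriMesh:
    """Read a Gmsh MSH 2.2 ASCII mesh (2D triangles; other elements ignored)."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    try:
        i_nodes = lines.index("$Nodes")
        i_elems = lines.index("$Elements")
    except ValueError as exc:
        raise ValueError(f"{path}: not a MSH 2.2 ASCII file") from exc
    n_nodes = int(lines[i_nodes + 1])
    nodes = np.empty((n_nodes, 2))
    for row, ln in enumerate(lines[i_nodes + 2 : i_nodes + 2 + n_nodes]):
        parts = ln.split()
        nodes[row] = (float(parts[1]), float(parts[2]))
    n_elems = int(lines[i_elems + 1])
    tris = []
    for ln in lines[i_elems + 2 : i_elems + 2 + n_elems]:
        parts = ln.split()
        etype = int(parts[1])
        if etype != 2:  # only 3-node triangles
            continue
        ntags = int(parts[2])
        conn = [int(v) - 1 for v in parts[3 + ntags : 6 + ntags]]
        tris.append(conn)
    return build_trimesh(nodes, np.array(tris, dtype=np.int64))


def write_node_ele(mesh: TriMesh, node_path, ele_path) -> None:
    """Write the plain two-file text format: 'index x y' / 'index n1 n2 n3' (1-based)."""
    with open(node_path, "w") as fh:
        for i, (x, y) in enumerate(mesh.nodes, start=1):
            fh.write(f"{i} {float(x)!r} {float(y)!r}\n")
    with open(ele_path, "w") as fh:
        for k, (n1, n2, n3) in enumerate(mesh.triangles + 1, start=1):
            fh.write(f"{k} {n1} {n2} {n3}\n")


def read_node_ele(node_path, ele_path) -> TriMesh:
    """Read the plain two-file node/element text format (1-based indices)."""
    nodes = []
    with open(node_path) as fh:
        for ln in fh:
            parts = ln.split()
            if parts:
                nodes.append((float(parts[1]), float(parts[2])))
    tris = []
    with open(ele_path) as fh:
        for ln in fh:
            parts = ln.split()
            if parts:
                tris.append([int(parts[1]) - 1, int(parts[2]) - 1, int(parts[3]) - 1])
    return build_trimesh(np.array(nodes), np.array(tris, dtype=np.int64))
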