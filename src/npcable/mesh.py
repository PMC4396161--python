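"""Triangulations of the elliptical cell domain.

Provides a deterministic built-in mesher (concentric elliptical rings of
points triangulated with Delaunay — the ellipse is convex so every simplex is
interior), midpoint uniform refinement, mesh-size and quality metrics, and
Gmsh MSH v2.2 ASCII read/write with physical tags for the boundary loop and
the interior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "TriangleMesh",
    "generate_ellipse_mesh",
    "mesh_size",
    "refine",
    "mesh_quality",
    "read_msh",
    "write_msh",
    "MshParseError",
]


class MshParseError(ValueError):
    """Raised when a Gmsh MSH file is malformed; names the offending section."""


@dataclass
class TriangleMesh:
    """An oriented 2D triangle mesh.

    Attributes
    ----------
    nodes : (n, 2) float array of vertex coordinates.
    triangles : (m, 3) int array of vertex indices, counter-clockwise.
    boundary_edges : (k, 2) int array of edges that belong to exactly one
        triangle; for a valid mesh of a simply connected domain these form a
        single closed loop.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    boundary_edges: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 2)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.triangles.size and (self.triangles.min() < 0
                                    or self.triangles.max() >= len(self.nodes)):
            raise ValueError("triangle node indices out of range")
        self._orient()
        if self.boundary_edges is None:
            self.boundary_edges = self._find_boundary_edges()
        else:
            self.boundary_edges = np.asarray(self.boundary_edges,
                                             dtype=np.int64).reshape(-1, 2)

    def _orient(self) -> None:
        a = self.signed_areas()
        flip = a < 0
        if flip.any():
            tri = self.triangles.copy()
            tri[flip, 1], tri[flip, 2] = self.triangles[flip, 2], self.triangles[flip, 1]
            self.triangles = tri
        if (self.signed_areas() <= 0).any():
            raise ValueError("mesh contains degenerate (zero-area) triangles")

    def signed_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                      - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))

    def _find_boundary_edges(self) -> np.ndarray:
        tri = self.triangles
        edges = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
        key = np.sort(edges, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True,
                                   return_counts=True)
        return edges[idx[counts == 1]]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def boundary_nodes(self) -> np.ndarray:
        """Sorted indices of nodes lying on the boundary loop."""
        return np.unique(self.boundary_edges)

    def area(self) -> float:
        return float(self.signed_areas().sum())

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation.

        Positive orientation, in-range indices, no orphaned nodes, and
        boundary edges forming a single closed loop (every boundary node has
        exactly two incident boundary edges and the loop is connected).
        """
        if (self.signed_areas() <= 0).any():
            raise ValueError("non-positive triangle area")
        used = np.zeros(self.n_nodes, dtype=bool)
        used[self.triangles.ravel()] = True
        if not used.all():
            raise ValueError(f"orphaned nodes: {np.flatnonzero(~used)[:10]}")
        bn = self.boundary_nodes
        deg = np.zeros(self.n_nodes, dtype=int)
        for a, b in self.boundary_edges:
            deg[a] += 1
            deg[b] += 1
        if (deg[bn] != 2).any():
            raise ValueError("boundary is not a collection of closed loops")
        # connectivity of the boundary loop
        adj: dict[int, list[int]] = {}
        for a, b in self.boundary_edges:
            adj.setdefault(int(a), []).append(int(b))
            adj.setdefault(int(b), []).append(int(a))
        start = int(bn[0])
        seen = {start}
        stack = [start]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if len(seen) != len(bn):
            raise ValueError("boundary edges form more than one loop")

    def nearest_node(self, point) -> int:
        p = np.asarray(point, dtype=float)
        return int(np.argmin(((self.nodes - p) ** 2).sum(axis=1)))


def _ellipse_perimeter(a: float, b: float) -> float:
    # Ramanujan's approximation, ample for choosing point counts
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def generate_ellipse_mesh(a: float, b: float, h_target: float) -> TriangleMesh:
    """Deterministic triangulation of the ellipse x^2/a^2 + y^2/b^2 <= 1.

    Points are laid on concentric elliptical rings (outermost exactly on the
    ellipse) with spacing ~``h_target`` both radially and circumferentially,
    staggered between rings, and triangulated with Delaunay; since the point
    cloud's convex hull is the outer ring polygon, every triangle is interior.
    The cell center is at the origin (0, 0).
    """
    if not (a >= b > 0):
        raise ValueError(f"require a >= b > 0, got a={a!r}, b={b!r}")
    if not (0 < h_target < b):
        raise ValueError(f"require 0 < h_target < b, got {h_target!r}")
    n_rings = max(2, math.ceil(a / h_target))
    perim = _ellipse_perimeter(a, b)
    pts = [(0.0, 0.0)]
    for j in range(1, n_rings + 1):
        r = j / n_rings
        m = max(8, math.ceil(r * perim / h_target))
        # stagger alternate rings by half a spacing for near-equilateral cells
        theta = 2.0 * math.pi * (np.arange(m) + 0.5 * (j % 2)) / m
        pts.append(np.column_stack([a * r * np.cos(theta),
                                    b * r * np.sin(theta)]))
    nodes = np.vstack([np.atleast_2d(p) for p in pts])
    tri = Delaunay(nodes)
    # drop degenerate slivers (collinear ring points can produce zero area)
    p = nodes[tri.simplices]
    areas = 0.5 * np.abs((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                         - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    simplices = tri.simplices[areas > 1e-14 * max(a, b) ** 2]
    mesh = TriangleMesh(nodes, simplices)
    mesh.validate()
    return mesh


def mesh_size(mesh: TriangleMesh) -> float:
    """h(T_h) = max over elements of the largest pairwise vertex distance."""
    if mesh.n_triangles == 0:
        raise ValueError("empty mesh has no mesh size")
    p = mesh.nodes[mesh.triangles]
    d01 = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    d12 = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    d20 = np.linalg.norm(p[:, 2] - p[:, 0], axis=1)
    return float(np.max(np.stack([d01, d12, d20])))


def refine(mesh: TriangleMesh) -> TriangleMesh:
    """Uniform midpoint (red) refinement: each triangle split into four."""
    tri = mesh.triangles
    edges = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    uniq, inverse = np.unique(key, axis=0, return_inverse=True)
    mid = 0.5 * (mesh.nodes[uniq[:, 0]] + mesh.nodes[uniq[:, 1]])
    mid_idx = mesh.n_nodes + np.arange(len(uniq))
    m01, m12, m20 = (mid_idx[inverse[i * len(tri):(i + 1) * len(tri)]]
                     for i in range(3))
    new_tri = np.vstack([
        np.column_stack([tri[:, 0], m01, m20]),
        np.column_stack([tri[:, 1], m12, m01]),
        np.column_stack([tri[:, 2], m20, m12]),
        np.column_stack([m01, m12, m20]),
    ])
    return TriangleMesh(np.vstack([mesh.nodes, mid]), new_tri)


def mesh_quality(mesh: TriangleMesh) -> dict:
    """Quality report: achieved h, min angle (deg), total area, element count."""
    p = mesh.nodes[mesh.triangles]
    angles = []
    for i in range(3):
        u = p[:, (i + 1) % 3] - p[:, i]
        v = p[:, (i + 2) % 3] - p[:, i]
        cosang = (u * v).sum(axis=1) / (np.linalg.norm(u, axis=1)
                                        * np.linalg.norm(v, axis=1))
        angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    return {
        "n_nodes": mesh.n_nodes,
        "n_triangles": mesh.n_triangles,
        "h": mesh_size(mesh),
        "min_angle_deg": float(np.min(angles)),
        "area": mesh.area(),
    }


# ---------------------------------------------------------------------------
# Gmsh MSH v2.2 ASCII I/O.  Element type 1 = 2-node line (boundary, physical
# tag 1), type 2 = 3-node triangle (interior, physical tag 2).  Node ids are
# written 1-based.
# ---------------------------------------------------------------------------

def write_msh(mesh: TriangleMesh, path) -> None:
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat",
             "$PhysicalNames", "2",
             '1 1 "boundary"', '2 2 "domain"',
             "$EndPhysicalNames",
             "$Nodes", str(mesh.n_nodes)]
    for i, (x, y) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {float(x)!r} {float(y)!r} 0")
    ne = len(mesh.boundary_edges) + mesh.n_triangles
    lines += ["$EndNodes", "$Elements", str(ne)]
    eid = 1
    for aa, bb in mesh.boundary_edges:
        lines.append(f"{eid} 1 2 1 1 {aa + 1} {bb + 1}")
        eid += 1
    for t in mesh.triangles:
        lines.append(f"{eid} 2 2 2 2 {t[0] + 1} {t[1] + 1} {t[2] + 1}")
        eid += 1
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_msh(path) -> TriangleMesh:
    with open(path) as fh:
        text = fh.read().splitlines()
    sections: dict[str, list[str]] = {}
    i = 0
    while i < len(text):
        line = text[i].strip()
        if line.startswith("$") and not line.startswith("$End"):
            name = line[1:]
            end = f"$End{name}"
            j = i + 1
            body = []
            while j < len(text) and text[j].strip() != end:
                body.append(text[j])
                j += 1
            if j == len(text):
                raise MshParseError(f"section ${name} is not terminated")
            sections[name] = body
            i = j + 1
        else:
            i += 1
    for required in ("MeshFormat", "Nodes", "Elements"):
        if required not in sections:
            raise MshParseError(f"missing ${required} section")
    fmt = sections["MeshFormat"][0].split()
    if not fmt or not fmt[0].startswith("2."):
        raise MshParseError("MeshFormat: only MSH v2.x ASCII is supported")
    body = sections["Nodes"]
    try:
        n_nodes = int(body[0])
        raw = [ln.split() for ln in body[1:1 + n_nodes]]
        ids = np.array([int(r[0]) for r in raw])
        coords = np.array([[float(r[1]), float(r[2])] for r in raw])
    except (ValueError, IndexError) as exc:
        raise MshParseError(f"Nodes: malformed node record ({exc})") from exc
    order = np.argsort(ids)
    id_map = {int(ids[k]): pos for pos, k in enumerate(order)}
    nodes = coords[order]
    body = sections["Elements"]
    tris, bedges = [], []
    try:
        n_elem = int(body[0])
        for ln in body[1:1 + n_elem]:
            parts = [int(x) for x in ln.split()]
            etype, ntags = parts[1], parts[2]
            conn = parts[3 + ntags:]
            if etype == 2:
                tris.append([id_map[c] for c in conn])
            elif etype == 1:
                bedges.append([id_map[c] for c in conn])
    except (ValueError, IndexError, KeyError) as exc:
        raise MshParseError(f"Elements: malformed element record ({exc})") from exc
    if not tris:
        raise MshParseError("Elements: no triangles (type 2) found")
    mesh = TriangleMesh(nodes, np.array(tris),
                        np.array(bedges) if bedges else None)
    return mesh
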