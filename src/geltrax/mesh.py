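"""Gel domain meshing.

The gel around an embedded tissue surface is meshed by radial extrusion:
each surface vertex defines a ray from the tissue centroid, nodes are laid
out along the ray from the surface to the outer gel boundary with geometric
grading (refinement concentrated at the tissue-matrix interface), and each
surface triangle sweeps out a stack of prisms that are split into
tetrahedra with a globally consistent diagonal rule. This requires the
surface to be star-shaped about its centroid, which holds for the
idealised tissue geometries used here (spheres, capsules, extruded
rectangles). Quadratic (10-node) tetrahedra are obtained by inserting
edge midpoints, optionally projected onto the true interface geometry.

The default outer boundary is a cylinder 2 mm in height and diameter,
representing the collagen gel; displacement boundary data is applied on
the tagged ``interface`` and ``outer`` node sets by the solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

try:
    import trimesh
except ImportError:  # pragma: no cover
    trimesh = None


# --------------------------------------------------------------------------
# Tissue surface
# --------------------------------------------------------------------------

@dataclass
class TissueSurface:
    """Triangulated tissue-matrix interface.

    Faces are wound so that normals point outward from the tissue into the
    gel. ``projection``, when set, maps nearby points onto the exact
    analytic surface (used to curve quadratic edge midpoints).
    """

    vertices: np.ndarray
    faces: np.ndarray
    projection: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        self.faces = np.asarray(self.faces, int)
        self._orient_outward()

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def _orient_outward(self) -> None:
        c = self.centroid
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        mid = v[f].mean(axis=1)
        flip = np.einsum("ij,ij->i", n, mid - c) < 0
        self.faces[flip] = self.faces[flip][:, [0, 2, 1]]

    def face_normals(self) -> np.ndarray:
        v, f = self.vertices, self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    @classmethod
    def sphere(cls, radius: float, subdivisions: int = 2,
               center=(0.0, 0.0, 0.0)) -> "TissueSurface":
        """Icosphere approximation of a spherical tissue; midpoints are
        projected back onto the exact sphere."""
        if trimesh is None:  # pragma: no cover
            raise ImportError("trimesh is required for icosphere generation")
        m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
        ctr = np.asarray(center, float)

        def proj(points: np.ndarray) -> np.ndarray:
            rel = points - ctr
            r = np.linalg.norm(rel, axis=-1, keepdims=True)
            return ctr + radius * rel / r

        return cls(m.vertices + ctr, m.faces, projection=proj)

    @classmethod
    def from_file(cls, path: str) -> "TissueSurface":
        """Load a watertight STL/PLY surface."""
        if trimesh is None:  # pragma: no cover
            raise ImportError("trimesh is required for STL/PLY loading")
        m = trimesh.load_mesh(path)
        if not m.is_watertight:
            raise ValueError(f"surface {path} is not watertight")
        return cls(np.asarray(m.vertices), np.asarray(m.faces))


# --------------------------------------------------------------------------
# Outer gel shapes (ray-exit distances from the tissue centroid)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CylinderShape:
    """Gel cylinder, axis along z. Default matches a 2-mm (height and
    diameter) collagen gel domain."""

    height: float = 2000.0
    diameter: float = 2000.0

    def ray_exit(self, dirs: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(dirs)
        rho = np.hypot(d[:, 0], d[:, 1])
        with np.errstate(divide="ignore"):
            t_r = np.where(rho > 0, (self.diameter / 2.0) / rho, np.inf)
            t_z = np.where(np.abs(d[:, 2]) > 0,
                           (self.height / 2.0) / np.abs(d[:, 2]), np.inf)
        return np.minimum(t_r, t_z)


@dataclass(frozen=True)
class SphereShape:
    radius: float = 1000.0

    def ray_exit(self, dirs: np.ndarray) -> np.ndarray:
        return np.full(len(np.atleast_2d(dirs)), self.radius)


@dataclass(frozen=True)
class BoxShape:
    size: tuple[float, float, float] = (2000.0, 2000.0, 2000.0)

    def ray_exit(self, dirs: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(dirs)
        half = np.asarray(self.size, float) / 2.0
        with np.errstate(divide="ignore"):
            t = np.where(np.abs(d) > 0, half / np.abs(d), np.inf)
        return t.min(axis=1)


GelShape = CylinderShape | SphereShape | BoxShape

# TET10 edge ordering: midnode k corresponds to corner pair TET_EDGES[k]
TET_EDGES = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass
class GelDomainMesh:
    """Tetrahedral mesh of the gel with tagged boundary node sets.

    ``tets`` is (M, 4) for linear or (M, 10) for quadratic elements
    (corners first, then midpoints of edges in :data:`TET_EDGES` order).
    ``interface_faces`` are corner-node triangles on the tissue surface,
    wound outward (normal from tissue into gel).
    """

    nodes: np.ndarray
    tets: np.ndarray
    order: int
    interface_nodes: np.ndarray
    outer_nodes: np.ndarray
    interface_faces: np.ndarray
    center: np.ndarray
    interface_faces_q: np.ndarray | None = None  # (K, 6) tri6 for order 2

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def interface_normals(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-interface-node outward unit normals and nodal areas.

        Normals are area-weighted averages of adjacent interface-face
        normals; each face's area is shared equally among the nodes it
        carries (3 corners, plus 3 edge midnodes on quadratic meshes).
        """
        v = self.nodes
        f = self.interface_faces_q if self.interface_faces_q is not None \
            else self.interface_faces
        fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        areas = 0.5 * np.linalg.norm(fn, axis=1)
        fn_unit = fn / np.linalg.norm(fn, axis=1, keepdims=True)

        normals = np.zeros((self.n_nodes, 3))
        area_acc = np.zeros(self.n_nodes)
        share = f.shape[1]
        for j in range(share):
            np.add.at(normals, f[:, j], fn_unit * areas[:, None])
            np.add.at(area_acc, f[:, j], areas / share)
        idx = self.interface_nodes
        n = normals[idx]
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        return n, area_acc[idx]


def _split_prism(prism: np.ndarray) -> list[tuple[int, ...]]:
    """Split prism (bottom v0 v1 v2, top v3 v4 v5, vertical edges vi-vi+3)
    into 3 tets with quad-face diagonals through the globally smallest
    vertex index, so adjacent prisms triangulate shared faces identically."""
    rots = [(0, 1, 2, 3, 4, 5), (1, 2, 0, 4, 5, 3), (2, 0, 1, 5, 3, 4)]
    flip = (3, 5, 4, 0, 2, 1)
    perms = rots + [tuple(rot[i] for i in flip) for rot in rots]
    best = min(perms, key=lambda perm: prism[perm[0]])
    v = [prism[i] for i in best]
    if min(v[1], v[5]) < min(v[2], v[4]):
        return [(v[0], v[1], v[2], v[5]), (v[0], v[1], v[5], v[4]),
                (v[0], v[4], v[5], v[3])]
    return [(v[0], v[1], v[2], v[4]), (v[0], v[4], v[2], v[5]),
            (v[0], v[4], v[5], v[3])]


def build_gel_mesh(
    surface: TissueSurface,
    gel_shape: GelShape = CylinderShape(),
    n_layers: int = 10,
    order: int = 2,
) -> GelDomainMesh:
    """Mesh the gel between ``surface`` and the outer ``gel_shape`` boundary.

    Radial node layers are geometrically graded from the interface to the
    outer boundary. ``order=2`` produces 10-node tetrahedra with interface
    edge midpoints snapped onto the analytic surface when the surface
    provides a projection.

    Raises
    ------
    ValueError
        If the surface reaches or exceeds the gel boundary along any ray,
        or if ``n_layers < 1``.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if order not in (1, 2):
        raise ValueError("order must be 1 (linear) or 2 (quadratic tets)")
    c = surface.centroid
    rel = surface.vertices - c
    r_in = np.linalg.norm(rel, axis=1)
    if np.any(r_in == 0):
        raise ValueError("surface vertex coincides with the centroid")
    dirs = rel / r_in[:, None]
    r_out = gel_shape.ray_exit(dirs)
    if np.any(r_out <= r_in * (1.0 + 1e-9)):
        raise ValueError("tissue surface reaches or exceeds the gel boundary")

    V = len(surface.vertices)
    ratio = (r_out / r_in) ** (1.0 / n_layers)
    # nodes[i*V + k] = centroid + d_k * r_in_k * ratio_k^i
    radii = r_in[None, :] * ratio[None, :] ** np.arange(n_layers + 1)[:, None]
    nodes = (c[None, None, :] + dirs[None, :, :] * radii[:, :, None]
             ).reshape(-1, 3)

    tets: list[tuple[int, ...]] = []
    for i in range(n_layers):
        base, top = i * V, (i + 1) * V
        for (a, b, cc) in surface.faces:
            prism = np.array([base + a, base + b, base + cc,
                              top + a, top + b, top + cc])
            tets.extend(_split_prism(prism))
    tets_arr = np.asarray(tets, dtype=np.int64)

    # enforce positive orientation (volumes > 0)
    x = nodes[tets_arr]
    vol6 = np.einsum("ij,ij->i", np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]),
                     x[:, 3] - x[:, 0])
    neg = vol6 < 0
    tets_arr[neg] = tets_arr[neg][:, [0, 1, 3, 2]]
    if np.any(np.einsum("ij,ij->i",
                        np.cross(nodes[tets_arr[:, 1]] - nodes[tets_arr[:, 0]],
                                 nodes[tets_arr[:, 2]] - nodes[tets_arr[:, 0]]),
                        nodes[tets_arr[:, 3]] - nodes[tets_arr[:, 0]]) <= 0):
        raise ValueError("meshing failure: degenerate (zero-volume) element")

    interface_nodes = np.arange(V)
    outer_nodes = np.arange(n_layers * V, (n_layers + 1) * V)
    interface_faces = surface.faces.copy()
    interface_faces_q = None

    if order == 2:
        nodes, tets_arr, mid_of = _to_quadratic(nodes, tets_arr)
        # midnodes whose corner endpoints are both on a boundary layer
        iface_set = set(interface_nodes.tolist())
        outer_set = set(outer_nodes.tolist())
        iface_mids = [m for (a, b), m in mid_of.items()
                      if a in iface_set and b in iface_set]
        outer_mids = [m for (a, b), m in mid_of.items()
                      if a in outer_set and b in outer_set]
        if surface.projection is not None and iface_mids:
            nodes[iface_mids] = surface.projection(nodes[iface_mids])
        # tri6 interface faces: corners then midnodes of edges (0,1),(1,2),(2,0)
        interface_faces_q = np.empty((len(interface_faces), 6), dtype=np.int64)
        interface_faces_q[:, :3] = interface_faces
        for k, (i, j) in enumerate(((0, 1), (1, 2), (2, 0))):
            pairs = np.sort(interface_faces[:, [i, j]], axis=1)
            interface_faces_q[:, 3 + k] = [
                mid_of[(int(a), int(b))] for a, b in pairs]
        interface_nodes = np.concatenate([interface_nodes, iface_mids]).astype(int)
        outer_nodes = np.concatenate([outer_nodes, outer_mids]).astype(int)

    return GelDomainMesh(nodes=nodes, tets=tets_arr, order=order,
                         interface_nodes=np.asarray(interface_nodes, int),
                         outer_nodes=np.asarray(outer_nodes, int),
                         interface_faces=interface_faces, center=c,
                         interface_faces_q=interface_faces_q)


def _to_quadratic(
    nodes: np.ndarray, tets: np.ndarray
) -> tuple[np.ndarray, np.ndarray, dict[tuple[int, int], int]]:
    """Insert unique edge-midpoint nodes, returning the TET10 connectivity
    and the (sorted corner pair) -> midnode index map."""
    edges = np.concatenate([np.sort(tets[:, e], axis=1) for e in TET_EDGES])
    uniq, inv = np.unique(edges, axis=0, return_inverse=True)
    mid_start = len(nodes)
    midpoints = 0.5 * (nodes[uniq[:, 0]] + nodes[uniq[:, 1]])
    new_nodes = np.vstack([nodes, midpoints])
    M = len(tets)
    tet10 = np.empty((M, 10), dtype=np.int64)
    tet10[:, :4] = tets
    for k in range(6):
        tet10[:, 4 + k] = mid_start + inv[k * M:(k + 1) * M]
    mid_of = {(int(a), int(b)): mid_start + i for i, (a, b) in enumerate(uniq)}
    return new_nodes, tet10, mid_of
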