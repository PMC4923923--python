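"""Symmetry-preserving triangulations of cell cross-sections and P1 FEM assembly.

The simulator works in a quasi-2D mode: the bulk is the lateral (x-y)
cross-section of the cell, the membrane is its closed 1D boundary curve.
Meshes are built so that the node set and the connectivity are exactly
invariant under reflection through both symmetry axes; this lets reflection
act as a node permutation, which the parity classification and the
symmetry-preservation tests rely on.

Conventions: the cell's long axis lies along x, the short axis along y,
with the centroid at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["Mesh", "build_mesh"]


@dataclass
class Mesh:
    """Triangulated cross-section with an ordered closed boundary curve.

    Attributes
    ----------
    points : (n, 2) float array of node coordinates (um).
    triangles : (nt, 3) int array, CCW vertex indices.
    boundary_nodes : (m,) int array, bulk indices of the boundary nodes in
        CCW order around the closed curve.
    """

    points: np.ndarray
    triangles: np.ndarray
    boundary_nodes: np.ndarray
    geometry: object = None
    _cache: dict = field(default_factory=dict, repr=False)

    # ------------------------------------------------------------------ sizes
    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def n_boundary(self) -> int:
        return len(self.boundary_nodes)

    @property
    def boundary_points(self) -> np.ndarray:
        return self.points[self.boundary_nodes]

    # ----------------------------------------------------------------- geometry
    def triangle_areas(self) -> np.ndarray:
        p = self.points[self.triangles]
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        return 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    @property
    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def segment_lengths(self) -> np.ndarray:
        """Length of boundary segment j (from boundary node j to j+1)."""
        if "seglen" not in self._cache:
            bp = self.boundary_points
            self._cache["seglen"] = np.linalg.norm(np.roll(bp, -1, axis=0) - bp, axis=1)
        return self._cache["seglen"]

    @property
    def perimeter(self) -> float:
        return float(self.segment_lengths().sum())

    def boundary_normals(self) -> np.ndarray:
        """Unit outward normals at the boundary nodes (angle-averaged)."""
        bp = self.boundary_points
        seg = np.roll(bp, -1, axis=0) - bp
        # CCW curve: outward normal of a segment is (dy, -dx) normalized
        seg_n = np.stack([seg[:, 1], -seg[:, 0]], axis=1)
        seg_n /= np.linalg.norm(seg_n, axis=1)[:, None]
        node_n = seg_n + np.roll(seg_n, 1, axis=0)
        node_n /= np.linalg.norm(node_n, axis=1)[:, None]
        return node_n

    # --------------------------------------------------------------- assembly
    def bulk_matrices(self) -> tuple[sp.csc_matrix, sp.csc_matrix]:
        """Consistent P1 mass and stiffness matrices on the bulk (M, K)."""
        if "MK" not in self._cache:
            tri = self.triangles
            p = self.points[tri]
            area = self.triangle_areas()
            # gradients of the three barycentric basis functions
            x, y = p[..., 0], p[..., 1]
            bx = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
            by = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
            inv2a = 1.0 / (2.0 * area)
            gx = bx * inv2a[:, None]
            gy = by * inv2a[:, None]
            k_loc = (gx[:, :, None] * gx[:, None, :] + gy[:, :, None] * gy[:, None, :])
            k_loc *= area[:, None, None]
            m_ref = np.array([[2, 1, 1], [1, 2, 1], [1, 1, 2]], dtype=float) / 12.0
            m_loc = area[:, None, None] * m_ref[None]
            rows = np.repeat(tri, 3, axis=1).ravel()
            cols = np.tile(tri, (1, 3)).ravel()
            n = self.n_nodes
            K = sp.coo_matrix((k_loc.ravel(), (rows, cols)), shape=(n, n)).tocsc()
            M = sp.coo_matrix((m_loc.ravel(), (rows, cols)), shape=(n, n)).tocsc()
            self._cache["MK"] = (M, K)
        return self._cache["MK"]

    def boundary_matrices(self) -> tuple[sp.csc_matrix, sp.csc_matrix]:
        """P1 mass and stiffness on the closed boundary curve (Mb, Kb).

        Indexed in boundary ordering (0..m-1), periodic.
        """
        if "MbKb" not in self._cache:
            m = self.n_boundary
            ln = self.segment_lengths()
            i = np.arange(m)
            j = (i + 1) % m
            rows = np.concatenate([i, i, j, j])
            cols = np.concatenate([i, j, i, j])
            mv = np.concatenate([ln / 3, ln / 6, ln / 6, ln / 3])
            kv = np.concatenate([1 / ln, -1 / ln, -1 / ln, 1 / ln])
            Mb = sp.coo_matrix((mv, (rows, cols)), shape=(m, m)).tocsc()
            Kb = sp.coo_matrix((kv, (rows, cols)), shape=(m, m)).tocsc()
            self._cache["MbKb"] = (Mb, Kb)
        return self._cache["MbKb"]

    def boundary_weights(self) -> np.ndarray:
        """Lumped arc-length weight per boundary node (integrates to perimeter)."""
        if "bw" not in self._cache:
            ln = self.segment_lengths()
            self._cache["bw"] = 0.5 * (ln + np.roll(ln, 1))
        return self._cache["bw"]

    def lumped_bulk_weights(self) -> np.ndarray:
        """Lumped area weight per bulk node (integrates to total area)."""
        if "aw" not in self._cache:
            M, _ = self.bulk_matrices()
            self._cache["aw"] = np.asarray(M.sum(axis=1)).ravel()
        return self._cache["aw"]

    # -------------------------------------------------------------- symmetry
    def reflection_map(self, axis: str = "x") -> np.ndarray:
        """Node permutation of the reflection through the given axis.

        axis="x" reflects y -> -y (long-axis reflection, used for the
        even/odd mode classification); axis="y" reflects x -> -x.
        Raises if the mesh is not symmetric.
        """
        key = f"refl_{axis}"
        if key not in self._cache:
            pts = self.points.copy()
            if axis == "x":
                pts[:, 1] *= -1.0
            elif axis == "y":
                pts[:, 0] *= -1.0
            else:
                raise ValueError("axis must be 'x' or 'y'")
            scale = max(np.abs(self.points).max(), 1.0)
            key_of = lambda q: (round(q[0] / scale, 9), round(q[1] / scale, 9))
            lookup = {key_of(q): i for i, q in enumerate(self.points)}
            perm = np.empty(self.n_nodes, dtype=int)
            for i, q in enumerate(pts):
                j = lookup.get(key_of(q))
                if j is None:
                    raise ValueError(f"mesh not symmetric under {axis}-reflection")
                perm[i] = j
            self._cache[key] = perm
        return self._cache[key]


# ---------------------------------------------------------------------------
# mesh constructors
# ---------------------------------------------------------------------------


def _rectangle_mesh(L: float, W: float, h: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Union-jack triangulation of [-L/2,L/2] x [-W/2,W/2].

    Every quad of a regular grid is split into four triangles around its
    centroid, so the connectivity is exactly invariant under both axis
    reflections regardless of the grid dimensions.
    """
    nx = max(2, int(round(L / h)))
    ny = max(2, int(round(W / h)))
    xs = np.linspace(-L / 2, L / 2, nx + 1)
    ys = np.linspace(-W / 2, W / 2, ny + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    grid = np.stack([gx.ravel(), gy.ravel()], axis=1)  # index i*(ny+1)+j
    n_grid = len(grid)

    def gid(i, j):
        return i * (ny + 1) + j

    # centroid nodes
    ci, cj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx = 0.5 * (xs[ci] + xs[ci + 1])
    cy = 0.5 * (ys[cj] + ys[cj + 1])
    cents = np.stack([cx.ravel(), cy.ravel()], axis=1)
    points = np.vstack([grid, cents])

    tris = []
    for i in range(nx):
        for j in range(ny):
            c = n_grid + i * ny + j
            a, b = gid(i, j), gid(i + 1, j)
            d, e = gid(i + 1, j + 1), gid(i, j + 1)
            tris += [(a, b, c), (b, d, c), (d, e, c), (e, a, c)]
    triangles = np.array(tris, dtype=int)

    # boundary in CCW order starting at (-L/2, -W/2)
    bottom = [gid(i, 0) for i in range(nx)]
    right = [gid(nx, j) for j in range(ny)]
    top = [gid(i, ny) for i in range(nx, 0, -1)]
    left = [gid(0, j) for j in range(ny, 0, -1)]
    boundary = np.array(bottom + right + top + left, dtype=int)
    return points, triangles, boundary


def _ellipse_mesh(a: float, b: float, h: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ring triangulation of the ellipse x^2/a^2 + y^2/b^2 <= 1.

    Concentric scaled-ellipse rings with a common angular grid (a multiple
    of 4 nodes, so both axis reflections are node permutations); quads
    between rings are split union-jack style around mid-ring centroids,
    and the innermost ring is fanned to the center node.
    """
    per = float(np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b))))  # Ramanujan
    m = max(8, 4 * int(round(per / h / 4)))
    n_r = max(2, int(round(min(a, b) / h)))
    theta = 2 * np.pi * np.arange(m) / m
    ct, st = np.cos(theta), np.sin(theta)

    pts = [np.zeros((1, 2))]  # center node, index 0
    ring_start = []
    for j in range(1, n_r + 1):
        rho = j / n_r
        ring_start.append(len(np.vstack(pts)))
        pts.append(np.stack([a * rho * ct, b * rho * st], axis=1))
    # centroid nodes between ring j and j+1 (at rho_{j+1/2}, theta_{k+1/2})
    theta_h = theta + np.pi / m
    cth, sth = np.cos(theta_h), np.sin(theta_h)
    cent_start = []
    for j in range(1, n_r):
        rho = (j + 0.5) / n_r
        cent_start.append(len(np.vstack(pts)))
        pts.append(np.stack([a * rho * cth, b * rho * sth], axis=1))
    points = np.vstack(pts)

    tris = []
    # center fan
    r1 = ring_start[0]
    for k in range(m):
        tris.append((0, r1 + k, r1 + (k + 1) % m))
    # annuli
    for j in range(n_r - 1):
        ri, ro, c0 = ring_start[j], ring_start[j + 1], cent_start[j]
        for k in range(m):
            k1 = (k + 1) % m
            c = c0 + k
            tris += [
                (ri + k, ro + k, c),
                (ro + k, ro + k1, c),
                (ro + k1, ri + k1, c),
                (ri + k1, ri + k, c),
            ]
    triangles = np.array(tris, dtype=int)
    boundary = np.arange(ring_start[-1], ring_start[-1] + m, dtype=int)
    return points, triangles, boundary


def build_mesh(geometry, resolution: float | None = None) -> Mesh:
    """Triangulate a :class:`~minpat.model_core.CellGeometry` cross-section.

    Parameters
    ----------
    geometry : CellGeometry
        Shape descriptor (rectangle, ellipse, or stadium).
    resolution : float, optional
        Target element edge length in um; defaults to
        ``geometry.mesh_resolution``.

    Returns
    -------
    Mesh
        Bulk triangulation plus ordered closed boundary curve.
    """
    h = float(resolution if resolution is not None else geometry.mesh_resolution)
    L, W = geometry.length_L, geometry.width_W
    if h > W / 4:
        raise ValueError(
            f"mesh resolution {h} um is coarser than width/4 = {W / 4} um"
        )
    if geometry.shape == "rectangle":
        pts, tris, bnd = _rectangle_mesh(L, W, h)
    elif geometry.shape == "ellipse":
        pts, tris, bnd = _ellipse_mesh(L / 2, W / 2, h)
    elif geometry.shape == "stadium":
        pts, tris, bnd = _stadium_mesh(L, W, h)
    else:
        raise ValueError(f"unknown shape {geometry.shape!r}")
    mesh = Mesh(points=pts, triangles=tris, boundary_nodes=bnd, geometry=geometry)
    if mesh.triangle_areas().min() <= 0:
        raise RuntimeError("mesh construction produced degenerate triangles")
    return mesh


def _stadium_mesh(L: float, W: float, h: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stadium (rectangle with semicircular caps) via Delaunay of a convex set."""
    from scipy.spatial import Delaunay

    r = W / 2
    Ls = L - W  # straight section length
    # boundary: sampled symmetric about both axes
    n_straight = max(2, int(round(Ls / h)))
    n_cap = max(4, 2 * int(round(np.pi * r / h / 2)))
    xs = np.linspace(-Ls / 2, Ls / 2, n_straight + 1)
    bottom = np.stack([xs, np.full_like(xs, -r)], axis=1)
    phi = np.linspace(-np.pi / 2, np.pi / 2, n_cap + 1)[1:-1]
    cap_r = np.stack([Ls / 2 + r * np.cos(phi), r * np.sin(phi)], axis=1)
    top = np.stack([xs[::-1], np.full_like(xs, r)], axis=1)
    cap_l = np.stack([-Ls / 2 - r * np.cos(phi), -r * np.sin(phi)], axis=1)
    bnd_pts = np.vstack([bottom, cap_r, top, cap_l])
    # interior: symmetric grid clipped strictly inside
    nx = int(np.ceil(L / h))
    ny = int(np.ceil(W / h))
    gx, gy = np.meshgrid(
        np.linspace(-L / 2, L / 2, nx + 1), np.linspace(-r, r, ny + 1), indexing="ij"
    )
    g = np.stack([gx.ravel(), gy.ravel()], axis=1)
    ax = np.clip(np.abs(g[:, 0]) - Ls / 2, 0, None)
    inside = ax**2 + g[:, 1] ** 2 < (r - 0.4 * h) ** 2
    interior = g[inside]
    points = np.vstack([bnd_pts, interior])
    tri = Delaunay(points)
    triangles = tri.simplices.copy()
    # enforce CCW orientation
    p = points[triangles]
    det = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 1, 1] - p[:, 0, 1]
    ) * (p[:, 2, 0] - p[:, 0, 0])
    flip = det < 0
    triangles[flip] = triangles[flip][:, [0, 2, 1]]
    # drop slivers along the boundary (collinear boundary triples)
    areas = 0.5 * np.abs(det)
    triangles = triangles[areas > 1e-12 * h * h]
    boundary = np.arange(len(bnd_pts), dtype=int)
    return points, triangles, boundary
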