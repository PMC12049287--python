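"""Closest-point queries from points to a triangle mesh.

This is the geometric kernel behind both ICP correspondence search and the
bone-to-implant distance map. Candidate triangles are pruned with a KD-tree
over triangle centroids; the exact closest point on each candidate triangle
is then computed with the standard Voronoi-region (barycentric clamp)
algorithm, fully vectorised over (point, triangle) pairs. For small meshes
the pruning is skipped and all pairs are evaluated in chunks.

Signs for the distance map come from angle-weighted pseudonormals: the
closest feature (face, edge or vertex) contributes a normal that is
guaranteed to classify inside/outside correctly for closed meshes, which a
bare face normal does not on edges and vertices.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateInputError
from .volio import TriangleMesh

_EXHAUSTIVE_LIMIT = 1024   # fixed meshes up to this many faces skip the tree
_CHUNK = 4096


def closest_point_on_triangles(points: np.ndarray,
                               triangles: np.ndarray) -> np.ndarray:
    """Closest point on triangle i to point i, for paired inputs.

    ``points``: (n, 3); ``triangles``: (n, 3, 3). Ericson's Voronoi-region
    walk, vectorised with masks.
    """
    p = np.asarray(points, dtype=float)
    a = triangles[:, 0]
    b = triangles[:, 1]
    c = triangles[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def settle(mask, value):
        m = mask & ~done
        out[m] = value[m] if value.ndim == 2 else value
        done[m] = True

    settle((d1 <= 0) & (d2 <= 0), a)                       # vertex A
    settle((d3 >= 0) & (d4 <= d3), b)                      # vertex B
    vc = d1 * d4 - d3 * d2
    with np.errstate(invalid="ignore", divide="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)  # edge AB
    settle((d6 >= 0) & (d5 <= d6), c)                      # vertex C
    vb = d5 * d2 - d1 * d6
    with np.errstate(invalid="ignore", divide="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)  # edge AC
    va = d3 * d6 - d5 * d4
    e1 = d4 - d3
    e2 = d5 - d6
    with np.errstate(invalid="ignore", divide="ignore"):
        w_bc = np.where(e1 + e2 != 0, e1 / (e1 + e2), 0.0)
    settle((va <= 0) & (e1 >= 0) & (e2 >= 0), b + w_bc[:, None] * (c - b))
    # interior
    m = ~done
    denom = va[m] + vb[m] + vc[m]
    denom = np.where(denom != 0, denom, 1.0)
    v = (vb[m] / denom)[:, None]
    w = (vc[m] / denom)[:, None]
    out[m] = a[m] + v * ab[m] + w * ac[m]
    return out


class MeshDistanceQuery:
    """Reusable closest-point structure for one fixed triangle mesh."""

    def __init__(self, mesh: TriangleMesh):
        if mesh.n_faces == 0:
            raise DegenerateInputError("mesh has no faces")
        self.mesh = mesh
        self.tri = mesh.vertices[mesh.faces]          # (m, 3, 3)
        self.centroids = self.tri.mean(axis=1)
        self._r = np.linalg.norm(
            self.tri - self.centroids[:, None, :], axis=2).max(axis=1)
        self._r_max = float(self._r.max())
        self._n_faces = len(self.tri)
        if self._n_faces > _EXHAUSTIVE_LIMIT:
            self._tree = cKDTree(self.centroids)
        else:
            self._tree = None
        self._pseudo = None

    # -- closest point ----------------------------------------------------

    def query(self, points: np.ndarray):
        """Return (distances, closest_points, triangle_indices) for points (n,3)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self._tree is None:
            return self._query_exhaustive(points)
        return self._query_pruned(points)

    def _query_exhaustive(self, points):
        n = len(points)
        dist = np.empty(n)
        cp = np.empty((n, 3))
        ti = np.empty(n, dtype=np.int64)
        m = self._n_faces
        for s in range(0, n, max(1, _CHUNK // max(m, 1) * 64)):
            blk = points[s:s + max(1, _CHUNK // max(m, 1) * 64)]
            k = len(blk)
            P = np.repeat(blk, m, axis=0)
            T = np.tile(self.tri, (k, 1, 1))
            C = closest_point_on_triangles(P, T)
            D = np.linalg.norm(P - C, axis=1).reshape(k, m)
            idx = D.argmin(axis=1)
            rows = np.arange(k)
            dist[s:s + k] = D[rows, idx]
            cp[s:s + k] = C.reshape(k, m, 3)[rows, idx]
            ti[s:s + k] = idx
        return dist, cp, ti

    def _query_pruned(self, points):
        n = len(points)
        k0 = min(8, self._n_faces)
        _, cand = self._tree.query(points, k=k0)
        cand = np.atleast_2d(cand)
        # upper bound from the k nearest centroids' exact distances
        P = np.repeat(points, k0, axis=0)
        T = self.tri[cand.ravel()]
        C = closest_point_on_triangles(P, T)
        D = np.linalg.norm(P - C, axis=1).reshape(n, k0)
        j = D.argmin(axis=1)
        rows = np.arange(n)
        ub = D[rows, j]
        best_cp = C.reshape(n, k0, 3)[rows, j]
        best_ti = cand[rows, j]
        # any triangle that could beat ub has centroid within ub + r_max
        radii = ub + self._r_max + 1e-12
        groups = self._tree.query_ball_point(points, radii)
        pt_idx = np.concatenate([np.full(len(g), i, dtype=np.int64)
                                 for i, g in enumerate(groups)]) \
            if n else np.empty(0, dtype=np.int64)
        tri_idx = np.concatenate([np.asarray(sorted(g), dtype=np.int64)
                                  for g in groups]) \
            if n else np.empty(0, dtype=np.int64)
        if len(pt_idx):
            C2 = closest_point_on_triangles(points[pt_idx], self.tri[tri_idx])
            D2 = np.linalg.norm(points[pt_idx] - C2, axis=1)
            better = D2 < ub[pt_idx]
            # keep the first strict improvement per point in (pt, tri) order
            order = np.lexsort((tri_idx[better], pt_idx[better]))
            bp = pt_idx[better][order]
            bd = D2[better][order]
            bc = C2[better][order]
            bt = tri_idx[better][order]
            for i in range(len(bp)):           # few survivors; cheap loop
                pi = bp[i]
                if bd[i] < ub[pi]:
                    ub[pi] = bd[i]
                    best_cp[pi] = bc[i]
                    best_ti[pi] = bt[i]
        return ub, best_cp, best_ti

    # -- signed distance --------------------------------------------------

    def _pseudonormals(self):
        """Face, edge and angle-weighted vertex pseudonormals (cached)."""
        if self._pseudo is not None:
            return self._pseudo
        V, F = self.mesh.vertices, self.mesh.faces
        e1 = V[F[:, 1]] - V[F[:, 0]]
        e2 = V[F[:, 2]] - V[F[:, 0]]
        fn = np.cross(e1, e2)
        norms = np.linalg.norm(fn, axis=1, keepdims=True)
        fn = fn / np.where(norms > 0, norms, 1.0)
        # angle-weighted vertex normals
        vn = np.zeros_like(V)
        for corner in range(3):
            a = V[F[:, (corner + 1) % 3]] - V[F[:, corner]]
            b = V[F[:, (corner + 2) % 3]] - V[F[:, corner]]
            na = np.linalg.norm(a, axis=1)
            nb = np.linalg.norm(b, axis=1)
            cosang = np.clip(np.einsum("ij,ij->i", a, b)
                             / np.where(na * nb > 0, na * nb, 1.0), -1, 1)
            ang = np.arccos(cosang)
            np.add.at(vn, F[:, corner], fn * ang[:, None])
        nv = np.linalg.norm(vn, axis=1, keepdims=True)
        vn = vn / np.where(nv > 0, nv, 1.0)
        # edge normals: sum of the (<=2) adjacent face normals
        edges = {}
        for fi, face in enumerate(F):
            for a, b in ((0, 1), (1, 2), (2, 0)):
                key = (min(face[a], face[b]), max(face[a], face[b]))
                edges.setdefault(key, np.zeros(3))
                edges[key] = edges[key] + fn[fi]
        en = {k: v / (np.linalg.norm(v) or 1.0) for k, v in edges.items()}
        self._pseudo = (fn, vn, en)
        return self._pseudo

    def signed_query(self, points: np.ndarray):
        """(signed distances, closest points, triangle indices, normals).

        Positive sign = point on the outward side of the surface at its
        closest feature; requires consistently outward-oriented faces.
        ``normals`` are the pseudonormals of the closest features.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        dist, cp, ti = self.query(points)
        fn, vn, en = self._pseudonormals()
        F = self.mesh.faces
        tri = self.tri[ti]
        # barycentric coords of the closest points on their triangles
        v0 = tri[:, 1] - tri[:, 0]
        v1 = tri[:, 2] - tri[:, 0]
        v2 = cp - tri[:, 0]
        d00 = np.einsum("ij,ij->i", v0, v0)
        d01 = np.einsum("ij,ij->i", v0, v1)
        d11 = np.einsum("ij,ij->i", v1, v1)
        d20 = np.einsum("ij,ij->i", v2, v0)
        d21 = np.einsum("ij,ij->i", v2, v1)
        denom = d00 * d11 - d01 * d01
        denom = np.where(np.abs(denom) > 0, denom, 1.0)
        v = (d11 * d20 - d01 * d21) / denom
        w = (d00 * d21 - d01 * d20) / denom
        u = 1.0 - v - w
        bary = np.stack([u, v, w], axis=1)
        onzero = np.abs(bary) < 1e-9
        normals = fn[ti].copy()
        n_zero = onzero.sum(axis=1)
        # vertex feature: two barycentrics ~ 0
        at_vertex = n_zero >= 2
        if at_vertex.any():
            corner = np.argmax(bary[at_vertex], axis=1)
            vid = F[ti[at_vertex], corner]
            normals[at_vertex] = vn[vid]
        # edge feature: exactly one barycentric ~ 0
        at_edge = n_zero == 1
        if at_edge.any():
            idxs = np.flatnonzero(at_edge)
            zero_c = np.argmin(np.abs(bary[idxs]), axis=1)
            for i, zc in zip(idxs, zero_c):
                fa = F[ti[i]]
                pair = [fa[c] for c in range(3) if c != zc]
                key = (min(pair), max(pair))
                n = en.get(key)
                if n is not None:
                    normals[i] = n
        side = np.einsum("ij,ij->i", points - cp, normals)
        sign = np.where(side >= 0, 1.0, -1.0)
        return sign * dist, cp, ti, normals
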