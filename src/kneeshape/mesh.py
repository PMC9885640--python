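"""Triangulated-surface primitives for landmark-corresponded bone meshes.

All geometry is in millimetres, right-handed coordinates, 0-based vertex
indices.  The central container is :class:`LandmarkSurface`: an *ordered*
set of 3D landmark points with a shared triangulation.  Surfaces carrying
the same ``topology`` string are corresponded point-for-point, which is
what makes regional measures and statistical shape modelling possible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "SurfaceMeta",
    "LandmarkSurface",
    "RigidTransform",
    "ICPResult",
    "surface_area",
    "vertex_normals",
    "ray_surface_intersect",
    "cast_rays",
    "point_to_surface_distance",
    "closest_points_on_surface",
    "mean_absolute_surface_distance",
    "icp_register",
    "save_surface",
    "load_surface",
]

BONES = ("femur", "tibia")
MODALITIES = ("CT", "MR", "synthetic-truth")


class RegionError(ValueError):
    """Raised for invalid region selections (empty, or no complete triangle)."""


@dataclass
class SurfaceMeta:
    """Acquisition/subject metadata carried in a JSON sidecar next to mesh files."""

    bone: str = "femur"
    modality: str = "synthetic-truth"
    subject: str = ""
    timepoint: str = "baseline"
    sex: str = "pooled"
    group: str = "ungraded"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SurfaceMeta":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


class LandmarkSurface:
    """An ordered, corresponded set of 3D landmarks with shared triangulation.

    Parameters
    ----------
    points : (n, 3) float array
        Landmark coordinates in mm.
    faces : (m, 3) int array
        Triangles as 0-based vertex index triples.
    topology : str
        Identifier of the landmark topology.  Two surfaces with the same
        topology have identical faces and point count and are corresponded
        landmark-by-landmark.
    meta : SurfaceMeta, optional
    """

    def __init__(self, points, faces, topology: str = "anon",
                 meta: Optional[SurfaceMeta] = None, validate: bool = True):
        self.points = np.ascontiguousarray(points, dtype=np.float64)
        self.faces = np.ascontiguousarray(faces, dtype=np.int64)
        self.topology = str(topology)
        self.meta = meta if meta is not None else SurfaceMeta()
        if validate:
            self._validate()

    def _validate(self) -> None:
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if not np.isfinite(self.points).all():
            raise ValueError("points contain non-finite coordinates")
        n = len(self.points)
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= n:
                raise ValueError("face index out of range")
            a, b, c = self.faces.T
            if np.any((a == b) | (b == c) | (a == c)):
                raise ValueError("a face repeats a vertex")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def copy(self, points=None, meta: Optional[SurfaceMeta] = None) -> "LandmarkSurface":
        return LandmarkSurface(
            self.points.copy() if points is None else points,
            self.faces, self.topology,
            dataclasses.replace(meta if meta is not None else self.meta),
            validate=points is not None,
        )

    def same_topology(self, other: "LandmarkSurface") -> bool:
        return (self.topology == other.topology
                and self.n_points == other.n_points
                and self.faces.shape == other.faces.shape)

    def transformed(self, transform: "RigidTransform") -> "LandmarkSurface":
        return self.copy(points=transform.apply(self.points))

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def triangles(self, faces=None) -> np.ndarray:
        f = self.faces if faces is None else faces
        return self.points[f]

    def edge_lengths(self) -> np.ndarray:
        tri = self.triangles()
        e = np.concatenate([tri[:, 1] - tri[:, 0],
                            tri[:, 2] - tri[:, 1],
                            tri[:, 0] - tri[:, 2]])
        return np.linalg.norm(e, axis=1)


@dataclass
class RigidTransform:
    """Similarity transform x -> scale * R @ x + t (scale 1.0 for rigid)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        RtR = self.rotation.T @ self.rotation
        if not np.allclose(RtR, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthogonal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0),
                        center=None, scale: float = 1.0) -> "RigidTransform":
        """Rotation of ``angle_deg`` about ``axis`` (optionally about ``center``)."""
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        th = np.deg2rad(angle_deg)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
        t = np.asarray(translation, dtype=float)
        if center is not None:
            c = np.asarray(center, dtype=float)
            t = t + c - scale * R @ c
        return cls(R, t, scale)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return self.scale * pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.scale * self.rotation @ other.translation + self.translation,
            self.scale * other.scale,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation / self.scale, 1.0 / self.scale)

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# areas and normals

def _face_cross(surface: LandmarkSurface, faces=None) -> np.ndarray:
    tri = surface.triangles(faces)
    return np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])


def region_faces(surface: LandmarkSurface, region: Sequence[int]) -> np.ndarray:
    """Faces whose three vertices all lie inside ``region`` (strict rule)."""
    idx = np.asarray(region, dtype=np.int64)
    if idx.size == 0:
        raise RegionError("region contains no vertices")
    if idx.min() < 0 or idx.max() >= surface.n_points:
        raise RegionError("region index out of range for this surface")
    mask = np.zeros(surface.n_points, dtype=bool)
    mask[idx] = True
    keep = mask[surface.faces].all(axis=1)
    faces = surface.faces[keep]
    if len(faces) == 0:
        raise RegionError("region has vertices but no complete triangle")
    return faces


def surface_area(surface: LandmarkSurface, region: Optional[Sequence[int]] = None) -> float:
    """Total area (mm^2) of the surface, or of the faces fully inside ``region``.

    A triangle belongs to a region iff all three of its vertices do;
    degenerate (zero-area) triangles contribute nothing.
    """
    faces = surface.faces if region is None else region_faces(surface, region)
    if len(faces) == 0:
        return 0.0
    return float(0.5 * np.linalg.norm(_face_cross(surface, faces), axis=1).sum())


def vertex_normals(surface: LandmarkSurface) -> np.ndarray:
    """Area-weighted per-vertex unit normals, oriented by face winding.

    Isolated vertices (no incident face) get a NaN row; downstream
    joint-space measurement excludes them.
    """
    cross = _face_cross(surface)  # |cross| = 2 * area, so this is area weighting
    acc = np.zeros_like(surface.points)
    for k in range(3):
        np.add.at(acc, surface.faces[:, k], cross)
    norm = np.linalg.norm(acc, axis=1)
    out = np.full_like(acc, np.nan)
    ok = norm > 0
    out[ok] = acc[ok] / norm[ok, None]
    return out


# ---------------------------------------------------------------------------
# ray casting (vectorized Moller-Trumbore)

_EPS = 1e-12


def cast_rays(origins: np.ndarray, directions: np.ndarray,
              target: LandmarkSurface, max_dist: float = np.inf):
    """First-hit distances for a batch of rays against every triangle.

    Returns ``(dist, hit)``: ``dist[i]`` is the smallest positive ray
    parameter <= max_dist, NaN where ``hit[i]`` is False.  A miss is a
    value of the ``hit`` mask, never a sentinel distance.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    tri = target.triangles()
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    n_rays = len(origins)
    best = np.full(n_rays, np.inf)
    # chunk over rays to bound the (rays x faces) temporaries
    chunk = max(1, int(2_000_000 // max(len(tri), 1)))
    for s in range(0, n_rays, chunk):
        o = origins[s:s + chunk][:, None, :]
        d = directions[s:s + chunk][:, None, :]
        p = np.cross(d, e2[None, :, :])
        det = np.einsum("rfk,fk->rf", p, e1)
        valid = np.abs(det) > _EPS
        inv = np.where(valid, 1.0 / np.where(valid, det, 1.0), 0.0)
        tvec = o - v0[None, :, :]
        u = np.einsum("rfk,rfk->rf", tvec, p) * inv
        q = np.cross(tvec, e1[None, :, :])
        v = np.einsum("rfk,rk->rf", q, directions[s:s + chunk]) * inv
        t = np.einsum("rfk,fk->rf", q, e2) * inv
        tol = 1e-9
        ok = valid & (u >= -tol) & (v >= -tol) & (u + v <= 1 + tol) & (t > tol)
        t = np.where(ok, t, np.inf)
        best[s:s + chunk] = t.min(axis=1)
    hit = best <= max_dist
    dist = np.where(hit, best, np.nan)
    return dist, hit


def ray_surface_intersect(origin, direction, target: LandmarkSurface,
                          max_dist: float = np.inf) -> Optional[float]:
    """Distance to the first triangle hit along a unit ray, or ``None`` (miss)."""
    direction = np.asarray(direction, dtype=float)
    if not np.isclose(np.linalg.norm(direction), 1.0, atol=1e-8):
        raise ValueError("direction must be a unit vector")
    if not max_dist > 0:
        raise ValueError("max_dist must be positive")
    dist, hit = cast_rays(origin, direction, target, max_dist)
    return float(dist[0]) if hit[0] else None


# ---------------------------------------------------------------------------
# point-to-surface distances

def _closest_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on triangle ``tri[i]`` to ``points[i]`` (paired, vectorized).

    Standard region-based point/triangle projection (Ericson).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, points - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)                      # vertex a
    out[m] = a[m]; done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)           # vertex b
    out[m] = b[m]; done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)           # vertex c
    out[m] = c[m]; done |= m

    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    denom = np.where(d1 - d3 == 0, 1.0, d1 - d3)
    w = (d1 / denom)[m, None]
    out[m] = a[m] + w * ab[m]; done |= m

    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    denom = np.where(d2 - d6 == 0, 1.0, d2 - d6)
    w = (d2 / denom)[m, None]
    out[m] = a[m] + w * ac[m]; done |= m

    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge bc
    denom = (d4 - d3) + (d5 - d6)
    denom = np.where(denom == 0, 1.0, denom)
    w = ((d4 - d3) / denom)[m, None]
    out[m] = b[m] + w * (c[m] - b[m]); done |= m

    m = ~done                                       # face interior
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = (vb / denom)[m, None]
    w = (vc / denom)[m, None]
    out[m] = a[m] + v * ab[m] + w * ac[m]
    return out


def point_to_surface_distance(point, target: LandmarkSurface) -> float:
    """Unsigned minimum distance (mm) from a point to any triangle of ``target``."""
    if len(target.faces) == 0:
        raise ValueError("target surface has no faces")
    p = np.asarray(point, dtype=float).reshape(3)
    tri = target.triangles()
    closest = _closest_on_triangles(np.broadcast_to(p, (len(tri), 3)).copy(), tri)
    return float(np.linalg.norm(closest - p, axis=1).min())


def vertex_face_adjacency(faces: np.ndarray, n_points: int):
    """CSR-style vertex -> incident-face lists: (offsets, face_ids)."""
    counts = np.zeros(n_points, dtype=np.int64)
    for col in faces.T:
        np.add.at(counts, col, 1)
    offsets = np.zeros(n_points + 1, dtype=np.int64)
    np.cumsum(counts, out=offsets[1:])
    order = np.argsort(faces.ravel(), kind="stable")
    face_ids = (order // faces.shape[1]).astype(np.int64)
    return offsets, face_ids


class _VertexFaceIndex:
    """KD-tree over vertices plus vertex->incident-face lists, for fast
    approximate-candidate closest-point queries on dense meshes."""

    def __init__(self, surface: LandmarkSurface, k: int = 4, adjacency=None):
        self.surface = surface
        self.tree = cKDTree(surface.points)
        self.k = min(k, surface.n_points)
        self.offsets, self.face_ids = (
            adjacency if adjacency is not None
            else vertex_face_adjacency(surface.faces, surface.n_points))
        self.triangles = surface.triangles()

    def query(self, points: np.ndarray, return_faces: bool = False):
        """Closest surface points by searching faces incident to the k
        nearest vertices of each query point (fully vectorized)."""
        points = np.asarray(points, dtype=float)
        n = len(points)
        _, vidx = self.tree.query(points, k=self.k)
        v = np.asarray(vidx).reshape(-1)                     # (n * k,)
        counts = self.offsets[v + 1] - self.offsets[v]
        pt_ids = np.repeat(np.arange(n), counts.reshape(n, -1).sum(axis=1))
        starts = np.repeat(self.offsets[v], counts)
        within = np.arange(counts.sum()) - np.repeat(
            np.cumsum(counts) - counts, counts)
        fc_ids = self.face_ids[starts + within]
        cand = _closest_on_triangles(points[pt_ids], self.triangles[fc_ids])
        d2 = np.einsum("ij,ij->i", cand - points[pt_ids], cand - points[pt_ids])
        best = np.full(n, np.inf)
        np.minimum.at(best, pt_ids, d2)
        pick = d2 <= best[pt_ids] + 1e-15
        closest = np.empty_like(points)
        closest[pt_ids[pick]] = cand[pick]
        if return_faces:
            best_face = np.empty(n, dtype=np.int64)
            best_face[pt_ids[pick]] = fc_ids[pick]
            return closest, np.sqrt(best), best_face
        return closest, np.sqrt(best)


def closest_points_on_surface(points, target: LandmarkSurface, exact: bool = False):
    """Closest points on ``target`` for a batch of query points.

    Returns ``(closest, dist)``.  The default candidate search (faces
    incident to the nearest vertices) is exact on meshes whose feature
    size exceeds the local edge length — the regime of all bone surfaces
    here; ``exact=True`` forces the all-faces scan.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if exact:
        tri = target.triangles()
        best_d2 = np.full(len(points), np.inf)
        closest = np.empty_like(points)
        chunk = max(1, int(4_000_000 // max(len(tri), 1)))
        for s in range(0, len(points), chunk):
            p = points[s:s + chunk]
            rep_p = np.repeat(p, len(tri), axis=0)
            rep_t = np.tile(tri, (len(p), 1, 1))
            cand = _closest_on_triangles(rep_p, rep_t).reshape(len(p), len(tri), 3)
            d2 = np.einsum("pfk,pfk->pf", cand - p[:, None, :], cand - p[:, None, :])
            j = d2.argmin(axis=1)
            best_d2[s:s + chunk] = d2[np.arange(len(p)), j]
            closest[s:s + chunk] = cand[np.arange(len(p)), j]
        return closest, np.sqrt(best_d2)
    return _VertexFaceIndex(target).query(points)


def mean_absolute_surface_distance(source: LandmarkSurface, target: LandmarkSurface,
                                   exact: bool = False):
    """Directional mean (and SD) of point-to-surface distances, source -> target.

    This is the segmentation-accuracy metric: for every source vertex, the
    unsigned distance to the closest point anywhere on the target surface.
    It is *not* symmetric; swap the arguments for the reverse direction.
    """
    _, d = closest_points_on_surface(source.points, target, exact=exact)
    return float(d.mean()), float(d.std())


# ---------------------------------------------------------------------------
# rigid registration

@dataclass
class ICPResult:
    transform: RigidTransform
    residual: float              # RMS closest-point distance, mm
    n_iterations: int
    converged: bool
    residuals: np.ndarray        # per-iteration RMS history


def _kabsch(src: np.ndarray, dst: np.ndarray, with_scale: bool = False):
    """Least-squares similarity transform src -> dst over paired points."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    A, B = src - mu_s, dst - mu_d
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if with_scale:
        denom = np.einsum("ij,ij->", A, A)
        s = float((S * np.diag(D)).sum() / denom) if denom > 0 else 1.0
    else:
        s = 1.0
    t = mu_d - s * R @ mu_s
    return RigidTransform(R, t, s)


def _principal_axis_inits(source_pts, target_pts):
    """Candidate initial rotations aligning principal axes: the 4 proper
    sign assignments of the eigenvector correspondence."""
    mu_s, mu_t = source_pts.mean(axis=0), target_pts.mean(axis=0)
    _, Vs = np.linalg.eigh(np.cov((source_pts - mu_s).T))
    _, Vt = np.linalg.eigh(np.cov((target_pts - mu_t).T))
    inits = []
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            signs = np.array([s1, s2, s1 * s2])  # keeps det(R) = +1
            R = Vt @ np.diag(signs) @ Vs.T
            if np.linalg.det(R) < 0:
                R = Vt @ np.diag(-signs) @ Vs.T
            inits.append(RigidTransform(R, mu_t - R @ mu_s))
    return inits


def _icp_refine(source_pts, target_pts, tree, T, max_iterations, tol):
    history = []
    prev = np.inf
    converged = False
    for _ in range(max_iterations):
        moved = T.apply(source_pts)
        d, j = tree.query(moved)
        rms = float(np.sqrt(np.mean(d ** 2)))
        history.append(rms)
        if prev - rms < tol:
            converged = True
            break
        prev = rms
        T = _kabsch(source_pts, target_pts[j], with_scale=False)
    return T, history, converged


def icp_register(source: LandmarkSurface, target: LandmarkSurface,
                 max_iterations: int = 200, tol: float = 1e-6,
                 init: Optional[RigidTransform] = None) -> ICPResult:
    """Point-to-point rigid ICP of source onto target (scale fixed at 1).

    Correspondence is nearest target vertex via a KD-tree; pose updates are
    closed-form least squares.  By default the pose is initialized by
    centroid + principal-axes alignment: plain point-to-point ICP has a
    narrow convergence basin (around 15 degrees), so each of the four
    proper axis-sign assignments is given a short trial run and the best
    one is refined.  The RMS residual is non-increasing per iteration;
    iteration stops when its change drops below ``tol`` (mm) or at
    ``max_iterations`` (then the result carries ``converged=False``).
    """
    tree = cKDTree(target.points)
    if init is None:
        candidates = [RigidTransform(np.eye(3),
                                     target.centroid() - source.centroid())]
        candidates += _principal_axis_inits(source.points, target.points)
        trials = []
        for T0 in candidates:
            T1, hist, _ = _icp_refine(source.points, target.points, tree, T0,
                                      max_iterations=15, tol=tol)
            trials.append((hist[-1], T1))
        # earliest candidate wins near-ties, so the trivial (centroid)
        # alignment beats a symmetry flip of equal residual
        best = min(r for r, _ in trials)
        T = next(T1 for r, T1 in trials if r <= best + 1e-9 * (1 + best))
    else:
        T = init
    T, history, converged = _icp_refine(source.points, target.points, tree, T,
                                        max_iterations, tol)
    return ICPResult(T, history[-1], len(history), converged, np.array(history))


# ---------------------------------------------------------------------------
# mesh and region I/O

def save_surface(surface: LandmarkSurface, path) -> Path:
    """Write a mesh (PLY or OBJ by extension) plus a ``<stem>.meta.json`` sidecar."""
    path = Path(path)
    tm = trimesh.Trimesh(surface.points, surface.faces, process=False)
    tm.export(path)
    sidecar = path.with_suffix("").with_suffix(".meta.json")
    payload = surface.meta.to_dict()
    payload["topology"] = surface.topology
    sidecar.write_text(json.dumps(payload, indent=1))
    return path


def load_surface(path) -> LandmarkSurface:
    """Read a PLY/OBJ mesh, preserving vertex order, with its JSON sidecar."""
    path = Path(path)
    tm = trimesh.load(path, process=False, force="mesh")
    sidecar = path.with_suffix("").with_suffix(".meta.json")
    topology = "anon"
    meta = SurfaceMeta()
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        topology = payload.pop("topology", "anon")
        meta = SurfaceMeta.from_dict(payload)
    return LandmarkSurface(np.asarray(tm.vertices), np.asarray(tm.faces),
                           topology, meta)
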