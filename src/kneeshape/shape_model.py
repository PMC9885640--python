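"""Statistical shape models of corresponded bone surfaces.

A shape population is a set of :class:`~kneeshape.mesh.LandmarkSurface`
objects sharing one landmark topology.  Generalized Procrustes analysis
removes pose (and, by default, size), PCA of the aligned coordinates
yields a linear shape space, and :func:`fit_model_to_surface` fits the
model to an *arbitrary* triangulated surface — the step that lets a model
trained on one modality parametrize a surface segmented from another.

With size normalization on (the default used for shape scoring), the
aligned frame is centroid-size-normalized, so shape parameters are
invariant under uniform scaling of the input surfaces.  Bone area and
joint-space width are always measured on the original, unnormalized
surfaces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .mesh import (LandmarkSurface, RigidTransform, SurfaceMeta, _kabsch,
                   mean_absolute_surface_distance, vertex_face_adjacency,
                   _VertexFaceIndex)

__all__ = [
    "ShapePopulation",
    "AlignedPopulation",
    "ShapeModel",
    "FitResult",
    "procrustes_align",
    "build_shape_model",
    "project",
    "reconstruct",
    "fit_model_to_surface",
    "save_model",
    "load_model",
]

SCHEMA_VERSION = 1


class ShapePopulation:
    """An ordered collection of corresponded surfaces (one topology)."""

    def __init__(self, surfaces: Sequence[LandmarkSurface]):
        surfaces = list(surfaces)
        if not surfaces:
            raise ValueError("population is empty")
        first = surfaces[0]
        for s in surfaces[1:]:
            if not s.same_topology(first) or not np.array_equal(s.faces, first.faces):
                raise ValueError("population mixes topologies")
        self.surfaces = surfaces
        self.topology = first.topology
        self.faces = first.faces

    def __len__(self) -> int:
        return len(self.surfaces)

    def __iter__(self):
        return iter(self.surfaces)

    def coords(self) -> np.ndarray:
        """(n_shapes, n_points, 3) coordinate stack."""
        return np.stack([s.points for s in self.surfaces])

    def labels(self, key: str) -> List[str]:
        return [getattr(s.meta, key) for s in self.surfaces]


@dataclass
class AlignedPopulation:
    coords: np.ndarray                 # (n_shapes, n_points, 3) in aligned frame
    mean: np.ndarray                   # (n_points, 3), centroid at origin
    transforms: List[RigidTransform]   # original -> aligned frame
    with_scale: bool
    topology: str
    faces: np.ndarray
    labels: dict = field(default_factory=dict)


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0)


def _centroid_size(x: np.ndarray) -> float:
    return float(np.linalg.norm(_center(x)))


def _align_one(points: np.ndarray, reference: np.ndarray,
               with_scale: bool) -> RigidTransform:
    """Full Procrustes superimposition of one shape onto a reference."""
    return _kabsch(points, reference, with_scale=with_scale)


def procrustes_align(population: ShapePopulation, with_scale: bool = True,
                     tol: float = 1e-7, max_iterations: int = 100) -> AlignedPopulation:
    """Generalized Procrustes alignment of a corresponded population.

    Iteratively superimposes every shape on the current mean (rotation +
    translation, plus size normalization when ``with_scale``), re-estimates
    the mean, and stops when the mean moves by less than ``tol``.  When
    ``with_scale`` is on, shapes and mean live in a centroid-size-normalized
    frame (centroid size 1), which makes downstream shape parameters
    scale-invariant.
    """
    X = population.coords().astype(float)
    sizes = np.array([_centroid_size(x) for x in X])
    if np.any(sizes == 0):
        raise ValueError("degenerate (all-coincident) shape in population")

    # permutation-invariant initialization: average of the centered
    # (and size-normalized) shapes, so alignment does not depend on order
    pre = np.stack([_center(x) for x in X])
    if with_scale:
        pre = pre / sizes[:, None, None]
    ref = _center(pre.mean(axis=0))
    if np.linalg.norm(ref) == 0:
        raise ValueError("degenerate population: mean shape collapses to a point")
    if with_scale:
        ref = ref / np.linalg.norm(ref)
    aligned = X.copy()
    for _ in range(max_iterations):
        for i in range(len(X)):
            T = _align_one(X[i], ref, with_scale)
            aligned[i] = T.apply(X[i])
        mean = _center(aligned.mean(axis=0))
        if with_scale:
            mean = mean / np.linalg.norm(mean)
        shift = np.linalg.norm(mean - ref) / np.sqrt(mean.size)
        ref = mean
        if shift < tol:
            break
    transforms = [_align_one(X[i], ref, with_scale) for i in range(len(X))]
    aligned = np.stack([transforms[i].apply(X[i]) for i in range(len(X))])
    # the stored mean is the empirical mean of the final aligned coordinates
    # (not the previous iterate), so PCA centering is exact; its centroid
    # size is 1 up to the convergence tolerance
    ref = _center(aligned.mean(axis=0))
    return AlignedPopulation(aligned, ref, transforms, with_scale,
                             population.topology, population.faces,
                             {"group": population.labels("group"),
                              "sex": population.labels("sex"),
                              "subject": population.labels("subject")})


@dataclass
class ShapeModel:
    """Mean + orthonormal PCA modes of an aligned population."""

    mean: np.ndarray            # (n_points, 3)
    modes: np.ndarray           # (3 n_points, n_modes), orthonormal columns
    mode_variances: np.ndarray  # (n_modes,), non-increasing
    faces: np.ndarray
    topology: str
    with_scale: bool
    total_variance: float

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    @property
    def n_points(self) -> int:
        return len(self.mean)

    def mean_surface(self) -> LandmarkSurface:
        return LandmarkSurface(self.mean.copy(), self.faces, self.topology,
                               SurfaceMeta(modality="synthetic-truth"))


def build_shape_model(aligned: AlignedPopulation,
                      variance_retained: float = 0.98) -> ShapeModel:
    """PCA of the aligned coordinates about the Procrustes mean.

    Retains the smallest number of leading modes whose cumulative variance
    reaches ``variance_retained`` (1.0 keeps every non-null mode).  Each
    mode's sign is fixed so that its largest-magnitude training coefficient
    is positive, making models reproducible across runs.
    """
    if not 0 < variance_retained <= 1:
        raise ValueError("variance_retained must be in (0, 1]")
    n = len(aligned.coords)
    if n < 2:
        raise ValueError("need at least 2 shapes to build a model")
    X = aligned.coords.reshape(n, -1)
    mu = aligned.mean.reshape(-1)
    D = X - mu
    U, S, Vt = np.linalg.svd(D, full_matrices=False)
    variances = S ** 2 / (n - 1)
    nonnull = variances > max(variances.max(), 1.0) * 1e-12
    variances, Vt = variances[nonnull], Vt[nonnull]
    total = float(variances.sum())
    if variance_retained >= 1.0:
        k = len(variances)
    else:
        frac = np.cumsum(variances) / total
        k = int(np.searchsorted(frac, variance_retained) + 1)
    modes = Vt[:k].T
    # sign convention: largest-|coefficient| over the training set positive
    coeffs = D @ modes
    j = np.abs(coeffs).argmax(axis=0)
    signs = np.sign(coeffs[j, np.arange(k)])
    signs[signs == 0] = 1.0
    modes = modes * signs
    return ShapeModel(aligned.mean.copy(), modes, variances[:k].copy(),
                      aligned.faces, aligned.topology, aligned.with_scale, total)


def _align_to_model(model: ShapeModel, points: np.ndarray) -> np.ndarray:
    T = _align_one(points, model.mean, with_scale=model.with_scale)
    return T.apply(points)


def project(model: ShapeModel, shape: LandmarkSurface,
            align: bool = True) -> np.ndarray:
    """Shape parameters b of a corresponded surface.

    The surface is Procrustes-superimposed on the model mean (with size
    normalization if the model uses it) and projected on the modes:
    ``b = modes^T (x_aligned - mean)``.  Pass ``align=False`` for a shape
    already expressed in the model's aligned frame (e.g. the output of
    :func:`reconstruct`); re-aligning such a shape would perturb b at the
    level of the optimal residual similarity transform.
    """
    if shape.topology != model.topology or shape.n_points != model.n_points:
        raise ValueError("surface topology does not match model")
    x = _align_to_model(model, shape.points) if align else shape.points
    return model.modes.T @ (x.reshape(-1) - model.mean.reshape(-1))


def reconstruct(model: ShapeModel, b: np.ndarray,
                meta: Optional[SurfaceMeta] = None) -> LandmarkSurface:
    """Shape instance mean + modes @ b, in the model's aligned frame."""
    b = np.asarray(b, dtype=float)
    if b.ndim != 1 or len(b) > model.n_modes:
        raise ValueError("parameter vector longer than mode count")
    x = model.mean.reshape(-1) + model.modes[:, :len(b)] @ b
    return LandmarkSurface(x.reshape(-1, 3), model.faces, model.topology,
                           meta if meta is not None else
                           SurfaceMeta(modality="synthetic-truth"))


def _barycentric(points: np.ndarray, tri: np.ndarray):
    """Clamped barycentric coordinates of (projected) points in triangles."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    v0, v1, v2 = b - a, c - a, points - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    den = d00 * d11 - d01 * d01
    den = np.where(np.abs(den) < 1e-18, 1.0, den)
    v = np.clip((d11 * d20 - d01 * d21) / den, 0.0, 1.0)
    w = np.clip((d00 * d21 - d01 * d20) / den, 0.0, 1.0)
    s = v + w
    over = s > 1
    v[over] /= s[over]
    w[over] /= s[over]
    return np.stack([1.0 - v - w, v, w], axis=1)


@dataclass
class FitResult:
    b: np.ndarray
    pose: RigidTransform        # model aligned frame -> target world frame
    residual_mm: float          # mean absolute point-to-surface distance
    residual_sd_mm: float
    n_iterations: int
    converged: bool
    history: np.ndarray         # per-outer-iteration RMS paired distance


def fit_model_to_surface(model: ShapeModel, target: LandmarkSurface,
                         max_iterations: int = 150, tol: float = 1e-9,
                         clamp_sd: Optional[float] = 3.0,
                         reverse_stride: int = 3) -> FitResult:
    """Fit a shape model to an arbitrary triangulated surface.

    Alternating minimization over pose, correspondence and shape.
    Correspondences are bidirectional: every model landmark is paired with
    its closest point on the target surface, and every target vertex with
    its closest point on the current instance surface (expressed in
    barycentric coordinates of the instance triangle).  The one-directional
    variant admits "sliding" fixed points — landmark sets lying on the
    target surface but tangentially displaced — and the reverse constraints
    remove them by requiring the instance to *cover* the target.  Each
    outer iteration then solves (i) pose: closed-form similarity over the
    pooled pairs; (ii) shape: linear least squares for b over both pair
    sets, optionally clamped to ``|b_k| <= clamp_sd * sqrt(variance_k)``.
    Iteration stops when the pooled RMS paired distance, expressed in the
    model's aligned frame (i.e. divided by the pose scale), improves by
    less than ``tol`` — a criterion independent of the target's size.
    Reverse constraints are taken from every ``reverse_stride``-th target
    vertex (weighted by the stride so the two directions stay balanced);
    on the smooth, densely sampled surfaces this fits, the subsampling
    changes the solution far less than the surface noise does.

    This is the cross-modality pathway: a model trained on one modality's
    corresponded surfaces produces an instance with *model* landmarks but
    the *target's* shape, which can then be scored in the model's space.
    """
    b = np.zeros(model.n_modes)
    sqrt_var = np.sqrt(model.mode_variances)
    index = _VertexFaceIndex(target, k=2)
    faces = model.faces
    adjacency = vertex_face_adjacency(faces, model.n_points)
    mu = model.mean.reshape(-1)
    mu_pts = model.mean
    Phi = model.modes
    Phi_pts = Phi.reshape(-1, 3, Phi.shape[1])     # (n_points, 3, n_modes)
    sub = np.arange(0, target.n_points, max(1, reverse_stride))
    t_sub = target.points[sub]
    w_rev = float(max(1, reverse_stride))

    instance = reconstruct(model, b).points
    # initial pose: match centroid and centroid size (the model frame may be
    # size-normalized, so a naive rigid pre-alignment would be degenerate),
    # then refine with similarity-ICP pose-only iterations
    s0 = (_centroid_size(target.points) / _centroid_size(instance)
          if model.with_scale else 1.0)
    pose = RigidTransform(np.eye(3),
                          target.centroid() - s0 * instance.mean(axis=0), s0)
    for _ in range(30):
        _, jj = index.tree.query(pose.apply(instance))
        new = _kabsch(instance, target.points[jj], with_scale=model.with_scale)
        if np.allclose(new.rotation, pose.rotation, atol=1e-9) and \
           np.allclose(new.translation, pose.translation, atol=1e-9):
            pose = new
            break
        pose = new

    history = []
    prev = np.inf
    converged = False
    for _ in range(max_iterations):
        moved = pose.apply(instance)
        # forward: model landmarks -> target surface
        y_fwd, d_fwd = index.query(moved)
        # reverse: (subsampled) target vertices -> instance surface, model frame
        t_model = pose.inverse().apply(t_sub)
        inst_index = _VertexFaceIndex(
            LandmarkSurface(instance, faces, model.topology, validate=False),
            k=1, adjacency=adjacency)
        p_rev, d_rev, f_rev = inst_index.query(t_model, return_faces=True)
        rms = float(np.sqrt((np.sum(d_fwd ** 2)
                             + pose.scale ** 2 * np.sum(d_rev ** 2))
                            / (len(d_fwd) + len(d_rev))))
        history.append(rms)
        # convergence measured in the model's aligned frame so the criterion
        # is independent of the target's physical size
        if prev - rms < tol * pose.scale:
            converged = True
            break
        prev = rms

        # pose: similarity over pooled pairs (model frame -> world frame)
        src = np.vstack([instance, p_rev])
        dst = np.vstack([y_fwd, t_sub])
        pose = _kabsch(src, dst, with_scale=model.with_scale)

        # shape: least squares for b over both pair sets
        y_model = pose.inverse().apply(y_fwd).reshape(-1)
        rhs = Phi.T @ (y_model - mu)                   # forward, identity design
        verts = faces[f_rev]                           # (m, 3) vertex ids
        t_model = pose.inverse().apply(t_sub)
        W = _barycentric(t_model, instance[verts])
        A = np.einsum("mc,mcdk->mdk", W, Phi_pts[verts]).reshape(-1, Phi.shape[1])
        pred_mu = np.einsum("mc,mcd->md", W, mu_pts[verts])
        r = (t_model - pred_mu).reshape(-1)
        H = np.eye(Phi.shape[1]) + w_rev * (A.T @ A)
        b = np.linalg.solve(H, rhs + w_rev * (A.T @ r))
        if clamp_sd is not None:
            lim = clamp_sd * sqrt_var
            b = np.clip(b, -lim, lim)
        instance = reconstruct(model, b).points

    world = LandmarkSurface(pose.apply(instance), model.faces, model.topology)
    res_mean, res_sd = mean_absolute_surface_distance(world, target)
    return FitResult(b, pose, res_mean, res_sd, len(history), converged,
                     np.array(history))


# ---------------------------------------------------------------------------
# serialization: a directory holding arrays (.npz) and a JSON manifest

def save_model(model: ShapeModel, directory, provenance: Optional[dict] = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "arrays.npz", mean=model.mean, modes=model.modes,
             mode_variances=model.mode_variances, faces=model.faces)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "topology": model.topology,
        "with_scale": model.with_scale,
        "total_variance": model.total_variance,
        "n_modes": model.n_modes,
        "provenance": provenance or {},
    }
    (directory / "model.json").write_text(json.dumps(manifest, indent=1))
    return directory


def load_model(directory) -> ShapeModel:
    directory = Path(directory)
    manifest = json.loads((directory / "model.json").read_text())
    if manifest["schema_version"] != SCHEMA_VERSION:
        raise ValueError("unsupported model schema version")
    arr = np.load(directory / "arrays.npz")
    return ShapeModel(arr["mean"], arr["modes"], arr["mode_variances"],
                      arr["faces"], manifest["topology"],
                      manifest["with_scale"], manifest["total_variance"])
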