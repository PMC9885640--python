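"""Synthetic paired CT/MR knee-surface generator with known ground truth.

Builds a schematic distal-femur + proximal-tibia landmark template (two
condylar lobes and a trochlear groove band over two gently dished tibial
plateau patches), deforms it along a fixed OA-like deformation field
(marginal osteophyte-like bulge plus plateau/condyle flattening) scaled by
a latent severity t, and renders each subject's bones as they would be
observed by either modality:

* CT — the true surface plus small smooth segmentation-like noise, knee
  extended.
* MR — the surface offset *inward* by delta mm along vertex normals (the
  bone boundary seen by MR sits inside the CT boundary), warped by a
  smooth low-frequency distortion field (field-inhomogeneity analogue),
  plus noise; the femur is slightly flexed and the tibia externally
  rotated about its long axis (screw-home analogue), because the knee is
  scanned supported and not fully extended.

Test-retest replicates re-render the same true surface with independent
noise and a small random repositioning.

The OA deformation field is geometric fiction, not anatomy: it exists so
that shape scores have a recoverable ground-truth direction.  Group labels
derived from thresholds on t stand in for radiographic grades without any
claim of equivalence.  Everything is deterministic given the configured
seed.

Axes: x medial(-)/lateral(+), y posterior(-)/anterior(+), z inferior/
superior; units mm.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .mesh import LandmarkSurface, RigidTransform, SurfaceMeta, vertex_normals
from .measures import RegionDefinition

__all__ = [
    "SyntheticConfig",
    "SyntheticKnee",
    "TemplateKnee",
    "make_template_knee",
    "sample_population",
    "render_modality",
    "make_test_retest",
    "parallel_patch_fixture",
]

# template geometry constants (mm)
_TIBIA_X = (-42.0, 42.0)
_TIBIA_Y = (-27.0, 27.0)
_FEMUR_X = (-42.0, 42.0)
_FEMUR_Y = (-32.0, 38.0)
_GAP0 = 12.0            # femoral base height above the tibial plane
_CONDYLE_AMP = 8.0      # condylar lobe depth
_CONDYLE_X = 20.0       # +/- lobe centre, mediolateral
_CONDYLE_Y = -2.0       # lobe centre, anteroposterior
_SIGMA_X = 9.0
_SIGMA_Y_MED = 7.0      # medial lobe is shorter anteroposteriorly than lateral:
_SIGMA_Y_LAT = 12.0     # the asymmetry that makes tibial rotation matter medially
_TROCHLEA_AMP = 5.0
# medial plateau dish is slightly deeper and wider than the lateral one
# (no mirror symmetry: real tibiae have none, and exact symmetry would
# make medial/lateral registrations ambiguous)
_DISH_DEPTH_MED = 1.6
_DISH_DEPTH_LAT = 1.3
_DISH_SIGMA_MED = 9.5
_DISH_SIGMA_LAT = 8.5
_EDGE_MARGIN = 6.0      # width of the convex rolled border of each patch
_EDGE_DROP = 3.0
_CENTRAL_RADIUS = 11.0  # cMT/cLT disc radius
_TROCHLEA_Y_SPLIT = 15.0

# OA deformation field
_BULGE_AMP = 0.35       # mm of marginal bulge per unit t
_BULGE_SCALE = 4.0      # e-folding distance of the bulge weight from the margin
_FLATTEN_RATE = 0.06    # fraction of dish/condyle relief removed per unit t


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic paired-modality dataset.

    Defaults are the package's reference conditions: a 60-knee cohort
    spanning the severity range, a 0.2 mm inward MR boundary offset (inside
    the sub-millimetre segmentation-accuracy regime), low-frequency MR
    distortion, a flexed and externally rotated MR pose, and smooth
    segmentation-like surface noise of 0.1 mm per scan.
    """

    n_subjects: int = 60
    resolution: int = 2            # grid level; vertex spacing = 2.6 / level mm
    seed: int = 0
    # latent severity and group thresholds
    t_min: float = -2.0
    t_max: float = 7.0
    non_oa_max_t: float = 0.5
    oa_min_t: float = 2.5
    moderate_max_t: float = 5.5    # upper bound of the moderate-severity stratum
    # anatomy variation
    shape_noise_mm: float = 0.5    # smooth per-subject anatomy noise (SD)
    size_sd: float = 0.05          # lognormal SD of per-subject global size
    n_levels: int = 1              # sex-like strata; level B scaled by size_offset
    size_offset: float = 1.08
    # modality effects
    modality_offset_mm: float = 0.2    # MR boundary sits this far inside CT's
    distortion_amplitude_mm: float = 0.3
    distortion_length_mm: float = 40.0
    mr_flexion_deg: float = 5.0
    mr_tibial_rotation_deg: float = 15.0
    surface_noise_mm: float = 0.1      # per-scan smooth noise (SD)
    noise_length_mm: float = 15.0
    # repositioning between acquisitions / replicates
    reposition_deg: float = 2.0
    reposition_mm: float = 2.0
    # test-retest
    n_retest: int = 20

    def __post_init__(self):
        if self.n_subjects < 4:
            raise ValueError("need at least 4 subjects")
        for name in ("shape_noise_mm", "size_sd", "modality_offset_mm",
                     "distortion_amplitude_mm", "surface_noise_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class TemplateKnee:
    femur: LandmarkSurface
    tibia: LandmarkSurface
    regions: Dict[str, RegionDefinition]
    resolution: int
    spacing_mm: float
    oa_field_femur: np.ndarray = None   # (n, 3) displacement per unit t
    oa_field_tibia: np.ndarray = None


@dataclass
class SyntheticKnee:
    """One subject: latent ground truth plus deterministic render seeds."""

    subject: str
    t: float
    group: str                      # nonOA | intermediate | OA
    level: str                      # sex-like stratum key
    size: float
    truth_femur: LandmarkSurface
    truth_tibia: LandmarkSurface
    render_seeds: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# template construction

def _grid(x0, x1, y0, y1, h, flip_winding=False):
    nx = int(round((x1 - x0) / h)) + 1
    ny = int(round((y1 - y0) / h)) + 1
    xs = np.linspace(x0, x1, nx)
    ys = np.linspace(y0, y1, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    i, j = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), indexing="ij")
    v00 = (i * ny + j).ravel()
    v10 = ((i + 1) * ny + j).ravel()
    v01 = (i * ny + j + 1).ravel()
    v11 = ((i + 1) * ny + j + 1).ravel()
    # CCW seen from +z
    faces = np.concatenate([np.column_stack([v00, v10, v11]),
                            np.column_stack([v00, v11, v01])])
    if flip_winding:
        faces = faces[:, ::-1]
    return pts, faces


def _edge_roll(x, y, x_rng, y_rng):
    """Quadratic roll-off within _EDGE_MARGIN of the rectangle boundary."""
    d = np.minimum.reduce([x - x_rng[0], x_rng[1] - x,
                           y - y_rng[0], y_rng[1] - y])
    w = np.clip((_EDGE_MARGIN - d) / _EDGE_MARGIN, 0.0, None)
    return _EDGE_DROP * w ** 2


def _dish(x, y, cx, sigma):
    r2 = (x - cx) ** 2 + y ** 2
    return np.exp(-r2 / (2 * sigma ** 2))


def _dish_relief(x, y):
    """Total (positive) dish depth profile of the tibial plateau."""
    return (_DISH_DEPTH_MED * _dish(x, y, -_CONDYLE_X, _DISH_SIGMA_MED)
            + _DISH_DEPTH_LAT * _dish(x, y, _CONDYLE_X, _DISH_SIGMA_LAT))


def _condyle(x, y, cx, sigma_y):
    return np.exp(-((x - cx) ** 2 / (2 * _SIGMA_X ** 2)
                    + (y - _CONDYLE_Y) ** 2 / (2 * sigma_y ** 2)))


def _trochlea(x, y):
    band = np.exp(-(y - 27.0) ** 2 / (2 * 7.0 ** 2))
    facets = (np.exp(-(x + 12.0) ** 2 / (2 * 8.0 ** 2))
              + np.exp(-(x - 12.0) ** 2 / (2 * 8.0 ** 2)))
    return band * facets


def _tibia_height(x, y):
    z = -_edge_roll(x, y, _TIBIA_X, _TIBIA_Y)
    z -= _dish_relief(x, y)
    return z


def _femur_height(x, y):
    z = np.full_like(x, _GAP0)
    z -= _CONDYLE_AMP * (_condyle(x, y, -_CONDYLE_X, _SIGMA_Y_MED)
                         + _condyle(x, y, _CONDYLE_X, _SIGMA_Y_LAT))
    z -= _TROCHLEA_AMP * _trochlea(x, y)
    # rim curls up, away from the tibia: convex w.r.t. the femur's outward
    # (downward) normal, like the condylar surface wrapping around the bone
    z += _edge_roll(x, y, _FEMUR_X, _FEMUR_Y)
    return z


def _oa_displacement(surface: LandmarkSurface, x_rng, y_rng,
                     relief: np.ndarray) -> np.ndarray:
    """Per-unit-severity deformation: marginal bulge along vertex normals
    plus partial flattening of the articular relief (z displacement)."""
    x, y = surface.points[:, 0], surface.points[:, 1]
    d = np.minimum.reduce([x - x_rng[0], x_rng[1] - x,
                           y - y_rng[0], y_rng[1] - y])
    w = np.exp(-np.clip(d, 0, None) / _BULGE_SCALE)
    normals = vertex_normals(surface)
    normals = np.nan_to_num(normals)
    disp = _BULGE_AMP * w[:, None] * normals
    disp[:, 2] += _FLATTEN_RATE * relief
    return disp


def make_template_knee(resolution: int = 2) -> TemplateKnee:
    """Schematic femur + tibia template with regions and OA deformation field.

    ``resolution`` sets the landmark spacing (2.6 / resolution mm).  The
    central joint-space regions must contain at least 200 vertices, which
    puts the minimum usable resolution at 2; at resolution 7 they reach
    the order of 2000 landmarks.
    """
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    h = 2.6 / resolution

    t_pts, t_faces = _grid(*_TIBIA_X, *_TIBIA_Y, h)
    t_pts[:, 2] = _tibia_height(t_pts[:, 0], t_pts[:, 1])
    tibia = LandmarkSurface(t_pts, t_faces, topology=f"tibia-r{resolution}",
                            meta=SurfaceMeta(bone="tibia"))

    f_pts, f_faces = _grid(*_FEMUR_X, *_FEMUR_Y, h, flip_winding=True)
    f_pts[:, 2] = _femur_height(f_pts[:, 0], f_pts[:, 1])
    femur = LandmarkSurface(f_pts, f_faces, topology=f"femur-r{resolution}",
                            meta=SurfaceMeta(bone="femur"))

    regions = _make_regions(femur, tibia)
    for name in ("cMT", "cLT"):
        if regions[name].size < 200:
            raise ValueError(
                f"resolution {resolution} gives only {regions[name].size} "
                f"vertices in {name}; need >= 200 (use resolution >= 2)")

    # severity deformation fields (per unit t)
    t_relief = _dish_relief(t_pts[:, 0], t_pts[:, 1])
    f_relief = _CONDYLE_AMP * 0.5 * (
        _condyle(f_pts[:, 0], f_pts[:, 1], -_CONDYLE_X, _SIGMA_Y_MED)
        + _condyle(f_pts[:, 0], f_pts[:, 1], _CONDYLE_X, _SIGMA_Y_LAT))
    oa_tibia = _oa_displacement(tibia, _TIBIA_X, _TIBIA_Y, t_relief)
    oa_femur = _oa_displacement(femur, _FEMUR_X, _FEMUR_Y, f_relief)

    return TemplateKnee(femur, tibia, regions, resolution, h,
                        oa_field_femur=oa_femur, oa_field_tibia=oa_tibia)


def _make_regions(femur: LandmarkSurface,
                  tibia: LandmarkSurface) -> Dict[str, RegionDefinition]:
    fx, fy = femur.points[:, 0], femur.points[:, 1]
    tx, ty = tibia.points[:, 0], tibia.points[:, 1]
    post = fy <= _TROCHLEA_Y_SPLIT
    # area regions run to the bone margin: the convex rolled rim is where
    # marginal (osteophyte-like) growth lives, so it belongs to the tAB
    regions = {
        "MF.tAB": np.flatnonzero(post & (fx < 0)),
        "LF.tAB": np.flatnonzero(post & (fx > 0)),
        "TrFMed.tAB": np.flatnonzero(~post & (fx < 0)),
        "TrFLat.tAB": np.flatnonzero(~post & (fx > 0)),
        "MT.tAB": np.flatnonzero(tx < 0),
        "LT.tAB": np.flatnonzero(tx > 0),
        "cMT": np.flatnonzero((tx + _CONDYLE_X) ** 2 + ty ** 2
                              <= _CENTRAL_RADIUS ** 2),
        "cLT": np.flatnonzero((tx - _CONDYLE_X) ** 2 + ty ** 2
                              <= _CENTRAL_RADIUS ** 2),
    }
    out = {}
    for name, idx in regions.items():
        topo = tibia.topology if name.startswith(("MT", "LT", "c")) else femur.topology
        out[name] = RegionDefinition(name, topo, idx)
    return out


# ---------------------------------------------------------------------------
# random smooth fields

def _smooth_field(points: np.ndarray, rng: np.random.Generator,
                  sd_mm: float, length_mm: float, n_waves: int = 12) -> np.ndarray:
    """Smooth random vector field with pointwise SD ~ sd_mm per component,
    built from random plane waves of wavelength ~ length_mm."""
    if sd_mm == 0:
        return np.zeros_like(points)
    disp = np.zeros_like(points)
    amp = sd_mm * np.sqrt(2.0 / n_waves)
    for _ in range(n_waves):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        omega = 2 * np.pi / (length_mm * rng.lognormal(0.0, 0.3))
        phase = rng.uniform(0, 2 * np.pi)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        disp += amp * np.sin(points @ (omega * direction) + phase)[:, None] * axis
    return disp


# ---------------------------------------------------------------------------
# population sampling

def sample_population(cfg: SyntheticConfig,
                      template: Optional[TemplateKnee] = None
                      ) -> Tuple[TemplateKnee, List[SyntheticKnee]]:
    """Draw a cohort of ground-truth knees spanning the severity range.

    Latent severity t is uniform on [t_min, t_max]; each subject's true
    surfaces are template + t * OA-field + smooth anatomy noise, scaled by
    a per-subject size factor.  Deterministic given ``cfg.seed``: the same
    configuration always yields bit-identical surfaces.
    """
    if template is None:
        template = make_template_knee(cfg.resolution)
    root = np.random.SeedSequence(cfg.seed)
    subject_seeds = root.spawn(cfg.n_subjects)
    knees = []
    for i, ss in enumerate(subject_seeds):
        truth_ss, ct_ss, mr_ss, rt_ss = ss.spawn(4)
        rng = np.random.default_rng(truth_ss)
        t = float(rng.uniform(cfg.t_min, cfg.t_max))
        level = "A" if cfg.n_levels == 1 else ("A" if i % cfg.n_levels == 0 else "B")
        size = float(np.exp(rng.normal(0.0, cfg.size_sd)))
        if level == "B":
            size *= cfg.size_offset
        group = ("nonOA" if t <= cfg.non_oa_max_t
                 else "OA" if t >= cfg.oa_min_t else "intermediate")
        subject = f"syn{i:03d}"

        def _truth(surface, oa_field, bone):
            pts = surface.points + t * oa_field
            pts = pts + _smooth_field(pts, rng, cfg.shape_noise_mm, 30.0)
            pts = pts * size
            meta = SurfaceMeta(bone=bone, modality="synthetic-truth",
                               subject=subject, sex=level, group=group)
            return LandmarkSurface(pts, surface.faces, surface.topology, meta)

        knees.append(SyntheticKnee(
            subject=subject, t=t, group=group, level=level, size=size,
            truth_femur=_truth(template.femur, template.oa_field_femur, "femur"),
            truth_tibia=_truth(template.tibia, template.oa_field_tibia, "tibia"),
            render_seeds={"CT": ct_ss, "MR": mr_ss, "retest": rt_ss},
        ))
    return template, knees


# ---------------------------------------------------------------------------
# modality rendering

def _offset_inward(surface: LandmarkSurface, delta: float) -> np.ndarray:
    """Move the surface ``delta`` mm against its outward normals (into the
    bone).  Raises if the offset is large enough to flip any triangle."""
    if delta == 0:
        return surface.points.copy()
    normals = np.nan_to_num(vertex_normals(surface))
    pts = surface.points - delta * normals
    before = np.cross(surface.points[surface.faces[:, 1]] - surface.points[surface.faces[:, 0]],
                      surface.points[surface.faces[:, 2]] - surface.points[surface.faces[:, 0]])
    after = np.cross(pts[surface.faces[:, 1]] - pts[surface.faces[:, 0]],
                     pts[surface.faces[:, 2]] - pts[surface.faces[:, 0]])
    if np.any(np.einsum("ij,ij->i", before, after) <= 0):
        raise ValueError(f"inward offset {delta} mm self-intersects the surface")
    return pts


def _random_repositioning(rng, max_deg, max_mm) -> RigidTransform:
    axis = rng.normal(size=3)
    angle = rng.uniform(-max_deg, max_deg)
    trans = rng.uniform(-max_mm, max_mm, size=3)
    return RigidTransform.from_axis_angle(axis, angle, trans)


def render_modality(knee: SyntheticKnee, modality: str, cfg: SyntheticConfig,
                    rng: Optional[np.random.Generator] = None
                    ) -> Tuple[LandmarkSurface, LandmarkSurface]:
    """Observed (femur, tibia) surfaces for one acquisition of one knee.

    CT: true surface + smooth noise, extended pose.  MR: surface offset
    inward by the modality offset, warped by one shared low-frequency
    distortion field, plus noise; the femur is flexed and the tibia
    externally rotated about its long axis; finally a small whole-knee
    repositioning is applied.  With the default per-knee rng stream, every
    call renders bit-identical surfaces.
    """
    if modality not in ("CT", "MR"):
        raise ValueError("modality must be 'CT' or 'MR'")
    if rng is None:
        rng = np.random.default_rng(knee.render_seeds[modality])

    delta = cfg.modality_offset_mm if modality == "MR" else 0.0
    f_pts = _offset_inward(knee.truth_femur, delta)
    t_pts = _offset_inward(knee.truth_tibia, delta)

    if modality == "MR":
        warp_rng = np.random.default_rng(rng.integers(2 ** 31))
        warp_state = warp_rng.bit_generator.state
        f_pts = f_pts + _smooth_field(f_pts, warp_rng,
                                      cfg.distortion_amplitude_mm,
                                      cfg.distortion_length_mm)
        warp_rng.bit_generator.state = warp_state   # same field for both bones
        t_pts = t_pts + _smooth_field(t_pts, warp_rng,
                                      cfg.distortion_amplitude_mm,
                                      cfg.distortion_length_mm)
        flex = RigidTransform.from_axis_angle(
            (1, 0, 0), cfg.mr_flexion_deg, center=(0.0, _CONDYLE_Y, 4.0))
        f_pts = flex.apply(f_pts)
        # external tibial rotation about the tibial long axis (right-knee
        # sign convention: positive external rotation is clockwise from above)
        rot = RigidTransform.from_axis_angle(
            (0, 0, -1), cfg.mr_tibial_rotation_deg, center=(0.0, 0.0, 0.0))
        t_pts = rot.apply(t_pts)

    f_pts = f_pts + _smooth_field(f_pts, rng, cfg.surface_noise_mm,
                                  cfg.noise_length_mm)
    t_pts = t_pts + _smooth_field(t_pts, rng, cfg.surface_noise_mm,
                                  cfg.noise_length_mm)

    common = _random_repositioning(rng, cfg.reposition_deg, cfg.reposition_mm)
    f_pts = common.apply(f_pts)
    t_pts = common.apply(t_pts)

    def _obs(pts, truth, bone):
        meta = dataclasses.replace(truth.meta, modality=modality, bone=bone)
        return LandmarkSurface(pts, truth.faces, truth.topology, meta)

    return (_obs(f_pts, knee.truth_femur, "femur"),
            _obs(t_pts, knee.truth_tibia, "tibia"))


def make_test_retest(knee: SyntheticKnee, cfg: SyntheticConfig,
                     modality: str = "MR", n_replicates: int = 2
                     ) -> List[Tuple[LandmarkSurface, LandmarkSurface]]:
    """Replicate acquisitions of the same knee: same true surface,
    independent noise and repositioning per replicate."""
    rng = np.random.default_rng(knee.render_seeds["retest"])
    out = []
    for _ in range(n_replicates):
        rep_rng = np.random.default_rng(rng.integers(2 ** 31))
        out.append(render_modality(knee, modality, cfg, rng=rep_rng))
    return out


# ---------------------------------------------------------------------------
# analytic fixtures

def parallel_patch_fixture(separation: float = 4.0, h: float = 1.0,
                           extent: float = 20.0):
    """Two flat parallel patches: the joint-space width is ``separation``
    exactly at every tibial vertex (the closed-form oracle configuration)."""
    t_pts, t_faces = _grid(-extent, extent, -extent, extent, h)
    f_pts, f_faces = _grid(-extent * 1.5, extent * 1.5,
                           -extent * 1.5, extent * 1.5, h, flip_winding=True)
    f_pts = f_pts.copy()
    f_pts[:, 2] = separation
    tibia = LandmarkSurface(t_pts, t_faces, "flat-tibia",
                            SurfaceMeta(bone="tibia"))
    femur = LandmarkSurface(f_pts, f_faces, "flat-femur",
                            SurfaceMeta(bone="femur"))
    region = RegionDefinition("cMT", "flat-tibia",
                              np.flatnonzero(np.abs(t_pts[:, 0]) <= extent / 2))
    return tibia, femur, region
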