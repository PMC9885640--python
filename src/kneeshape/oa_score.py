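"""Bone-shape scoring along the OA vector.

The OA vector is the line in shape-parameter space through the mean shape
of a non-OA population and the mean shape of an OA population.  A shape's
score is its signed projection onto that line, in units of one standard
deviation of the non-OA group along the same line, with the origin at the
non-OA mean (positive toward the OA group).  For the femur this score is
the B-score; the tibial analogue is referred to as the tibia z-score.
Observable femoral scores in OA cohorts span roughly -3 to +7.

The origin and unit scale may be computed per stratum (e.g. per sex); the
direction is pooled across strata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .mesh import LandmarkSurface
from .shape_model import (FitResult, ShapeModel, ShapePopulation,
                          fit_model_to_surface, project)

__all__ = ["OAVector", "build_oa_vector", "score_shape", "score_surface",
           "save_oa_vector", "load_oa_vector"]

POOLED = "pooled"


@dataclass
class OAVector:
    """Origin, unit direction and non-OA SD scale in shape-parameter space."""

    direction: np.ndarray                    # unit vector, toward the OA group
    origins: Dict[str, np.ndarray]           # per stratum: non-OA mean b
    scales: Dict[str, float]                 # per stratum: non-OA SD along direction
    bone: str = "femur"

    def __post_init__(self):
        self.direction = np.asarray(self.direction, dtype=float)
        if not np.isclose(np.linalg.norm(self.direction), 1.0, atol=1e-9):
            raise ValueError("direction must be a unit vector")
        for level, s in self.scales.items():
            if not s > 0:
                raise ValueError(f"scale for stratum {level!r} must be positive")

    def levels(self) -> Tuple[str, ...]:
        return tuple(self.origins)


def _project_population(model: ShapeModel, population: ShapePopulation) -> np.ndarray:
    return np.stack([project(model, s) for s in population])


def build_oa_vector(model: ShapeModel, non_oa: ShapePopulation,
                    oa: ShapePopulation, group_key: Optional[str] = None,
                    bone: str = "femur") -> OAVector:
    """Construct the OA vector from non-OA and OA populations.

    direction = normalized difference of pooled group mean parameters
    (non-OA -> OA); per stratum of ``group_key`` (or a single pooled
    stratum), origin = non-OA mean b and scale = SD (ddof=1) of non-OA
    projections along the direction.
    """
    b_non = _project_population(model, non_oa)
    b_oa = _project_population(model, oa)
    delta = b_oa.mean(axis=0) - b_non.mean(axis=0)
    norm = np.linalg.norm(delta)
    if norm < 1e-12:
        raise ValueError("OA and non-OA group means coincide; direction undefined")
    direction = delta / norm

    if group_key is None:
        strata = {POOLED: np.arange(len(b_non))}
    else:
        labels = non_oa.labels(group_key)
        strata = {lev: np.flatnonzero([l == lev for l in labels])
                  for lev in sorted(set(labels))}

    origins, scales = {}, {}
    for level, idx in strata.items():
        if len(idx) < 2:
            raise ValueError(f"stratum {level!r} has fewer than 2 non-OA shapes")
        origins[level] = b_non[idx].mean(axis=0)
        proj = (b_non[idx] - origins[level]) @ direction
        sd = float(proj.std(ddof=1))
        if sd <= 0:
            raise ValueError(f"zero variance along OA vector in stratum {level!r}")
        scales[level] = sd
    return OAVector(direction, origins, scales, bone)


def score_shape(oav: OAVector, b: np.ndarray, level: str = POOLED) -> float:
    """Signed projection of parameters b onto the OA vector, in non-OA SD units."""
    if level not in oav.origins:
        raise KeyError(f"unknown stratum {level!r}; known: {oav.levels()}")
    b = np.asarray(b, dtype=float)
    return float((b - oav.origins[level]) @ oav.direction / oav.scales[level])


def score_surface(model: ShapeModel, oav: OAVector, surface: LandmarkSurface,
                  level: str = POOLED, **fit_opts) -> Tuple[float, FitResult]:
    """Score an arbitrary (uncorresponded) surface: fit the model, then project.

    This is the cross-modality pathway: the surface is fitted by the shape
    model (producing an instance with model landmarks but the surface's
    shape) and the fitted parameters are scored on the OA vector.  The fit
    residual — the mean absolute point-to-surface distance between instance
    and target — is returned alongside as the fidelity measure.
    """
    fit = fit_model_to_surface(model, surface, **fit_opts)
    return score_shape(oav, fit.b, level), fit


def save_oa_vector(oav: OAVector, path) -> None:
    """Write an OA vector as JSON (direction, per-stratum origins/scales)."""
    import json
    from pathlib import Path
    payload = {
        "direction": oav.direction.tolist(),
        "origins": {k: v.tolist() for k, v in oav.origins.items()},
        "scales": {k: float(v) for k, v in oav.scales.items()},
        "bone": oav.bone,
    }
    Path(path).write_text(json.dumps(payload))


def load_oa_vector(path) -> OAVector:
    import json
    from pathlib import Path
    payload = json.loads(Path(path).read_text())
    return OAVector(np.asarray(payload["direction"]),
                    {k: np.asarray(v) for k, v in payload["origins"].items()},
                    payload["scales"], payload.get("bone", "femur"))
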