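"""Regional bone measures: subchondral bone area (tAB) and 3D joint-space width.

Regions are named vertex-index sets on a model topology.  The six area
regions are medial/lateral femur (MF.tAB, LF.tAB), medial/lateral tibia
(MT.tAB, LT.tAB) and the medial/lateral femoral trochlea (TrFMed.tAB,
TrFLat.tAB).  Joint-space width is measured from the central medial and
lateral tibial plateau regions (cMT, cLT): from every region vertex a ray
is cast along the outward tibial vertex normal and the distance to the
first femoral intersection is recorded; the regional 3DJSW is the mean
over vertices that hit.

Because regions are vertex-index sets on a fixed landmark topology, they
propagate to every corresponded surface for free; transferring a region to
a *different* topology goes through rigid ICP of the two mean surfaces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
from scipy.spatial import cKDTree

from .mesh import (ICPResult, LandmarkSurface, cast_rays, icp_register,
                   surface_area, vertex_normals)

__all__ = [
    "RegionDefinition",
    "JSWResult",
    "propagate_region",
    "transfer_region",
    "tab_area",
    "jsw_3d",
    "save_regions",
    "load_regions",
]

AREA_REGIONS = ("MF.tAB", "LF.tAB", "MT.tAB", "LT.tAB", "TrFMed.tAB", "TrFLat.tAB")
JSW_REGIONS = ("cMT", "cLT")
FEMUR_REGIONS = ("MF.tAB", "LF.tAB", "TrFMed.tAB", "TrFLat.tAB")
TIBIA_REGIONS = ("MT.tAB", "LT.tAB", "cMT", "cLT")


@dataclass
class RegionDefinition:
    """A named vertex-index subset on one landmark topology."""

    name: str
    topology: str
    indices: np.ndarray

    def __post_init__(self):
        self.indices = np.unique(np.asarray(self.indices, dtype=np.int64))
        if self.indices.size and self.indices.min() < 0:
            raise ValueError("negative region index")

    @property
    def size(self) -> int:
        return len(self.indices)


@dataclass
class JSWResult:
    """Per-vertex joint-space widths for one central region."""

    region: str
    distances: np.ndarray      # (n_region,) mm, NaN where not measured
    measured: np.ndarray       # (n_region,) bool; False = MISS or invalid normal
    mean_mm: float
    n_measured: int
    n_excluded: int
    valid: bool                # False when more than half the region missed


def propagate_region(region: RegionDefinition,
                     surface: LandmarkSurface) -> np.ndarray:
    """Region on a corresponded surface: the identity index mapping.

    Landmark correspondence is what makes regions anatomically
    corresponded across subjects; a topology mismatch is an error
    (use :func:`transfer_region` instead).
    """
    if surface.topology != region.topology:
        raise ValueError(
            f"surface topology {surface.topology!r} does not match region "
            f"topology {region.topology!r}; use transfer_region")
    if region.indices.size and region.indices.max() >= surface.n_points:
        raise ValueError("region index out of range for surface")
    return region.indices.copy()


def transfer_region(region: RegionDefinition, source_mean: LandmarkSurface,
                    target_mean: LandmarkSurface,
                    distance_cap: Optional[float] = None) -> RegionDefinition:
    """Transfer a region between topologies via rigid ICP of the mean surfaces.

    The source mean is ICP-registered onto the target mean; a target vertex
    joins the transferred region iff its nearest transformed-source vertex
    is a region member and lies within ``distance_cap`` (default: twice the
    median edge length of the target mesh).
    """
    if region.topology != source_mean.topology:
        raise ValueError("region is not defined on the source topology")
    icp: ICPResult = icp_register(source_mean, target_mean)
    moved = icp.transform.apply(source_mean.points)
    if distance_cap is None:
        distance_cap = 2.0 * float(np.median(target_mean.edge_lengths()))
    d, nearest = cKDTree(moved).query(target_mean.points)
    in_region = np.zeros(source_mean.n_points, dtype=bool)
    in_region[region.indices] = True
    keep = (d <= distance_cap) & in_region[nearest]
    return RegionDefinition(region.name, target_mean.topology,
                            np.flatnonzero(keep))


def tab_area(surface: LandmarkSurface, region: RegionDefinition) -> float:
    """Total area of subchondral bone (mm^2) for one region on one surface."""
    return surface_area(surface, propagate_region(region, surface))


def jsw_3d(tibia: LandmarkSurface, femur: LandmarkSurface,
           region: RegionDefinition, max_dist: float = 15.0) -> JSWResult:
    """3D joint-space width from a central tibial region to the femoral surface.

    Rays are cast from each region vertex along its outward (toward-femur)
    area-weighted vertex normal; the first femoral intersection within
    ``max_dist`` mm is the local width, no intersection is a MISS.  Normals
    are flipped as a block if the region's mean normal points away from the
    femoral centroid, making the measure robust to face-winding convention.
    The regional value is the mean over measured vertices; a result with
    more than 50% MISS is flagged invalid, zero hits is an error.  Both
    bones must be expressed in the same world frame (one acquisition).
    """
    idx = propagate_region(region, tibia)
    normals = vertex_normals(tibia)[idx]
    finite = np.isfinite(normals).all(axis=1)
    pts = tibia.points[idx]

    mean_normal = np.nanmean(normals, axis=0)
    toward_femur = femur.centroid() - pts.mean(axis=0)
    if float(mean_normal @ toward_femur) < 0:
        normals = -normals

    dist = np.full(len(idx), np.nan)
    hit = np.zeros(len(idx), dtype=bool)
    if finite.any():
        # nudge origins off the tibial surface to avoid self-intersection
        o = pts[finite] + 1e-6 * normals[finite]
        d, h = cast_rays(o, normals[finite], femur, max_dist)
        dist[finite] = d
        hit[finite] = h

    n_measured = int(hit.sum())
    n_excluded = len(idx) - n_measured
    if n_measured == 0:
        raise ValueError(f"no joint space measurable in region {region.name!r} "
                         f"(all rays missed within {max_dist} mm)")
    return JSWResult(region.name, dist, hit, float(np.nanmean(dist[hit])),
                     n_measured, n_excluded, valid=n_measured >= 0.5 * len(idx))


# ---------------------------------------------------------------------------
# region file I/O: JSON mapping name -> {"topology": ..., "indices": [...]}

def save_regions(regions: Dict[str, RegionDefinition], path) -> Path:
    path = Path(path)
    payload = {name: {"topology": r.topology,
                      "indices": sorted(int(i) for i in r.indices)}
               for name, r in regions.items()}
    path.write_text(json.dumps(payload))
    return path


def load_regions(path) -> Dict[str, RegionDefinition]:
    payload = json.loads(Path(path).read_text())
    return {name: RegionDefinition(name, d["topology"],
                                   np.asarray(d["indices"], dtype=np.int64))
            for name, d in payload.items()}
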