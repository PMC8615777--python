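"""Generative object models for synthetic micrographs.

Three object kinds mimic the morphological classes seen in submerged
filamentous cultures:

* **pellet** — a filled disk of radius ``core_radius`` carrying a radial hair
  fringe: sparse triangular spikes of depth ``fringe_depth`` at angular
  density ``fringe_density``.  The fringe inflates the perimeter and pulls the
  morphology number of a measured pellet below the smooth-disk value of 1,
  into the band observed for real fully evolved pellets.
* **clump** — a union of 3–8 jittered ellipses, an irregular loose aggregate.
* **hypha** — a constant-thickness tube along a smoothly curling random
  curve; ``tortuosity`` is the total heading turn (radians) over the length,
  so curled fragments have moderate Feret elongation like real hyphal debris.

An optional anisotropy ``axis_ratio`` is applied as an area-preserving affine
stretch, so the generative Feret elongation of a smooth object equals
``axis_ratio`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import shapely.affinity as saff
from shapely.geometry import LineString, Polygon
from shapely.ops import unary_union

from ..errors import ParameterError

KINDS = ("pellet", "clump", "hypha")
SPECIES = ("A", "B")

#: number of fringe spikes at fringe_density == 1
MAX_SPIKES = 120
#: angular half-width of one fringe spike (radians)
SPIKE_HALF_WIDTH = np.deg2rad(1.25)


@dataclass(frozen=True)
class ObjectSpec:
    """Generative parameters of one object (lengths in µm, angles in radians)."""

    kind: str
    center: tuple[float, float] = (0.0, 0.0)
    core_radius: float = 0.0
    fringe_depth: float = 0.0
    fringe_density: float = 0.0
    axis_ratio: float = 1.0
    length: float = 0.0
    thickness: float = 0.0
    orientation: float = 0.0
    tortuosity: float = 0.0
    true_species: str = "A"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ParameterError(f"unknown object kind {self.kind!r}")
        if self.true_species not in SPECIES:
            raise ParameterError(f"unknown species {self.true_species!r}")
        if self.kind in ("pellet", "clump") and not self.core_radius > 0:
            raise ParameterError(f"{self.kind} requires core_radius > 0")
        if self.kind == "hypha":
            if not (0 < self.thickness < self.length):
                raise ParameterError("hypha requires 0 < thickness < length")
            if self.tortuosity < 0:
                raise ParameterError("tortuosity must be >= 0")
        if self.fringe_depth < 0:
            raise ParameterError("fringe_depth must be >= 0")
        if not 0 <= self.fringe_density <= 1:
            raise ParameterError("fringe_density must lie in [0, 1]")
        if self.axis_ratio < 1:
            raise ParameterError("axis_ratio must be >= 1")

    @property
    def bounding_diameter(self) -> float:
        """Conservative outer diameter (µm) used for overlap-free placement."""
        stretch = np.sqrt(self.axis_ratio)
        if self.kind == "pellet":
            return 2.0 * (self.core_radius + self.fringe_depth) * stretch
        if self.kind == "clump":
            return 2.6 * self.core_radius * stretch
        return self.length + self.thickness

    def moved_to(self, center: tuple[float, float]) -> "ObjectSpec":
        return replace(self, center=center)


def _apply_pose(geom, spec: ObjectSpec):
    """Area-preserving anisotropy, rotation by orientation, translation to center."""
    s = np.sqrt(spec.axis_ratio)
    if spec.axis_ratio != 1.0:
        geom = saff.scale(geom, xfact=s, yfact=1.0 / s, origin=(0, 0))
    if spec.orientation:
        geom = saff.rotate(geom, spec.orientation, origin=(0, 0), use_radians=True)
    return saff.translate(geom, xoff=spec.center[0], yoff=spec.center[1])


def _pellet_polygon(spec: ObjectSpec, rng: np.random.Generator) -> Polygon:
    n = 1440
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = np.full(n, spec.core_radius)
    n_spikes = int(round(spec.fringe_density * MAX_SPIKES))
    if spec.fringe_depth > 0 and n_spikes > 0:
        centers = rng.uniform(0.0, 2.0 * np.pi, n_spikes)
        depths = spec.fringe_depth * rng.uniform(0.6, 1.0, n_spikes)
        delta = np.abs((theta[None, :] - centers[:, None] + np.pi) % (2.0 * np.pi) - np.pi)
        bumps = depths[:, None] * np.clip(1.0 - delta / SPIKE_HALF_WIDTH, 0.0, 1.0)
        r = r + bumps.max(axis=0)
    poly = Polygon(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
    return _apply_pose(poly, spec)


def _ellipse(a: float, b: float, angle: float, offset: tuple[float, float]) -> Polygon:
    t = np.linspace(0.0, 2.0 * np.pi, 180, endpoint=False)
    xy = np.column_stack([a * np.cos(t), b * np.sin(t)])
    rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    xy = xy @ rot.T + offset
    return Polygon(xy)


def _clump_polygon(spec: ObjectSpec, rng: np.random.Generator) -> Polygon:
    R = spec.core_radius
    k = int(rng.integers(3, 9))
    parts = []
    for _ in range(k):
        a = rng.uniform(0.35, 0.75) * R
        b = rng.uniform(0.35, 0.75) * R
        off_r = rng.uniform(0.0, 0.3) * R
        off_a = rng.uniform(0.0, 2.0 * np.pi)
        parts.append(_ellipse(a, b, rng.uniform(0, np.pi), (off_r * np.cos(off_a), off_r * np.sin(off_a))))
    union = unary_union(parts)
    if union.geom_type != "Polygon":  # extremely unlikely: keep the largest part
        union = max(union.geoms, key=lambda g: g.area)
    blob = Polygon(union.exterior)
    blob = _whiten(blob)
    # rescale so the blob area equals the drawn target area pi*R^2
    f = np.sqrt(np.pi * R**2 / blob.area)
    blob = saff.scale(blob, xfact=f, yfact=f, origin=(0, 0))
    return _apply_pose(blob, spec)


def _whiten(poly: Polygon) -> Polygon:
    """Remove a blob's incidental anisotropy (area-preserving PCA whitening).

    Ensures the clump's generative elongation is set by ``axis_ratio`` alone
    rather than by the random union of ellipses.
    """
    xy = np.asarray(poly.exterior.coords)[:-1]
    xy = xy - xy.mean(axis=0)
    cov = np.cov(xy.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() <= 0:
        return saff.translate(poly, -poly.centroid.x, -poly.centroid.y)
    # rotate onto principal axes, equalize spreads without changing area
    rot = xy @ evecs
    s = np.power(evals, 0.25)
    rot[:, 0] *= s[1] / s[0]
    rot[:, 1] *= s[0] / s[1]
    out = Polygon(rot)
    return saff.translate(out, -out.centroid.x, -out.centroid.y)


def _hypha_polygon(spec: ObjectSpec, rng: np.random.Generator) -> Polygon:
    n = 64
    step = spec.length / n
    curl = rng.choice([-1.0, 1.0]) * spec.tortuosity
    wiggle_sd = 0.35 / np.sqrt(n) if spec.tortuosity > 0 else 0.0
    heading = np.linspace(-curl / 2.0, curl / 2.0, n) + np.cumsum(rng.normal(0.0, 1.0, n)) * wiggle_sd
    dx = step * np.cos(heading)
    dy = step * np.sin(heading)
    pts = np.column_stack([np.concatenate([[0.0], np.cumsum(dx)]), np.concatenate([[0.0], np.cumsum(dy)])])
    pts -= pts.mean(axis=0)
    tube = LineString(pts).buffer(spec.thickness / 2.0, cap_style="flat", quad_segs=8)
    if tube.geom_type != "Polygon":
        tube = max(tube.geoms, key=lambda g: g.area)
    tube = Polygon(tube.exterior)
    return _apply_pose(tube, spec)


def object_geometry(spec: ObjectSpec, rng: np.random.Generator) -> Polygon:
    """Realize the object's silhouette as a shapely polygon in µm coordinates.

    The polygon's ``area`` is the ground-truth projected area recorded in
    truth tables (for pellets it exceeds π·core_radius² by the small fringe
    contribution).
    """
    if spec.kind == "pellet":
        return _pellet_polygon(spec, rng)
    if spec.kind == "clump":
        return _clump_polygon(spec, rng)
    return _hypha_polygon(spec, rng)
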