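"""Population sampling: from statistical specs to lists of object specs.

Projected areas are drawn log-normally with a prescribed mean and coefficient
of variation — the canonical size model for pellet populations in submerged
culture.  For pellets and clumps the drawn area sets the core radius
(r = √(A/π)); hyphal fragments are instead parameterized by uniform length and
thickness ranges, matching how dispersed debris is described in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ParameterError
from .objects import KINDS, SPECIES, ObjectSpec


@dataclass
class PopulationSpec:
    """Statistical description of one object population.

    Parameters
    ----------
    kind : str
        ``pellet`` / ``clump`` / ``hypha``.
    count : int
        Number of objects to draw (>= 0).
    mean_area_um2, cv_area :
        Mean and coefficient of variation of the log-normal projected-area
        distribution (core area, before any fringe).  Ignored for hyphae.
    axis_ratio_range / axis_ratio_mean, axis_ratio_sd :
        Generative elongation: uniform over the range by default, or normal
        (clipped at 1) when a mean is given.
    fringe_depth_rel, fringe_density :
        Pellet fringe: spike depth as a fraction of the core radius, and
        angular spike density in [0, 1].
    length_range, thickness_range, tortuosity_range :
        Hyphal geometry (µm, µm, total heading turn in radians).
    species : str
        Ground-truth species label carried into truth tables.
    """

    kind: str = "pellet"
    count: int = 30
    species: str = "A"
    mean_area_um2: float = 1.0e5
    cv_area: float = 0.3
    axis_ratio_range: tuple[float, float] = (1.0, 1.3)
    axis_ratio_mean: float | None = None
    axis_ratio_sd: float = 0.1
    fringe_depth_rel: float = 0.12
    fringe_density: float = 0.35
    length_range: tuple[float, float] = (150.0, 400.0)
    thickness_range: tuple[float, float] = (8.0, 15.0)
    tortuosity_range: tuple[float, float] = (2.0, 4.5)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ParameterError(f"unknown kind {self.kind!r}")
        if self.species not in SPECIES:
            raise ParameterError(f"unknown species {self.species!r}")
        if self.count < 0:
            raise ParameterError("count must be >= 0")
        if self.cv_area < 0:
            raise ParameterError("cv_area must be >= 0")
        if self.mean_area_um2 <= 0:
            raise ParameterError("mean_area_um2 must be > 0")


def _lognormal(mean: float, cv: float, size: int, rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def sample_population(pop: PopulationSpec, seed: int) -> list[ObjectSpec]:
    """Draw ``pop.count`` object specs; deterministic given the seed.

    Centers are left at the origin — scene assembly
    (:func:`mycomorph.synth.scene.place_on_grid`) assigns positions.
    """
    rng = np.random.default_rng(seed)
    n = pop.count
    if n == 0:
        return []
    if pop.axis_ratio_mean is not None:
        axis = np.clip(rng.normal(pop.axis_ratio_mean, pop.axis_ratio_sd, n), 1.0, None)
    else:
        axis = rng.uniform(*pop.axis_ratio_range, n)
    orient = rng.uniform(0.0, 2.0 * np.pi, n)
    out: list[ObjectSpec] = []
    if pop.kind == "hypha":
        lengths = rng.uniform(*pop.length_range, n)
        thicks = rng.uniform(*pop.thickness_range, n)
        torts = rng.uniform(*pop.tortuosity_range, n)
        for i in range(n):
            out.append(
                ObjectSpec(
                    kind="hypha",
                    length=float(lengths[i]),
                    thickness=float(min(thicks[i], 0.5 * lengths[i])),
                    tortuosity=float(torts[i]),
                    axis_ratio=1.0,
                    orientation=float(orient[i]),
                    true_species=pop.species,
                )
            )
        return out

    areas = _lognormal(pop.mean_area_um2, pop.cv_area, n, rng)
    radii = np.sqrt(areas / np.pi)
    for i in range(n):
        fringe = pop.fringe_depth_rel * radii[i] if pop.kind == "pellet" else 0.0
        out.append(
            ObjectSpec(
                kind=pop.kind,
                core_radius=float(radii[i]),
                fringe_depth=float(fringe),
                fringe_density=pop.fringe_density if pop.kind == "pellet" else 0.0,
                axis_ratio=float(axis[i]),
                orientation=float(orient[i]),
                true_species=pop.species,
            )
        )
    return out


def pick_scale(objects, candidates=(2.0, 4.0, 8.0, 16.0), max_bound_px: float = 480.0) -> float:
    """Smallest µm/px calibration at which the largest object fits a placement cell.

    Mimics the operator choosing magnification per sample: giant pellets are
    imaged coarsely, dispersed hyphae finely.
    """
    if not objects:
        return candidates[0]
    bound = max(o.bounding_diameter for o in objects)
    for s in candidates:
        if bound / s <= max_bound_px:
            return s
    return candidates[-1]
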