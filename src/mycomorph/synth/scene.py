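"""Scene specification and phase-contrast-style rendering.

A scene is a list of :class:`ObjectSpec` plus imaging parameters.  Rendering
produces a dark-objects-on-bright-background grayscale image (optional bright
halo rim, additive Gaussian noise), a ground-truth label mask and a per-object
truth table.  Rendering is bit-deterministic: per-object randomness (fringe
pattern, clump ellipses, hyphal curl) is drawn from a generator seeded by
``(scene.seed, object index)``, independent of the other objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import disk

from ..errors import ParameterError
from ..segmentation import CalibratedImage
from ._raster import polygon_pixels
from .objects import ObjectSpec, object_geometry


@dataclass
class SceneSpec:
    """One synthetic micrograph: objects + imaging parameters.

    Grayscale levels are 8-bit (0–255); ``halo_strength`` in [0, 1] sets how
    far the phase-contrast rim rises from the background toward white.
    """

    objects: Sequence[ObjectSpec]
    image_size: tuple[int, int] = (1024, 1024)  # (H, W) px
    scale: float = 2.0  # µm per px
    background_level: float = 200.0
    foreground_level: float = 60.0
    noise_sd: float = 8.0
    halo_strength: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ParameterError("scale must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0 <= self.halo_strength <= 1:
            raise ParameterError("halo_strength must lie in [0, 1]")


@dataclass
class RenderedScene:
    image: CalibratedImage
    truth_mask: np.ndarray  # uint16 labels, background 0
    truth_table: pd.DataFrame


TRUTH_COLUMNS = [
    "label",
    "kind",
    "true_species",
    "center_x_um",
    "center_y_um",
    "true_area_um2",
    "core_area_um2",
    "axis_ratio",
    "fringe_depth_um",
    "fringe_density",
    "length_um",
    "thickness_um",
    "tortuosity",
    "border_touching",
    "overlapping",
]


def render_scene(
    scene: SceneSpec,
    *,
    experiment: str = "",
    culture: str = "",
    time_h: float = 0.0,
) -> RenderedScene:
    """Rasterize and shade a scene; returns image, label mask and truth table."""
    H, W = scene.image_size
    labels = np.zeros((H, W), dtype=np.uint16)
    rows: list[dict] = []
    overlapped: set[int] = set()

    for idx, spec in enumerate(scene.objects, start=1):
        rng = np.random.default_rng([scene.seed, idx])
        poly = object_geometry(spec, rng)
        ext = np.asarray(poly.exterior.coords)
        rr, cc = polygon_pixels(ext[:, 0] / scene.scale, ext[:, 1] / scene.scale, (H, W))
        prior = labels[rr, cc]
        hit = np.unique(prior[prior > 0])
        if hit.size:
            overlapped.add(idx)
            overlapped.update(int(h) for h in hit)
        labels[rr, cc] = idx
        minx, miny, maxx, maxy = poly.bounds
        border = bool(
            minx <= 0 or miny <= 0 or maxx >= W * scene.scale or maxy >= H * scene.scale
        )
        if spec.kind == "pellet":
            core_area = np.pi * spec.core_radius**2
        elif spec.kind == "clump":
            core_area = np.pi * spec.core_radius**2
        else:
            core_area = spec.length * spec.thickness
        rows.append(
            {
                "label": idx,
                "kind": spec.kind,
                "true_species": spec.true_species,
                "center_x_um": spec.center[0],
                "center_y_um": spec.center[1],
                "true_area_um2": float(poly.area),
                "core_area_um2": float(core_area),
                "axis_ratio": spec.axis_ratio,
                "fringe_depth_um": spec.fringe_depth,
                "fringe_density": spec.fringe_density,
                "length_um": spec.length,
                "thickness_um": spec.thickness,
                "tortuosity": spec.tortuosity,
                "border_touching": border,
                "overlapping": False,
            }
        )

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    if overlapped:
        truth.loc[truth["label"].isin(sorted(overlapped)), "overlapping"] = True

    fg = labels > 0
    img = np.full((H, W), scene.background_level, dtype=float)
    if scene.halo_strength > 0 and fg.any():
        rim = ndi.binary_dilation(fg, structure=disk(2)) & ~fg
        img[rim] = scene.background_level + scene.halo_strength * (255.0 - scene.background_level)
    img[fg] = scene.foreground_level
    if scene.noise_sd > 0:
        noise_rng = np.random.default_rng([scene.seed, 0])
        img = img + noise_rng.normal(0.0, scene.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    cal = CalibratedImage(img, scene.scale, experiment=experiment, culture=culture, time_h=time_h)
    return RenderedScene(image=cal, truth_mask=labels, truth_table=truth)


def render_noise_free(scene: SceneSpec, **meta) -> RenderedScene:
    """Convenience: the same scene with noise_sd = 0 (the noise-free twin)."""
    clean = SceneSpec(
        objects=scene.objects,
        image_size=scene.image_size,
        scale=scene.scale,
        background_level=scene.background_level,
        foreground_level=scene.foreground_level,
        noise_sd=0.0,
        halo_strength=scene.halo_strength,
        seed=scene.seed,
    )
    return render_scene(clean, **meta)


def place_on_grid(
    objects: Sequence[ObjectSpec],
    scale: float,
    *,
    seed: int = 0,
    max_frame_px: int = 3072,
    margin_px: int = 8,
    jitter: float = 0.15,
    **scene_kwargs,
) -> list[SceneSpec]:
    """Assign non-overlapping centers on a jittered grid and build scene specs.

    The cell size is set by the largest object's bounding diameter, so objects
    never overlap.  If one frame (capped at ``max_frame_px``) cannot hold all
    objects, they spill into further scenes; each scene gets a sub-seed
    ``seed + scene index``.
    """
    if not objects:
        raise ParameterError("cannot place an empty object list")
    bound_px = max(o.bounding_diameter for o in objects) / scale
    cell = int(np.ceil(bound_px)) + margin_px
    if cell > max_frame_px:
        raise ParameterError(
            f"largest object ({bound_px:.0f} px) exceeds the frame cap at scale {scale} µm/px"
        )
    n = len(objects)
    side_wanted = int(np.ceil(np.sqrt(n)))
    side = min(side_wanted, max_frame_px // cell)
    per_scene = side * side
    rng = np.random.default_rng(seed)
    scenes: list[SceneSpec] = []
    for s_idx, start in enumerate(range(0, n, per_scene)):
        chunk = objects[start : start + per_scene]
        k = len(chunk)
        side_k = min(side, int(np.ceil(np.sqrt(k))))
        rows_k = int(np.ceil(k / side_k))
        frame = (rows_k * cell, side_k * cell)
        placed = []
        for i, obj in enumerate(chunk):
            r, c = divmod(i, side_k)
            cx = (c + 0.5) * cell * scale
            cy = (r + 0.5) * cell * scale
            slack = (cell - bound_px) / 2.0 - 1.0
            if slack > 0 and jitter > 0:
                cx += rng.uniform(-1, 1) * jitter * slack * scale
                cy += rng.uniform(-1, 1) * jitter * slack * scale
            placed.append(obj.moved_to((cx, cy)))
        scenes.append(SceneSpec(objects=placed, image_size=frame, scale=scale, seed=seed + s_idx, **scene_kwargs))
    return scenes
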