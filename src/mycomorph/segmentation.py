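"""Semiautomatic segmentation front end.

Mirrors the image-processing workflow used for phase-contrast micrographs of
submerged filamentous cultures: median smoothing, Sobel edge detection,
threshold segmentation into labeled objects, and declarative operator
overrides that make the "semiautomatic" part reproducible.

Objects are dark on a bright background (phase contrast with a bright halo at
the rim); the default binarization is an Otsu threshold on the median-filtered
intensity, with the Sobel gradient map exposed as an alternative channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, morphology, segmentation as skseg
from skimage.measure import label as sklabel

from .errors import EditError, ParameterError

CULTURES = ("monoA", "monoB", "coculture")


@dataclass
class CalibratedImage:
    """A 2-D grayscale micrograph with physical calibration and sample metadata.

    Parameters
    ----------
    pixels : ndarray
        2-D grayscale array (any numeric dtype).
    scale : float
        Physical calibration in µm per pixel, > 0.
    experiment, culture, time_h :
        Sample provenance: experiment id, culture vessel
        (``monoA`` / ``monoB`` / ``coculture``) and sampling time in hours.
    """

    pixels: np.ndarray
    scale: float
    experiment: str = ""
    culture: str = ""
    time_h: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ParameterError(f"image must be 2-D, got shape {self.pixels.shape}")
        if not self.scale > 0:
            raise ParameterError(f"scale must be positive (µm/px), got {self.scale}")
        if self.time_h < 0:
            raise ParameterError("time_h must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "CalibratedImage":
        return replace(self, pixels=pixels)


@dataclass
class LabeledMask:
    """Connected-component labels aligned to a source image.

    Background is 0; objects carry labels 1..K assigned in raster order of
    their first pixel (8-connectivity).  ``species_tags`` carries operator
    species reassignments recorded during overrides; they are consumed by the
    fractionation stage.
    """

    labels: np.ndarray
    scale: float
    experiment: str = ""
    culture: str = ""
    time_h: float = 0.0
    species_tags: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ParameterError("label mask must be 2-D")
        if self.labels.min() < 0:
            raise ParameterError("labels must be non-negative")

    @property
    def label_values(self) -> np.ndarray:
        vals = np.unique(self.labels)
        return vals[vals > 0]

    @property
    def n_objects(self) -> int:
        return int(self.label_values.size)


@dataclass
class SegmentationParams:
    """Tunable segmentation parameters.

    min_object_area is physical (µm²) so the same debris cut-off applies at
    any magnification; it is converted to pixels via scale².
    """

    median_radius: int = 2
    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float | None = None
    threshold_channel: str = "intensity"  # "intensity" | "gradient"
    min_object_area: float = 500.0  # µm²
    fill_holes: bool = False
    exclude_border: bool = True

    def __post_init__(self) -> None:
        if self.median_radius < 0:
            raise ParameterError("median_radius must be >= 0")
        if self.min_object_area < 0:
            raise ParameterError("min_object_area must be >= 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ParameterError(f"unknown threshold_method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ParameterError("fixed_threshold required when threshold_method='fixed'")
        if self.threshold_channel not in ("intensity", "gradient"):
            raise ParameterError(f"unknown threshold_channel {self.threshold_channel!r}")


def _drop_small(binary: np.ndarray, min_px: float) -> np.ndarray:
    """Remove 8-connected components with pixel count below ``min_px``."""
    if min_px <= 1 or not binary.any():
        return binary
    lab = sklabel(binary, connectivity=2)
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[lab]


def preprocess(image: CalibratedImage, median_radius: int = 2) -> CalibratedImage:
    """Median-filter the image with a disk footprint; radius 0 is the identity."""
    if median_radius < 0:
        raise ParameterError("median_radius must be >= 0")
    if median_radius == 0:
        return image.with_pixels(image.pixels.copy())
    footprint = morphology.disk(median_radius)
    smoothed = ndi.median_filter(image.pixels, footprint=footprint, mode="nearest")
    return image.with_pixels(smoothed)


def detect_edges(image: CalibratedImage) -> np.ndarray:
    """Gradient magnitude from the two orthogonal 3x3 Sobel kernels.

    Returns a non-negative float array; zero on constant images.
    """
    return filters.sobel(image.pixels.astype(float))


def segment(image: CalibratedImage, params: SegmentationParams | None = None) -> LabeledMask:
    """Binarize, clean up and label a preprocessed micrograph.

    Objects darker than the background are kept when thresholding intensity;
    with the gradient channel, high-gradient regions are kept and holes filled
    so outlined objects become solid.  Components smaller than
    ``min_object_area`` µm² are dropped, border-touching components optionally
    removed, and the survivors labeled 1..K (8-connectivity, raster order).
    """
    params = params or SegmentationParams()
    work = preprocess(image, params.median_radius).pixels.astype(float)

    if params.threshold_channel == "gradient":
        channel = filters.sobel(work)
        dark_objects = False
    else:
        channel = work
        dark_objects = True

    if params.threshold_method == "fixed":
        thr = float(params.fixed_threshold)  # type: ignore[arg-type]
    else:
        if np.ptp(channel) == 0:
            warnings.warn(
                "uniform-intensity image: Otsu threshold undefined, returning 0 objects",
                stacklevel=2,
            )
            return LabeledMask(
                np.zeros(image.shape, dtype=np.int32),
                image.scale,
                image.experiment,
                image.culture,
                image.time_h,
            )
        thr = float(filters.threshold_otsu(channel))

    binary = channel < thr if dark_objects else channel > thr

    if params.fill_holes:
        binary = ndi.binary_fill_holes(binary)

    if params.exclude_border:
        binary = skseg.clear_border(binary)
    binary = _drop_small(binary, params.min_object_area / image.scale**2)

    labels = sklabel(binary, connectivity=2).astype(np.int32)
    return LabeledMask(labels, image.scale, image.experiment, image.culture, image.time_h)


# ---------------------------------------------------------------------------
# Operator overrides
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverrideEdit:
    """One declarative operator edit.

    action:
      * ``delete``  — remove the label,
      * ``merge``   — merge the labels in ``arg`` ("3+5") into ``label``,
      * ``split``   — split ``label`` by watershed from seed points
                      ``arg`` = "row:col;row:col;...",
      * ``species`` — tag the label with a species ("A"/"B"), consumed later
                      by the fractionation stage.
    """

    label: int
    action: str
    arg: str = ""


def read_overrides(path) -> list[OverrideEdit]:
    """Read an overrides CSV with columns ``label,action,arg``."""
    df = pd.read_csv(path, dtype={"arg": str}, keep_default_na=False)
    return [OverrideEdit(int(r.label), str(r.action), str(r.arg)) for r in df.itertuples()]


def _check_label(mask: np.ndarray, lab: int, edit: OverrideEdit) -> None:
    if not (mask == lab).any():
        raise EditError(f"edit {edit} references nonexistent label {lab}")


def apply_overrides(
    mask: LabeledMask, edits: Sequence[OverrideEdit]
) -> tuple[LabeledMask, list[dict]]:
    """Apply operator edits in file order; returns the new mask and an audit log."""
    labels = mask.labels.copy()
    tags = dict(mask.species_tags)
    audit: list[dict] = []
    for edit in edits:
        action = edit.action.lower()
        if action == "delete":
            _check_label(labels, edit.label, edit)
            labels[labels == edit.label] = 0
        elif action == "merge":
            _check_label(labels, edit.label, edit)
            others = [int(tok) for tok in edit.arg.replace(",", "+").split("+") if tok]
            for other in others:
                _check_label(labels, other, edit)
                labels[labels == other] = edit.label
        elif action == "split":
            _check_label(labels, edit.label, edit)
            labels = _split_label(labels, edit)
        elif action == "species":
            _check_label(labels, edit.label, edit)
            tags[edit.label] = edit.arg.strip()
        else:
            raise EditError(f"unknown override action {edit.action!r} in {edit}")
        audit.append({"label": edit.label, "action": action, "arg": edit.arg})
    out = LabeledMask(
        labels, mask.scale, mask.experiment, mask.culture, mask.time_h, species_tags=tags
    )
    return out, audit


def _split_label(labels: np.ndarray, edit: OverrideEdit) -> np.ndarray:
    seeds = []
    for tok in edit.arg.split(";"):
        tok = tok.strip()
        if not tok:
            continue
        r, c = tok.split(":")
        seeds.append((int(r), int(c)))
    if len(seeds) < 2:
        raise EditError(f"split edit {edit} needs >= 2 seed points 'r:c;r:c'")
    region = labels == edit.label
    for r, c in seeds:
        if not region[r, c]:
            raise EditError(f"split seed ({r},{c}) lies outside label {edit.label}")
    markers = np.zeros_like(labels)
    next_label = int(labels.max())
    new_ids = []
    for i, (r, c) in enumerate(seeds):
        new_ids.append(next_label + 1 + i)
        markers[r, c] = new_ids[-1]
    dist = ndi.distance_transform_edt(region)
    parts = skseg.watershed(-dist, markers=markers, mask=region)
    out = labels.copy()
    out[region] = parts[region]
    return out
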