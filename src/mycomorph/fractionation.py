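"""Fractionation: pellets vs hyphae/clumps, and species attribution.

Measured objects are split into the two morphological fractions analysed for
submerged filamentous cultures — *fully evolved pellets* (compact, near-round,
large) and *hyphae and clumps* (everything dispersed) — by conjunctive shape
and size filters, exactly as an operator sets shape/size filter limits in
interactive image-analysis software.  In cocultures, pellets are attributed to
a species by a projected-area threshold (the two species' pellet populations
differ by roughly an order of magnitude in size), while the dispersed fraction
is species-undetermined unless an operator override names the species.

Filter limits are per-experiment configuration; the defaults reconstruct the
published descriptor bands (pellet Mo 0.36–0.77 and E <= ~1.5–1.9 vs
hyphae/clumps Mo 0.1–0.35 and E 1.75–3.25).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import EditError, ParameterError
from .morphometrics import ObjectMeasurement, measurements_to_frame

logger = logging.getLogger(__name__)

FRACTIONS = ("fully_evolved_pellet", "hyphae_or_clumps")
PELLET = "fully_evolved_pellet"
DISPERSED = "hyphae_or_clumps"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class FilterConfig:
    """Operator-set shape/size filter limits.

    An object is a fully evolved pellet iff
    ``Mo >= pellet_min_Mo`` and ``E <= pellet_max_E`` and
    ``A >= pellet_min_area`` (all inclusive); otherwise it belongs to the
    hyphae/clumps fraction.  In coculture samples, pellets with
    ``A >= species_area_threshold`` are attributed to species A (the large
    pellet former), smaller ones to species B; calls within
    ``review_band`` (relative) of the threshold are flagged for review.
    """

    pellet_min_Mo: float = 0.35
    pellet_max_E: float = 1.9
    pellet_min_area: float = 1.0e4  # µm²
    species_area_threshold: float = 1.0e6  # µm²
    review_band: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.pellet_min_Mo < 1:
            raise ParameterError("pellet_min_Mo must lie in (0, 1)")
        if self.pellet_max_E < 1:
            raise ParameterError("pellet_max_E must be >= 1")
        if self.pellet_min_area <= 0 or self.species_area_threshold <= 0:
            raise ParameterError("area thresholds must be positive")


@dataclass(frozen=True)
class ClassifiedObject:
    measurement: ObjectMeasurement
    fraction: str
    species: str  # "A" | "B" | "undetermined"
    provenance: str  # "auto" | "operator"
    review: bool = False


def classify_fraction(m: ObjectMeasurement, cfg: FilterConfig) -> str:
    """Pellet iff the strict conjunction of the three filters holds (>= / <= inclusive)."""
    is_pellet = (
        m.morphology_number >= cfg.pellet_min_Mo
        and m.elongation <= cfg.pellet_max_E
        and m.area_um2 >= cfg.pellet_min_area
    )
    return PELLET if is_pellet else DISPERSED


def attribute_species(
    m: ObjectMeasurement,
    fraction: str,
    culture: str,
    cfg: FilterConfig,
    overrides: Mapping[tuple[str, float, int], str] | None = None,
) -> tuple[str, str, bool]:
    """Species call for one object: (species, provenance, review_flag).

    Monoculture samples inherit the vessel's organism.  Coculture pellets are
    attributed by the size threshold; coculture hyphae/clumps stay
    undetermined.  Operator overrides (keyed ``(experiment, time_h, label)``)
    always win and are flagged as such.
    """
    if overrides:
        key = (m.experiment, m.time_h, m.label)
        if key in overrides:
            species = overrides[key]
            if species not in ("A", "B", UNDETERMINED):
                raise EditError(f"override {key} names unknown species {species!r}")
            return species, "operator", False
    if culture == "monoA":
        return "A", "auto", False
    if culture == "monoB":
        return "B", "auto", False
    if culture != "coculture":
        raise ParameterError(f"unknown culture {culture!r}")
    if fraction == DISPERSED:
        return UNDETERMINED, "auto", False
    thr = cfg.species_area_threshold
    review = abs(m.area_um2 - thr) <= cfg.review_band * thr
    species = "A" if m.area_um2 >= thr else "B"
    if review:
        logger.info(
            "pellet %s/%s/t%g label %d area %.3g within ±%d%% of species threshold; flagged for review",
            m.experiment, culture, m.time_h, m.label, m.area_um2, int(cfg.review_band * 100),
        )
    return species, "auto", review


def classify_all(
    measurements: Sequence[ObjectMeasurement],
    cfg: FilterConfig | None = None,
    overrides: Mapping[tuple[str, float, int], str] | None = None,
) -> list[ClassifiedObject]:
    """Order-preserving classification of a measurement set; logs stratum counts."""
    cfg = cfg or FilterConfig()
    out: list[ClassifiedObject] = []
    for m in measurements:
        fraction = classify_fraction(m, cfg)
        species, provenance, review = attribute_species(m, fraction, m.culture, cfg, overrides)
        out.append(ClassifiedObject(m, fraction, species, provenance, review))
    counts: dict[tuple[str, str], int] = {}
    for c in out:
        counts[(c.fraction, c.species)] = counts.get((c.fraction, c.species), 0) + 1
    for (fr, sp), n in sorted(counts.items()):
        logger.info("classified %d objects as (%s, %s)", n, fr, sp)
    return out


def read_species_overrides(path) -> dict[tuple[str, float, int], str]:
    """Read an overrides CSV ``experiment,time_h,label,species``."""
    df = pd.read_csv(path)
    return {
        (str(r.experiment), float(r.time_h), int(r.label)): str(r.species)
        for r in df.itertuples()
    }


def classified_to_frame(classified: Sequence[ClassifiedObject]) -> pd.DataFrame:
    """Measurement table with ``fraction``, ``species``, ``provenance``, ``review`` appended."""
    df = measurements_to_frame([c.measurement for c in classified])
    df["fraction"] = [c.fraction for c in classified]
    df["species"] = [c.species for c in classified]
    df["provenance"] = [c.provenance for c in classified]
    df["review"] = [c.review for c in classified]
    return df
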