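"""Shared fixtures: synthetic populations pushed through the full pipeline.

The heavier renders (giant-pellet scenes, whole mono-/coculture time courses)
are session-scoped so the unit, integration and acceptance tests share one
computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from mycomorph.fractionation import FilterConfig, classify_all
from mycomorph.morphometrics import measure_all
from mycomorph.pipeline import analyze_scenario
from mycomorph.segmentation import SegmentationParams, segment
from mycomorph.synth import (
    PopulationSpec,
    delayed_introduction,
    pick_scale,
    place_on_grid,
    render_scene,
    sample_population,
    simultaneous_preculture,
)
from mycomorph.validation import match_labels


def run_population(pops, seed, scale=None, culture="monoA"):
    """Sample, render, segment, measure and classify; keep truth for validation."""
    objs = []
    for i, pop in enumerate(pops):
        objs.extend(sample_population(pop, seed + i))
    use_scale = scale if scale is not None else pick_scale(objs)
    rendered, measurements, matches = [], [], []
    for sc in place_on_grid(objs, use_scale, seed=seed):
        r = render_scene(sc, culture=culture)
        mask = segment(r.image, SegmentationParams())
        ms = measure_all(mask, r.image)
        rendered.append(r)
        measurements.extend(ms)
        matches.append(match_labels(mask.labels, r.truth_mask))
    classified = classify_all(measurements, FilterConfig())
    return {
        "objects": objs,
        "rendered": rendered,
        "measurements": measurements,
        "classified": classified,
        "matches": matches,
        "scale": use_scale,
    }


@pytest.fixture(scope="session")
def pellet_run():
    """35 fully evolved pellets at the large-species monoculture size scale."""
    pop = PopulationSpec(kind="pellet", count=35, mean_area_um2=1.3e7, cv_area=0.3)
    return run_population([pop], seed=13)


@pytest.fixture(scope="session")
def debris_run():
    """20 hyphal fragments + 15 clumps: the dispersed hyphae/clumps fraction."""
    pops = [
        PopulationSpec(kind="hypha", count=20, species="A"),
        PopulationSpec(
            kind="clump",
            count=15,
            species="A",
            mean_area_um2=1.0e5,
            cv_area=0.4,
            axis_ratio_range=(2.05, 3.0),
        ),
    ]
    return run_population(pops, seed=11, scale=2.0)


@pytest.fixture(scope="session")
def sim_result():
    """Simultaneous-preculture coculture time course, analysed end to end."""
    scen = simultaneous_preculture(times=(0.0, 24.0, 48.0, 72.0, 96.0))
    return analyze_scenario(scen, seed=5)


@pytest.fixture(scope="session")
def delayed_result():
    """Delayed-introduction coculture time course, analysed end to end."""
    scen = delayed_introduction(times=(24.0, 48.0, 72.0, 96.0, 120.0))
    return analyze_scenario(scen, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
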