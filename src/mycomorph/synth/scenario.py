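"""Time-course scenarios: mono- and coculture experiments with ground truth.

A :class:`ScenarioSpec` prescribes, per vessel (``monoA``, ``monoB``,
``coculture``) and sampling time, the object populations present in the broth
sample, plus optional bioreactor process-profile templates (air flowrate and
stirring speed trajectories).  :func:`generate_timecourse` renders every
sample into one or more calibrated images — one image per population, at a
magnification suited to its object size, the way an operator photographs giant
pellets and fine hyphae separately — and writes a manifest tying files to
(experiment, vessel, time).

Three templates reproduce the characteristic coculture outcomes of stirred
tank co-cultivation of a pellet-forming fungus (species A) with a
pellet-forming actinomycete (species B):

* :func:`simultaneous_preculture` — both precultures inoculated together;
  species A pellets persist but are roughly an order of magnitude smaller in
  the coculture (morphological *advantage* to B).
* :func:`delayed_introduction` — species B introduced 24 h late into an
  established species-A culture; B pellets are destroyed after the first
  sampling (morphological *domination* by A).
* :func:`spore_inoculation` — both species inoculated as spores; species A
  pellets never develop in the coculture (morphological *domination* by B).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..errors import ManifestError, ParameterError
from .population import PopulationSpec, pick_scale, sample_population
from .scene import place_on_grid, render_scene

VESSELS = ("monoA", "monoB", "coculture")

MANIFEST_COLUMNS = [
    "experiment",
    "culture",
    "time_h",
    "population_index",
    "scene_index",
    "kind",
    "species",
    "image",
    "mask",
    "truth",
    "scale_um_per_px",
    "seed",
]


@dataclass
class ProfileTemplate:
    """Piecewise-linear process trajectory with additive noise at synthesis."""

    times_h: tuple[float, ...]
    air_flow_l_min: tuple[float, ...]
    stirring_min1: tuple[float, ...]
    noise_air: float = 0.08
    noise_stir: float = 3.0


@dataclass
class ScenarioSpec:
    """One experiment: populations per (vessel, sampling time) plus metadata."""

    experiment: str
    populations: dict[tuple[str, float], list[PopulationSpec]]
    second_introduction_h: float = 0.0
    profiles: dict[str, ProfileTemplate] = field(default_factory=dict)
    filter_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for vessel, t in self.populations:
            if vessel not in VESSELS:
                raise ParameterError(f"unknown vessel {vessel!r}")
            if t < 0:
                raise ParameterError("sampling times must be >= 0")
        for vessel in set(v for v, _ in self.populations):
            times = sorted(t for v, t in self.populations if v == vessel)
            if len(times) != len(set(times)):
                raise ParameterError(f"duplicate sampling time for vessel {vessel}")

    @property
    def vessels(self) -> list[str]:
        return [v for v in VESSELS if any(v == vv for vv, _ in self.populations)]

    def times(self, vessel: str) -> list[float]:
        return sorted(t for v, t in self.populations if v == vessel)


def derive_seed(master_seed: int, *parts) -> int:
    """Deterministic sub-seed: CRC32 of the joined key, mixed with the master seed.

    Kept below 2**31 so seeds remain portable small integers.
    """
    key = "|".join(str(p) for p in parts).encode()
    return int((zlib.crc32(key) ^ (master_seed * 2654435761)) % (2**31))


def generate_timecourse(scenario: ScenarioSpec, seed: int, out_dir) -> pd.DataFrame:
    """Render every (vessel, time) sample and write images, masks, truth and manifest.

    Returns the manifest (also written to ``out_dir/manifest.csv``).  Each
    population within a sample is rendered at its own pixel calibration; the
    manifest therefore holds one row per image, with (experiment, culture,
    time_h) identifying the sampling group.
    """
    from .. import io as mio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    seen: set[tuple] = set()
    for vessel in scenario.vessels:
        for t in scenario.times(vessel):
            pops = scenario.populations[(vessel, t)]
            for p_idx, pop in enumerate(pops):
                pop_seed = derive_seed(seed, scenario.experiment, vessel, t, p_idx)
                objs = sample_population(pop, pop_seed)
                if not objs:
                    continue
                scale = pick_scale(objs)
                scenes = place_on_grid(objs, scale, seed=pop_seed)
                for s_idx, scene in enumerate(scenes):
                    key = (vessel, t, p_idx, s_idx)
                    if key in seen:
                        raise ManifestError(f"duplicate manifest key {key}")
                    seen.add(key)
                    rendered = render_scene(
                        scene, experiment=scenario.experiment, culture=vessel, time_h=t
                    )
                    stem = f"{scenario.experiment}_{vessel}_t{int(t):03d}_p{p_idx}_s{s_idx}"
                    img_path = out / f"{stem}.tif"
                    mask_path = out / f"{stem}_mask.tif"
                    truth_path = out / f"{stem}_truth.csv"
                    mio.write_image(img_path, rendered.image.pixels)
                    mio.write_mask(mask_path, rendered.truth_mask)
                    rendered.truth_table.to_csv(truth_path, index=False)
                    rows.append(
                        {
                            "experiment": scenario.experiment,
                            "culture": vessel,
                            "time_h": t,
                            "population_index": p_idx,
                            "scene_index": s_idx,
                            "kind": pop.kind,
                            "species": pop.species,
                            "image": img_path.name,
                            "mask": mask_path.name,
                            "truth": truth_path.name,
                            "scale_um_per_px": scale,
                            "seed": scene.seed,
                        }
                    )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def synth_profiles(scenario: ScenarioSpec, seed: int, step_h: float = 1.0) -> pd.DataFrame:
    """Synthesize noisy process logs from the scenario's profile templates.

    Returns a tidy frame ``time_h, air_flow_l_min, stirring_min1, vessel``.
    """
    rows = []
    for vessel, tpl in scenario.profiles.items():
        rng = np.random.default_rng(derive_seed(seed, scenario.experiment, vessel, "profile"))
        t = np.arange(tpl.times_h[0], tpl.times_h[-1] + step_h / 2, step_h)
        air = np.interp(t, tpl.times_h, tpl.air_flow_l_min) + rng.normal(0, tpl.noise_air, t.size)
        stir = np.interp(t, tpl.times_h, tpl.stirring_min1) + rng.normal(0, tpl.noise_stir, t.size)
        air = np.clip(air, 1.5, 5.5)
        stir = np.clip(stir, 220.0, 300.0)
        for ti, ai, si in zip(t, air, stir):
            rows.append(
                {"time_h": float(ti), "air_flow_l_min": float(ai), "stirring_min1": float(si), "vessel": vessel}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scenario templates
# ---------------------------------------------------------------------------

FULL_TIMES = (0.0, 24.0, 48.0, 72.0, 96.0, 120.0, 144.0, 168.0)

#: per-stratum object count; >= the 30-object rule used for the statistics
DEFAULT_COUNT = 35


def _pellets(species: str, mean: float, *, axis=(1.0, 1.2), axis_mean=None, count=DEFAULT_COUNT,
             fringe_rel=0.12, fringe_density=0.35, cv=0.3) -> PopulationSpec:
    return PopulationSpec(
        kind="pellet",
        count=count,
        species=species,
        mean_area_um2=mean,
        cv_area=cv,
        axis_ratio_range=axis,
        axis_ratio_mean=axis_mean,
        fringe_depth_rel=fringe_rel,
        fringe_density=fringe_density,
    )


def _debris(species: str, mean: float = 1.0e5, count=DEFAULT_COUNT) -> list[PopulationSpec]:
    """Hyphal fragments + clumps pooled as the dispersed fraction."""
    n_hyphae = count // 2
    n_clumps = count - n_hyphae
    return [
        PopulationSpec(kind="hypha", count=n_hyphae, species=species),
        PopulationSpec(
            kind="clump",
            count=n_clumps,
            species=species,
            mean_area_um2=mean,
            cv_area=0.4,
            axis_ratio_range=(2.05, 3.0),
        ),
    ]


def _traj(times, knots_t, knots_v):
    return {t: float(np.interp(t, knots_t, knots_v)) for t in times}


def simultaneous_preculture(times: tuple[float, ...] = FULL_TIMES, count: int = DEFAULT_COUNT) -> ScenarioSpec:
    """Both 24 h precultures inoculated together: advantage to species B.

    Species-A pellets are ~10x smaller in the coculture than in the
    monoculture at every sampling (1.3e6 vs 1.3e7 µm² at 24 h) and more
    elongated (E 1.56 vs 1.08 at 24 h); species-B pellets are statistically
    indistinguishable between vessels from 48 h on.
    """
    times = tuple(times)
    monoA_A = _traj(times, FULL_TIMES, (1.2e6, 1.3e7, 1.1e7, 1.1e7, 1.1e7, 1.05e7, 1.0e7, 1.0e7))
    coA_A = _traj(times, FULL_TIMES, (2.1e6, 1.3e6, 1.1e6, 1.0e6, 9.0e5, 8.5e5, 8.0e5, 7.3e5))
    monoB_A = _traj(times, FULL_TIMES, (0.0, 5.1e5, 3.4e5, 2.7e5, 2.2e5, 1.9e5, 1.8e5, 1.7e5))
    coB_A = _traj(times, FULL_TIMES, (0.0, 2.9e5, 3.4e5, 2.7e5, 2.2e5, 1.9e5, 1.8e5, 1.5e5))

    pops: dict[tuple[str, float], list[PopulationSpec]] = {}
    for t in times:
        pops[("monoA", t)] = [_pellets("A", monoA_A[t], axis_mean=1.08, count=count)]
        if t >= 48:
            pops[("monoA", t)] += _debris("A", count=count)
        pops[("monoB", t)] = []
        pops[("coculture", t)] = [_pellets("A", coA_A[t], axis_mean=1.56, count=count)]
        if monoB_A[t] > 0:
            pops[("monoB", t)] = [_pellets("B", monoB_A[t], axis_mean=1.29, count=count)] + _debris(
                "B", count=count
            )
            pops[("coculture", t)] += [_pellets("B", coB_A[t], axis_mean=1.36, count=count)]
            pops[("coculture", t)] += _debris("A", count=count // 2) + _debris("B", count=count // 2)
        else:
            pops[("monoB", t)] = _debris("B", count=count)

    profiles = {
        "coculture": ProfileTemplate((0, 8, 36, 60, 96, 168), (2.0, 5.5, 5.5, 3.0, 2.0, 1.6), (250, 300, 300, 280, 250, 235)),
        "monoB": ProfileTemplate((0, 10, 36, 60, 96, 168), (2.0, 5.5, 5.5, 3.1, 2.0, 1.6), (250, 300, 300, 282, 252, 236)),
        "monoA": ProfileTemplate((0, 17, 22, 63, 77, 168), (1.5, 3.5, 3.5, 2.2, 1.5, 1.5), (220, 230, 255, 284, 225, 220)),
    }
    return ScenarioSpec(
        experiment="SIM-PRE",
        populations=pops,
        second_introduction_h=0.0,
        profiles=profiles,
        filter_overrides={"species_area_threshold": 6.0e5},
    )


def delayed_introduction(
    times: tuple[float, ...] = (24.0, 48.0, 72.0, 96.0, 120.0, 144.0, 168.0, 192.0),
    count: int = DEFAULT_COUNT,
) -> ScenarioSpec:
    """Species B introduced 24 h late: domination by species A.

    Coculture B pellets (those formed in the preculture) appear only at the
    24 h sampling and are destroyed afterwards, while the B monoculture keeps
    forming pellets throughout.
    """
    times = tuple(times)
    base = (24.0, 48.0, 72.0, 96.0, 120.0, 144.0, 168.0, 192.0)
    monoA_A = _traj(times, base, (1.4e7, 1.2e7, 1.1e7, 1.0e7, 1.0e7, 9.5e6, 9.0e6, 8.5e6))
    coA_A = _traj(times, base, (6.3e6, 5.6e6, 4.8e6, 4.0e6, 3.2e6, 2.5e6, 1.9e6, 1.4e6))
    monoB_A = _traj(times, base, (0.0, 1.0e5, 1.0e5, 9.5e4, 9.0e4, 9.0e4, 8.5e4, 8.0e4))

    pops: dict[tuple[str, float], list[PopulationSpec]] = {}
    for t in times:
        pops[("monoA", t)] = [_pellets("A", monoA_A[t], axis_mean=1.1, count=count)]
        if t >= 72:
            pops[("monoA", t)] += _debris("A", count=count)
        pops[("coculture", t)] = [_pellets("A", coA_A[t], axis_mean=1.3, count=count)]
        if t == 24.0:
            # preculture-formed B pellets, destroyed within the next 24 h
            pops[("coculture", t)] += [_pellets("B", 3.0e4, axis_mean=1.3, count=count, fringe_rel=0.08)]
        else:
            pops[("coculture", t)] += _debris("A", count=count // 2) + _debris("B", count=count // 2)
        if t >= 48:
            pops[("monoB", t)] = [
                _pellets("B", monoB_A[t], axis_mean=1.3, count=count, fringe_rel=0.08)
            ] + _debris("B", count=count)
        else:
            pops[("monoB", t)] = []
    pops = {k: v for k, v in pops.items() if v}

    profiles = {
        "coculture": ProfileTemplate((24, 48, 96, 144, 192), (2.0, 2.6, 3.0, 2.4, 2.0), (230, 245, 260, 245, 235)),
        "monoA": ProfileTemplate((0, 48, 96, 144, 192), (1.9, 2.5, 3.0, 2.4, 2.0), (228, 244, 260, 246, 236)),
        "monoB": ProfileTemplate((24, 48, 96, 144, 192), (3.5, 5.0, 4.0, 3.0, 2.5), (280, 300, 290, 270, 260)),
    }
    return ScenarioSpec(
        experiment="DELAY-B",
        populations=pops,
        second_introduction_h=24.0,
        profiles=profiles,
    )


def spore_inoculation(times: tuple[float, ...] = FULL_TIMES, count: int = DEFAULT_COUNT) -> ScenarioSpec:
    """Both species inoculated as spores: domination by species B.

    Species-A pellets never appear in the coculture; species-B pellets are
    small (1e4–2e4 µm²) and near-identical between vessels.
    """
    times = tuple(times)
    base = FULL_TIMES
    monoA_A = _traj(times, base, (0.0, 0.0, 1.0e6, 1.2e6, 1.2e6, 1.1e6, 1.1e6, 1.0e6))
    monoB_A = _traj(times, base, (0.0, 1.4e4, 1.2e4, 1.0e4, 1.1e4, 1.2e4, 1.3e4, 1.4e4))
    coB_A = _traj(times, base, (0.0, 1.9e4, 1.6e4, 1.2e4, 1.1e4, 1.2e4, 1.25e4, 1.3e4))

    pops: dict[tuple[str, float], list[PopulationSpec]] = {}
    for t in times:
        pops[("monoA", t)] = []
        if monoA_A[t] > 0:
            pops[("monoA", t)] += [_pellets("A", monoA_A[t], axis_mean=1.2, count=count)]
        if t >= 24:
            pops[("monoA", t)] += _debris("A", count=count)
            pops[("monoB", t)] = [
                _pellets("B", monoB_A[t], axis_mean=1.3, count=count, fringe_rel=0.08, cv=0.25)
            ] + _debris("B", count=count)
            pops[("coculture", t)] = [
                _pellets("B", coB_A[t], axis_mean=1.3, count=count, fringe_rel=0.08, cv=0.25)
            ] + _debris("A", count=count // 2) + _debris("B", count=count // 2)
        else:
            pops[("monoB", t)] = []
            pops[("coculture", t)] = []
    pops = {k: v for k, v in pops.items() if v}

    profiles = {
        "coculture": ProfileTemplate((0, 24, 96, 111, 153, 168), (1.6, 2.2, 2.6, 3.5, 5.0, 4.5), (230, 255, 265, 280, 300, 295)),
        "monoB": ProfileTemplate((0, 24, 96, 111, 153, 168), (1.6, 2.3, 2.7, 5.0, 4.0, 3.6), (232, 256, 266, 292, 285, 280)),
        "monoA": ProfileTemplate((0, 168), (1.5, 1.5), (220, 220)),
    }
    return ScenarioSpec(
        experiment="SPORE",
        populations=pops,
        second_introduction_h=0.0,
        profiles=profiles,
        filter_overrides={"pellet_min_area": 3.0e3},
    )
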