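"""Generator correctness: determinism, analytic shapes, population statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from skimage.draw import polygon as sk_polygon
from skimage.measure import perimeter_crofton

from mycomorph.errors import ParameterError
from mycomorph.synth import (
    ObjectSpec,
    PopulationSpec,
    SceneSpec,
    delayed_introduction,
    generate_timecourse,
    pick_scale,
    place_on_grid,
    render_scene,
    sample_population,
    simultaneous_preculture,
)
from mycomorph.synth._raster import polygon_pixels


class TestSamplePopulation:
    def test_empty_population(self):
        pop = PopulationSpec(kind="pellet", count=0)
        assert sample_population(pop, 1) == []

    def test_negative_count_rejected(self):
        with pytest.raises(ParameterError):
            PopulationSpec(kind="pellet", count=-1)

    def test_negative_cv_rejected(self):
        with pytest.raises(ParameterError):
            PopulationSpec(kind="pellet", count=5, cv_area=-0.1)

    def test_lognormal_mean_converges(self):
        # law of large numbers against the closed-form log-normal mean
        pop = PopulationSpec(kind="pellet", count=10_000, mean_area_um2=1.0e5, cv_area=0.3)
        areas = np.array([np.pi * o.core_radius**2 for o in sample_population(pop, 1)])
        assert abs(areas.mean() - 1.0e5) / 1.0e5 < 0.02

    def test_core_radius_is_disk_radius_of_drawn_area(self):
        pop = PopulationSpec(kind="pellet", count=50, mean_area_um2=1.3e7, cv_area=0.3)
        objs = sample_population(pop, 3)
        for o in objs:
            assert o.core_radius > 0
            # radius and fringe follow the drawn area through the disk identity
            assert o.fringe_depth == pytest.approx(pop.fringe_depth_rel * o.core_radius)

    def test_mean_recovery_within_3_se(self):
        pop = PopulationSpec(kind="clump", count=400, mean_area_um2=2.0e5, cv_area=0.4)
        areas = np.array([np.pi * o.core_radius**2 for o in sample_population(pop, 7)])
        se = 2.0e5 * 0.4 / np.sqrt(400)
        assert abs(areas.mean() - 2.0e5) < 3 * se

    def test_deterministic(self):
        pop = PopulationSpec(kind="hypha", count=10)
        assert sample_population(pop, 42) == sample_population(pop, 42)


class TestRenderScene:
    def test_label_count_conservation(self):
        objs = [
            ObjectSpec(kind="pellet", center=(200.0 + 420 * i, 200.0), core_radius=80.0)
            for i in range(3)
        ]
        scene = SceneSpec(objects=objs, image_size=(512, 1024), scale=2.0, seed=1)
        r = render_scene(scene)
        assert sorted(np.unique(r.truth_mask)) == [0, 1, 2, 3]

    def test_bit_identical_rerender(self, tmp_path):
        objs = [
            ObjectSpec(kind="pellet", center=(300, 300), core_radius=120, fringe_depth=12, fringe_density=0.35),
            ObjectSpec(kind="hypha", center=(700, 300), length=300, thickness=10, tortuosity=3.0),
            ObjectSpec(kind="clump", center=(300, 700), core_radius=100, axis_ratio=2.5),
        ]
        scene = SceneSpec(objects=objs, image_size=(512, 512), scale=2.0, seed=7)
        a, b = render_scene(scene), render_scene(scene)
        assert np.array_equal(a.image.pixels, b.image.pixels)
        assert np.array_equal(a.truth_mask, b.truth_mask)
        # byte-identical on disk as well
        from mycomorph import io as mio

        mio.write_image(tmp_path / "a.tif", a.image.pixels)
        mio.write_image(tmp_path / "b.tif", b.image.pixels)
        assert (tmp_path / "a.tif").read_bytes() == (tmp_path / "b.tif").read_bytes()

    def test_smooth_disk_truth_area(self):
        spec = ObjectSpec(kind="pellet", center=(150.0, 150.0), core_radius=100.0)
        scene = SceneSpec(objects=[spec], image_size=(300, 300), scale=1.0, noise_sd=0, seed=1)
        r = render_scene(scene)
        target = np.pi * 100.0**2
        assert abs((r.truth_mask == 1).sum() - target) / target < 0.01
        assert abs(r.truth_table.true_area_um2[0] - target) / target < 0.01

    def test_straight_rod_truth_area(self):
        spec = ObjectSpec(kind="hypha", center=(250.0, 250.0), length=200.0, thickness=10.0, tortuosity=0.0)
        scene = SceneSpec(objects=[spec], image_size=(500, 500), scale=1.0, noise_sd=0, seed=2)
        r = render_scene(scene)
        assert abs((r.truth_mask == 1).sum() - 2000.0) / 2000.0 < 0.03

    def test_fringe_depth_increases_boundary_length(self):
        perims = []
        for depth in (0.0, 5.0, 10.0, 20.0):
            spec = ObjectSpec(
                kind="pellet", center=(256.0, 256.0), core_radius=150.0,
                fringe_depth=depth, fringe_density=0.35,
            )
            scene = SceneSpec(objects=[spec], image_size=(512, 512), scale=1.0, noise_sd=0, seed=5)
            r = render_scene(scene)
            perims.append(perimeter_crofton(r.truth_mask == 1, directions=4))
        assert all(b > a for a, b in zip(perims, perims[1:]))

    def test_overlapping_objects_flagged(self):
        objs = [
            ObjectSpec(kind="pellet", center=(200.0, 200.0), core_radius=80.0),
            ObjectSpec(kind="pellet", center=(260.0, 200.0), core_radius=80.0),
        ]
        scene = SceneSpec(objects=objs, image_size=(256, 256), scale=2.0, seed=3)
        r = render_scene(scene)
        assert r.truth_table["overlapping"].all()

    def test_zero_fringe_density_means_smooth_boundary(self):
        smooth = ObjectSpec(kind="pellet", center=(150.0, 150.0), core_radius=100.0,
                            fringe_depth=20.0, fringe_density=0.0)
        scene = SceneSpec(objects=[smooth], image_size=(300, 300), scale=1.0, noise_sd=0, seed=9)
        r = render_scene(scene)
        p = perimeter_crofton(r.truth_mask == 1, directions=4)
        assert abs(p - 2 * np.pi * 100) / (2 * np.pi * 100) < 0.02


class TestRasterizer:
    def test_matches_reference_rasterization(self, rng):
        # same strictly-inside-pixel-center convention as skimage.draw.polygon
        for _ in range(50):
            n = int(rng.integers(3, 12))
            xs = rng.uniform(2, 60, n)
            ys = rng.uniform(2, 60, n)
            order = np.argsort(np.arctan2(ys - ys.mean(), xs - xs.mean()))
            xs, ys = xs[order], ys[order]
            rr1, cc1 = sk_polygon(ys, xs, shape=(64, 64))
            rr2, cc2 = polygon_pixels(xs, ys, (64, 64))
            assert set(zip(rr1.tolist(), cc1.tolist())) == set(zip(rr2.tolist(), cc2.tolist()))


class TestPlacementAndScale:
    def test_pick_scale_for_giant_pellets_vs_hyphae(self):
        giants = sample_population(PopulationSpec(kind="pellet", count=5, mean_area_um2=1.3e7), 1)
        hyphae = sample_population(PopulationSpec(kind="hypha", count=5), 1)
        assert pick_scale(giants) == 16.0
        assert pick_scale(hyphae) == 2.0

    def test_grid_placement_never_overlaps(self):
        objs = sample_population(
            PopulationSpec(kind="pellet", count=12, mean_area_um2=1.0e6, cv_area=0.3), 2
        )
        for sc in place_on_grid(objs, 8.0, seed=2):
            r = render_scene(sc)
            assert not r.truth_table["overlapping"].any()


class TestTimecourse:
    def test_sample_group_count(self, tmp_path):
        # 3 vessels x 8 sampling times -> 24 distinct sampling groups
        scen = simultaneous_preculture(count=6)
        manifest = generate_timecourse(scen, seed=1, out_dir=tmp_path)
        groups = manifest.groupby(["culture", "time_h"]).ngroups
        assert groups == 24
        assert set(manifest["culture"]) == {"monoA", "monoB", "coculture"}

    def test_manifest_deterministic(self, tmp_path):
        scen = delayed_introduction(times=(24.0, 48.0), count=6)
        m1 = generate_timecourse(scen, seed=9, out_dir=tmp_path / "a")
        m2 = generate_timecourse(scen, seed=9, out_dir=tmp_path / "b")
        pd.testing.assert_frame_equal(m1, m2)
        img = m1.iloc[0]["image"]
        assert (tmp_path / "a" / img).read_bytes() == (tmp_path / "b" / img).read_bytes()

    def test_delayed_coculture_loses_species_b_pellets(self, tmp_path):
        # species-B pellets only exist at the first sampling after introduction
        scen = delayed_introduction(times=(24.0, 48.0, 72.0), count=6)
        manifest = generate_timecourse(scen, seed=4, out_dir=tmp_path)
        co_pellets = manifest[
            (manifest["culture"] == "coculture")
            & (manifest["kind"] == "pellet")
            & (manifest["species"] == "B")
        ]
        assert set(co_pellets["time_h"]) == {24.0}
        # while the B monoculture keeps its pellets
        mono_pellets = manifest[
            (manifest["culture"] == "monoB") & (manifest["kind"] == "pellet")
        ]
        assert set(mono_pellets["time_h"]) == {48.0, 72.0}

    def test_truth_mean_tracks_template(self, tmp_path):
        scen = simultaneous_preculture(times=(24.0,), count=25)
        manifest = generate_timecourse(scen, seed=8, out_dir=tmp_path)
        rows = manifest[
            (manifest["culture"] == "monoA") & (manifest["kind"] == "pellet")
        ]
        truths = pd.concat([pd.read_csv(tmp_path / t) for t in rows["truth"]])
        mean = truths["core_area_um2"].mean()
        se = 1.3e7 * 0.3 / np.sqrt(len(truths))
        assert abs(mean - 1.3e7) < 4 * se
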