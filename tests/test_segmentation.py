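"""Segmentation front end: filters, thresholding, labeling, operator overrides."""

from __future__ import annotations

import numpy as np
import pytest
from skimage.measure import label as sklabel

from mycomorph.errors import EditError
from mycomorph.segmentation import (
    CalibratedImage,
    LabeledMask,
    OverrideEdit,
    SegmentationParams,
    apply_overrides,
    detect_edges,
    preprocess,
    segment,
)
from mycomorph.synth import ObjectSpec, SceneSpec, render_noise_free, render_scene


def _disk_scene(radius_um=100.0, scale=1.0, noise=8.0, size=300):
    spec = ObjectSpec(kind="pellet", center=(size * scale / 2,) * 2, core_radius=radius_um)
    return SceneSpec(objects=[spec], image_size=(size, size), scale=scale, noise_sd=noise, seed=42)


class TestPreprocess:
    def test_radius_zero_is_identity(self):
        img = CalibratedImage(np.arange(64, dtype=float).reshape(8, 8), 1.0)
        out = preprocess(img, 0)
        assert np.array_equal(out.pixels, img.pixels)
        assert out.pixels is not img.pixels

    def test_salt_pixel_removed(self):
        field = np.full((21, 21), 100.0)
        field[10, 10] = 255.0
        out = preprocess(CalibratedImage(field, 1.0), 2)
        assert out.pixels[10, 10] == 100.0

    def test_noise_sd_strictly_decreases(self):
        scene = _disk_scene()
        noisy = render_scene(scene).image
        clean = render_noise_free(scene).image
        raw_sd = np.std(noisy.pixels.astype(float) - clean.pixels.astype(float))
        smooth_sd = np.std(preprocess(noisy, 2).pixels.astype(float) - clean.pixels.astype(float))
        assert smooth_sd < raw_sd

    def test_metadata_preserved(self):
        img = CalibratedImage(np.zeros((8, 8)), 2.0, experiment="E1", culture="monoA", time_h=24.0)
        out = preprocess(img, 1)
        assert (out.scale, out.experiment, out.culture, out.time_h) == (2.0, "E1", "monoA", 24.0)


class TestDetectEdges:
    def test_constant_image_zero_gradient(self):
        img = CalibratedImage(np.full((32, 32), 7.0), 1.0)
        assert np.all(detect_edges(img) == 0)

    def test_step_edge_band(self):
        arr = np.zeros((32, 32))
        arr[:, 16:] = 1.0
        g = detect_edges(CalibratedImage(arr, 1.0))
        cols = g.sum(axis=0)
        assert set(np.flatnonzero(cols >= 0.99 * cols.max())) <= {15, 16}

    def test_disk_boundary_ring(self):
        scene = _disk_scene(noise=0.0)
        img = render_scene(scene).image
        g = detect_edges(img)
        rr, cc = np.nonzero(g >= 0.5 * g.max())
        radii = np.hypot(rr - 150.0, cc - 150.0)
        assert abs(np.median(radii) - 100.0) <= 2.0


class TestSegment:
    def test_blank_scene_zero_objects(self):
        scene = SceneSpec(objects=[], image_size=(128, 128), scale=1.0, seed=0)
        img = render_scene(scene).image
        mask = segment(img)
        assert mask.n_objects == 0

    def test_uniform_image_warns_not_fails(self):
        img = CalibratedImage(np.full((64, 64), 50.0), 1.0)
        with pytest.warns(UserWarning, match="uniform"):
            mask = segment(img)
        assert mask.n_objects == 0

    def test_two_pellets_two_labels_area_within_5pct(self):
        objs = [
            ObjectSpec(kind="pellet", center=(150.0, 150.0), core_radius=60.0),
            ObjectSpec(kind="pellet", center=(420.0, 420.0), core_radius=80.0),
        ]
        scene = SceneSpec(objects=objs, image_size=(600, 600), scale=1.0, seed=6)
        r = render_scene(scene)
        mask = segment(r.image)
        assert mask.n_objects == 2
        for lab, true_r in zip(mask.label_values, (60.0, 80.0)):
            measured = (mask.labels == lab).sum()
            truth = np.pi * true_r**2
            assert abs(measured - truth) / truth < 0.05

    def test_small_speck_removed(self):
        objs = [
            ObjectSpec(kind="pellet", center=(100.0, 100.0), core_radius=60.0),
            ObjectSpec(kind="pellet", center=(250.0, 250.0), core_radius=5.6),  # ~100 µm²
        ]
        scene = SceneSpec(objects=objs, image_size=(300, 300), scale=1.0, seed=8)
        mask = segment(render_scene(scene).image, SegmentationParams(min_object_area=500.0))
        assert mask.n_objects == 1

    @pytest.mark.parametrize("scale", [1.0, 2.0])
    def test_min_area_is_resolution_invariant(self, scale):
        # the same physical 314 µm² speck dies at any magnification
        size = int(300 / scale)
        objs = [
            ObjectSpec(kind="pellet", center=(100.0, 100.0), core_radius=30.0),
            ObjectSpec(kind="pellet", center=(250.0, 250.0), core_radius=10.0),
        ]
        scene = SceneSpec(objects=objs, image_size=(size, size), scale=scale, seed=8)
        mask = segment(render_scene(scene).image, SegmentationParams(min_object_area=500.0))
        assert mask.n_objects == 1

    def test_border_touching_excluded_by_default(self):
        objs = [ObjectSpec(kind="pellet", center=(10.0, 150.0), core_radius=60.0)]
        scene = SceneSpec(objects=objs, image_size=(300, 300), scale=1.0, seed=3)
        img = render_scene(scene).image
        assert segment(img).n_objects == 0
        keep = SegmentationParams(exclude_border=False)
        assert segment(img, keep).n_objects == 1

    def test_idempotent_on_binary_rendering(self):
        scene = SceneSpec(
            objects=[
                ObjectSpec(kind="pellet", center=(150.0, 150.0), core_radius=60.0),
                ObjectSpec(kind="clump", center=(420.0, 420.0), core_radius=70.0, axis_ratio=2.2),
            ],
            image_size=(600, 600),
            scale=1.0,
            seed=12,
        )
        mask1 = segment(render_scene(scene).image)
        binary_img = np.where(mask1.labels > 0, 60, 200).astype(np.uint8)
        mask2 = segment(CalibratedImage(binary_img, 1.0), SegmentationParams(median_radius=0))
        assert mask2.n_objects == mask1.n_objects
        assert np.array_equal(mask2.labels > 0, mask1.labels > 0)

    def test_labels_partition_foreground(self):
        scene = _disk_scene()
        mask = segment(render_scene(scene).image)
        binary = mask.labels > 0
        relabeled = sklabel(binary, connectivity=2)
        assert relabeled.max() == mask.n_objects


class TestOverrides:
    @pytest.fixture()
    def three_mask(self):
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[2:10, 2:10] = 1
        labels[2:10, 10:18] = 2  # abuts label 1
        labels[25:35, 25:35] = 3
        return LabeledMask(labels, 1.0)

    def test_empty_edit_list_is_identity(self, three_mask):
        out, audit = apply_overrides(three_mask, [])
        assert np.array_equal(out.labels, three_mask.labels)
        assert audit == []

    def test_delete(self, three_mask):
        out, audit = apply_overrides(three_mask, [OverrideEdit(3, "delete")])
        assert out.n_objects == 2
        assert 3 not in out.label_values
        assert audit[0]["action"] == "delete"

    def test_merge_abutting_labels_connected(self, three_mask):
        out, _ = apply_overrides(three_mask, [OverrideEdit(1, "merge", "2")])
        merged = out.labels == 1
        assert sklabel(merged, connectivity=2).max() == 1
        assert merged.sum() == 2 * 64

    def test_split_by_seed_points(self):
        labels = np.zeros((20, 60), dtype=np.int32)
        labels[5:15, 5:55] = 1
        mask = LabeledMask(labels, 1.0)
        out, _ = apply_overrides(mask, [OverrideEdit(1, "split", "10:10;10:50")])
        assert out.n_objects == 2
        assert (out.labels > 0).sum() == (labels > 0).sum()

    def test_species_tag_recorded(self, three_mask):
        out, _ = apply_overrides(three_mask, [OverrideEdit(2, "species", "B")])
        assert out.species_tags == {2: "B"}

    def test_unknown_label_raises_named_error(self, three_mask):
        with pytest.raises(EditError, match="99"):
            apply_overrides(three_mask, [OverrideEdit(99, "delete")])


class TestPipelineRecall:
    def test_recall_and_area_error_on_default_scenes(self, debris_run, pellet_run):
        for run in (debris_run, pellet_run):
            recovered = sum(len(m.table[m.table.pred_label > 0]) for m in run["matches"])
            total = sum(len(m.table) for m in run["matches"])
            assert recovered / total >= 0.95
            errs = np.concatenate(
                [
                    (m.table[m.table.pred_label > 0]
                     .eval("abs(pred_area_px - true_area_px) / true_area_px")
                     .to_numpy())
                    for m in run["matches"]
                ]
            )
            assert errs.mean() <= 0.05
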