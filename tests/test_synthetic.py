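import numpy as np
import pytest

import weedvision as wv
from weedvision.features import ggcm, ggcm_stats
from weedvision.synthetic import TooCrowdedError


class TestMakeLeaf:
    def test_deterministic_per_class_and_seed(self):
        a = wv.make_leaf("corn", 11)
        b = wv.make_leaf("corn", 11)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, wv.make_leaf("corn", 12))
        assert not np.array_equal(a, wv.make_leaf("weed", 11))

    def test_zero_padded_background(self):
        """The frame outside the leaf support is exactly zero."""
        for seed in (0, 1, 2):
            img = wv.make_leaf("weed", seed)
            mask = img.any(axis=2)
            assert img.shape == (256, 256, 3)
            # padding convention: a substantial zero background remains
            assert (~mask).mean() > 0.4
            assert img[~mask].sum() == 0

    def test_corn_larger_than_weed_on_average(self):
        corn = np.mean([wv.make_leaf("corn", s).any(axis=2).mean()
                        for s in range(15)])
        weed = np.mean([wv.make_leaf("weed", s).any(axis=2).mean()
                        for s in range(15)])
        assert corn > weed

    def test_greenish_hue(self):
        img = wv.make_leaf("corn", 5)
        lab = wv.rgb_to_lab(img)
        mask = img.any(axis=2)
        assert lab[:, :, 1][mask].mean() < -15  # vegetation: negative a

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            wv.make_leaf("grass", 0)

    def test_class_texture_statistics_separate(self):
        """Mean GGCM small-gradient dominance differs between classes:
        corn is smooth/striped, weed carries high-frequency speckle."""
        def stat(cls, seed):
            gray = wv.to_gray(wv.make_leaf(cls, seed))
            return ggcm_stats(ggcm(gray))[0]

        corn = np.array([stat("corn", s) for s in range(40)])
        weed = np.array([stat("weed", s) for s in range(40)])
        gap = abs(corn.mean() - weed.mean())
        sem = np.sqrt(corn.var(ddof=1) / corn.size + weed.var(ddof=1) / weed.size)
        assert gap > 3 * sem


class TestMakeDataset:
    def test_manifest_reproducible_and_counts(self, tmp_path):
        _, y1, m1 = wv.make_dataset(8, 5, seed=3)
        _, y2, m2 = wv.make_dataset(8, 5, seed=3)
        assert m1.equals(m2)
        assert (y1 == 1).sum() == 8 and (y1 == -1).sum() == 5
        assert (m1["class"] == "corn").sum() == 8

    def test_writes_pngs_and_manifest(self, tmp_path):
        wv.make_dataset(2, 2, seed=0, out_dir=tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        assert len(list(tmp_path.glob("*.png"))) == 4
        img = wv.load_image(tmp_path / "leaf_corn_0000.png")
        assert np.array_equal(img, wv.make_leaf("corn", 0))

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            wv.make_dataset(0, 5)


class TestMakeFieldScene:
    def test_truth_record_count(self):
        _, truth = wv.make_field_scene(2, 4, size=(600, 1024), seed=1)
        assert truth.count() == 6
        assert truth.count("corn") == 2 and truth.count("weed") == 4

    def test_pixel_identical_given_seed(self):
        a, _ = wv.make_field_scene(1, 2, size=(400, 500), seed=9)
        b, _ = wv.make_field_scene(1, 2, size=(400, 500), seed=9)
        assert np.array_equal(a, b)

    def test_boxes_within_scene_and_disjoint(self):
        scene, truth = wv.make_field_scene(2, 4, size=(600, 1024), seed=2)
        for p in truth.plants:
            r0, c0, r1, c1 = p.box
            assert 0 <= r0 < r1 <= 600 and 0 <= c0 < c1 <= 1024
            assert p.area > 0
        boxes = [p.box for p in truth.plants]
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                a, b = boxes[i], boxes[j]
                assert (a[2] <= b[0] or b[2] <= a[0]
                        or a[3] <= b[1] or b[3] <= a[1])

    def test_vegetation_mask_matches_plant_areas(self):
        _, truth = wv.make_field_scene(1, 3, size=(500, 700), seed=4)
        assert truth.veg_mask.sum() == sum(p.area for p in truth.plants)

    def test_too_crowded_raises(self):
        with pytest.raises(TooCrowdedError):
            wv.make_field_scene(6, 12, size=(260, 260), seed=0, max_tries=30)

    def test_too_small_scene_rejected(self):
        with pytest.raises(ValueError):
            wv.make_field_scene(1, 1, size=(100, 500), seed=0)

    def test_json_export_is_serializable(self):
        import json
        _, truth = wv.make_field_scene(1, 1, size=(400, 400), seed=5)
        payload = json.dumps(truth.to_json_dict())
        assert "plants" in json.loads(payload)
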