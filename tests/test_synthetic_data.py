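"""Generator contracts: balance, determinism, separability, disk round trip."""

import numpy as np
import pytest

import fedleaf as fl
from fedleaf.synthetic_data import DATASET_PRESETS

from conftest import nearest_centroid_predict


class TestMakeDataset:
    def test_balanced_and_sized(self, small_dataset):
        assert len(small_dataset) == 120
        counts = np.bincount(small_dataset.labels, minlength=4)
        assert (counts == 30).all()
        assert small_dataset.images.shape == (120, 32, 32, 3)
        assert small_dataset.images.min() >= 0.0
        assert small_dataset.images.max() <= 1.0

    def test_identical_spec_bitwise_identical(self):
        spec = fl.SyntheticDatasetSpec(
            n_classes=4, images_per_class=5, image_size=(16, 16),
            noise_level=0.3, seed=11,
        )
        a, b = fl.make_dataset(spec), fl.make_dataset(spec)
        assert (a.images == b.images).all()
        assert (a.labels == b.labels).all()

    def test_noise_free_data_nearest_template_separable(self, clean_dataset):
        """At noise 0, centroids from 10 images/class classify the rest at 100%."""
        d = clean_dataset
        fit_idx, rest_idx = [], []
        for c in range(4):
            cls = np.flatnonzero(d.labels == c)
            fit_idx.extend(cls[:10])
            rest_idx.extend(cls[10:])
        pred = nearest_centroid_predict(
            d.images[fit_idx], d.labels[fit_idx], d.images[rest_idx], 4
        )
        assert (pred == d.labels[rest_idx]).all()

    def test_template_accuracy_non_increasing_in_noise(self):
        """Median oracle accuracy over 3 seeds does not rise with noise."""
        levels = [0.0, 0.4, 0.9]
        medians = []
        for noise in levels:
            accs = []
            for seed in (1, 2, 3):
                d = fl.make_dataset(
                    fl.SyntheticDatasetSpec(
                        n_classes=4, images_per_class=20,
                        image_size=(24, 24), noise_level=noise, seed=seed,
                    )
                )
                pred = nearest_centroid_predict(d.images, d.labels, d.images, 4)
                accs.append((pred == d.labels).mean())
            medians.append(np.median(accs))
        assert medians[0] == 1.0
        assert medians[0] >= medians[1] >= medians[2]

    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_classes", 1),
            ("images_per_class", 0),
            ("image_size", (4, 32)),
            ("noise_level", 1.5),
        ],
    )
    def test_invalid_spec_names_field(self, field, value):
        spec = fl.SyntheticDatasetSpec(**{field: value})
        with pytest.raises(ValueError, match=field.split("_")[0]):
            fl.make_dataset(spec)

    def test_presets_have_one_healthy_class(self):
        for name, classes in DATASET_PRESETS.items():
            assert sum(c.lower() == "healthy" for c in classes) == 1
        spec = fl.SyntheticDatasetSpec(name="tomato", n_classes=10,
                                       images_per_class=2)
        d = fl.make_dataset(spec)
        assert d.n_classes == 10 and len(d) == 20

    def test_preset_class_count_mismatch_rejected(self):
        spec = fl.SyntheticDatasetSpec(name="grape", n_classes=5,
                                       images_per_class=2)
        with pytest.raises(ValueError, match="grape"):
            fl.make_dataset(spec)


class TestStratifiedSplit:
    def test_exact_division(self, small_dataset):
        train, test = fl.stratified_split(small_dataset, 0.2, seed=0)
        assert len(train) == 96 and len(test) == 24
        assert (np.bincount(test.labels, minlength=4) == 6).all()

    def test_rounding_totals(self):
        spec = fl.SyntheticDatasetSpec(n_classes=2, images_per_class=5,
                                       image_size=(8, 8), seed=0)
        d = fl.make_dataset(spec)
        train, test = fl.stratified_split(d, 0.5, seed=3)
        assert len(train) == 5 and len(test) == 5
        per_class = np.bincount(test.labels, minlength=2)
        assert sorted(per_class) == [2, 3]

    def test_disjoint_cover_and_determinism(self, small_dataset):
        t1 = fl.stratified_split(small_dataset, 0.25, seed=9)
        t2 = fl.stratified_split(small_dataset, 0.25, seed=9)
        for (a, b) in zip(t1, t2):
            assert (a.images == b.images).all()
        train, test = t1
        assert len(train) + len(test) == len(small_dataset)
        # every source image lands in exactly one side
        pool = np.concatenate([train.images, test.images])
        assert sorted(map(tuple, pool.reshape(len(pool), -1)[:, :5])) == sorted(
            map(tuple, small_dataset.images.reshape(len(small_dataset), -1)[:, :5])
        )

    def test_tiny_class_rejected(self):
        d = fl.LabeledImageSet(
            np.zeros((3, 8, 8, 3)), [0, 0, 1], ["a", "b"]
        )
        with pytest.raises(ValueError, match="'b'"):
            fl.stratified_split(d, 0.5, seed=0)


class TestDiskRoundTrip:
    def test_write_read_recovers(self, tmp_path):
        spec = fl.SyntheticDatasetSpec(n_classes=3, images_per_class=4,
                                       image_size=(8, 8), seed=2)
        d = fl.make_dataset(spec)
        fl.write_dataset(d, tmp_path / "ds")
        back = fl.read_dataset(tmp_path / "ds")
        assert sorted(back.class_names) == back.class_names  # lexicographic
        assert np.bincount(back.labels).tolist() == [4, 4, 4]
        # pixels within 8-bit quantization; within-class file order is
        # written and read back sorted, so images align class by class
        for name in d.class_names:
            orig = d.images[d.labels == d.class_names.index(name)]
            got = back.images[back.labels == back.class_names.index(name)]
            assert np.abs(orig - got).max() <= 0.5 / 255.0 + 1e-12

    def test_empty_class_dir_errors(self, tmp_path):
        (tmp_path / "ds" / "healthy").mkdir(parents=True)
        (tmp_path / "ds" / "rust").mkdir()
        from PIL import Image

        Image.new("RGB", (8, 8)).save(tmp_path / "ds" / "healthy" / "a.png")
        with pytest.raises(ValueError, match="rust"):
            fl.read_dataset(tmp_path / "ds")

    def test_non_image_file_skipped_with_warning(self, tmp_path):
        from PIL import Image

        d = tmp_path / "ds" / "only"
        d.mkdir(parents=True)
        Image.new("RGB", (8, 8)).save(d / "a.png")
        (d / "notes.txt").write_text("not an image")
        (tmp_path / "ds" / "other").mkdir()
        Image.new("RGB", (8, 8)).save(tmp_path / "ds" / "other" / "b.png")
        with pytest.warns(UserWarning, match="notes.txt"):
            back = fl.read_dataset(tmp_path / "ds")
        assert len(back) == 2

    def test_refuses_nonempty_target(self, tmp_path):
        (tmp_path / "x.txt").write_text("occupied")
        d = fl.make_dataset(
            fl.SyntheticDatasetSpec(n_classes=2, images_per_class=2,
                                    image_size=(8, 8))
        )
        with pytest.raises(FileExistsError):
            fl.write_dataset(d, tmp_path)
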