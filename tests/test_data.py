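"""Preprocessing, stratified splitting, the synthetic phantom generator,
and directory IO."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pneunet.data import (
    ImageRecord,
    SplitSpec,
    SyntheticSpec,
    generate_synthetic,
    load_directory,
    lung_mask,
    preprocess,
    stratified_split,
    write_dataset,
)


class TestPreprocess:
    @pytest.mark.parametrize("value,expected", [(255, 1.0), (0, 0.0), (128, 128 / 255)])
    def test_uniform_images_scale_linearly(self, value, expected):
        rec = ImageRecord("u", np.full((50, 40), value, dtype=np.uint8), "normal")
        out = preprocess(rec, target=32)
        assert out.shape == (32, 32, 3)
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_channels_identical(self):
        rec = ImageRecord("r", np.random.default_rng(0).integers(
            0, 256, (64, 64), dtype=np.uint8), "normal")
        out = preprocess(rec, target=48)
        np.testing.assert_array_equal(out[..., 0], out[..., 1])
        np.testing.assert_array_equal(out[..., 0], out[..., 2])

    def test_idempotent_on_conforming_input(self):
        px = np.random.default_rng(1).integers(0, 256, (224, 224), dtype=np.uint8)
        out = preprocess(ImageRecord("x", px, "normal"), target=224)
        np.testing.assert_allclose(out[..., 0], px / 255.0, atol=1e-7)

    def test_rgb_converted_by_luminance(self):
        px = np.zeros((10, 10, 3), dtype=np.uint8)
        px[..., 1] = 255  # pure green
        out = preprocess(ImageRecord("g", px, "normal"), target=10)
        np.testing.assert_allclose(out[..., 0], 0.587, atol=1e-3)

    def test_empty_image_raises_with_identifier(self):
        with pytest.raises(IOError, match="bad_rec"):
            preprocess(ImageRecord("bad_rec", np.empty((0, 0), dtype=np.uint8), "normal"))


class TestStratifiedSplit:
    def test_ten_item_example(self):
        """6 class-A + 4 class-B at 0.8/0.1/0.1: sizes 8/1/1 by largest
        remainder, with each class represented in train."""
        labels = ["a"] * 6 + ["b"] * 4
        tr, va, te = stratified_split(labels, SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (8, 1, 1)
        assert {labels[i] for i in tr} == {"a", "b"}

    def test_counts_mode_reproduces_printed_sizes(self):
        """Counts mode reproduces the published 4,646/586/624 split of
        5,856 images (3,907 normal / 1,949 pneumonia), stratified to
        within one image per class."""
        labels = np.array(["normal"] * 3907 + ["pneumonia"] * 1949)
        spec = SplitSpec(ratios=None, counts=(4646, 586, 624), seed=42)
        tr, va, te = stratified_split(labels, spec)
        assert (len(tr), len(va), len(te)) == (4646, 586, 624)
        for idx, size in ((tr, 4646), (va, 586), (te, 624)):
            n_pneu = int(np.sum(labels[idx] == "pneumonia"))
            assert abs(n_pneu - size * 1949 / 5856) < 1.0

    def test_deterministic_under_seed(self):
        labels = ["normal"] * 30 + ["pneumonia"] * 20
        a = stratified_split(labels, SplitSpec(seed=9))
        b = stratified_split(labels, SplitSpec(seed=9))
        c = stratified_split(labels, SplitSpec(seed=10))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))
        assert [len(s) for s in c] == [len(s) for s in a]

    @given(n_a=st.integers(2, 40), n_b=st.integers(2, 40), seed=st.integers(0, 1000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_partition_and_stratification_invariants(self, n_a, n_b, seed):
        labels = np.array(["a"] * n_a + ["b"] * n_b)
        n = n_a + n_b
        tr, va, te = stratified_split(labels, SplitSpec(seed=seed))
        all_idx = np.concatenate([tr, va, te])
        assert len(all_idx) == n and len(set(all_idx.tolist())) == n
        sizes = SplitSpec().sizes(n)
        for idx, size in zip((tr, va, te), sizes):
            assert len(idx) == size
            for cls, n_cls in (("a", n_a), ("b", n_b)):
                got = int(np.sum(labels[idx] == cls))
                assert abs(got - size * n_cls / n) < 1.0

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split([], SplitSpec(seed=0))

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="exactly one"):
            SplitSpec(ratios=(0.8, 0.1, 0.1), counts=(8, 1, 1))
        with pytest.raises(ValueError, match="sum to 1"):
            SplitSpec(ratios=(0.8, 0.1, 0.2))


class TestGenerator:
    def test_deterministic_byte_identical(self):
        spec = SyntheticSpec(n_normal=4, n_pneumonia=4, image_size=64, seed=5)
        a = generate_synthetic(spec)
        b = generate_synthetic(spec)
        for ra, rb in zip(a, b):
            assert ra.identifier == rb.identifier and ra.label == rb.label
            np.testing.assert_array_equal(ra.pixels, rb.pixels)

    def test_null_effect_classes_identical(self):
        """With no noise and zero opacity intensity the two classes render
        pixel-identical phantoms."""
        spec = SyntheticSpec(n_normal=2, n_pneumonia=2, image_size=64,
                             noise_sd=0.0, opacity_intensity=0.0, seed=3)
        recs = generate_synthetic(spec)
        np.testing.assert_array_equal(recs[0].pixels, recs[2].pixels)
        np.testing.assert_array_equal(recs[0].pixels, recs[3].pixels)

    def test_pneumonia_brightens_lung_fields(self):
        spec = SyntheticSpec(n_normal=3, n_pneumonia=3, image_size=64,
                             noise_sd=0.0, seed=1)
        recs = generate_synthetic(spec)
        mask = lung_mask(spec)
        normal_mean = np.mean([r.pixels[mask].mean() for r in recs if r.label == "normal"])
        for r in recs:
            if r.label == "pneumonia":
                assert r.pixels[mask].mean() > normal_mean

    def test_opacities_confined_to_lung_mask(self):
        spec = SyntheticSpec(n_normal=1, n_pneumonia=5, image_size=64, seed=2)
        mask = lung_mask(spec)
        for r in generate_synthetic(spec):
            if r.opacity_mask is not None:
                assert not np.any(r.opacity_mask & ~mask)
                assert r.opacity_mask.any()

    def test_mean_lung_intensity_threshold_separates_classes(self, synthetic_dataset):
        """On the default dataset a single threshold on mean lung-field
        intensity classifies with accuracy >= 0.9 (learnability oracle)."""
        spec = SyntheticSpec(seed=7)
        mask = lung_mask(spec)
        feats = np.array([r.pixels[mask].mean() for r in synthetic_dataset])
        y = np.array([r.label == "pneumonia" for r in synthetic_dataset])
        thresholds = np.unique(feats)
        acc = max(np.mean((feats >= t) == y) for t in thresholds)
        assert acc >= 0.9

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            SyntheticSpec(lung_ellipses=((0.3, 0.5, 0.0, 0.2),))


class TestDirectoryIO:
    def test_write_read_roundtrip(self, tmp_path):
        spec = SyntheticSpec(n_normal=3, n_pneumonia=2, image_size=32, seed=4)
        recs = generate_synthetic(spec)
        manifest = write_dataset(recs, tmp_path / "ds")
        assert manifest.exists()
        loaded = load_directory(tmp_path / "ds")
        assert len(loaded) == 5
        assert sorted(r.label for r in loaded) == ["normal"] * 3 + ["pneumonia"] * 2
        by_id = {r.identifier.split("/")[-1]: r for r in loaded}
        for rec in recs:
            np.testing.assert_array_equal(by_id[f"{rec.identifier}.png"].pixels, rec.pixels)

    def test_jpeg_and_png_decode(self, tmp_path):
        from PIL import Image

        root = tmp_path / "mixed"
        (root / "NORMAL").mkdir(parents=True)
        px = np.full((16, 16), 200, dtype=np.uint8)
        Image.fromarray(px).save(root / "NORMAL" / "a.png")
        Image.fromarray(px).save(root / "NORMAL" / "b.jpg", quality=95)
        recs = load_directory(root)
        assert len(recs) == 2
        np.testing.assert_array_equal(recs[0].pixels, px)
        # JPEG is lossy but a constant image survives closely
        assert abs(recs[1].pixels.astype(int) - 200).max() <= 2

    def test_empty_directory_warns(self, tmp_path):
        (tmp_path / "empty" / "NORMAL").mkdir(parents=True)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            recs = load_directory(tmp_path / "empty")
        assert recs == []
        assert any("no images" in str(w.message) for w in caught)

    def test_unknown_class_directory_lists_expected(self, tmp_path):
        (tmp_path / "bad" / "COVID").mkdir(parents=True)
        with pytest.raises(ValueError, match="normal"):
            load_directory(tmp_path / "bad")
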