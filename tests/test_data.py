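"""Data pipeline: grayscale conversion, augmentation registration, patch
sampling, layout loading, inference padding."""

import numpy as np
import pytest

from vesselseg import data, synthetic


class TestToGray:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((1, 0, 0), 0.299), ((0, 1, 0), 0.578), ((0, 0, 1), 0.114),
         ((0, 0, 0), 0.0), ((1, 1, 1), 0.991)],
    )
    def test_printed_coefficients(self, rgb, expected):
        assert data.to_gray(np.array(rgb, dtype=float)) == pytest.approx(expected)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError, match="3 channels"):
            data.to_gray(np.zeros((4, 4)))

    def test_range_bound(self):
        rng = np.random.default_rng(0)
        g = data.to_gray(rng.random((32, 32, 3)))
        assert g.min() >= 0 and g.max() <= 0.991


class TestAugment:
    def test_default_count_is_eight_per_record(self, synth_records):
        out = data.augment(synth_records[:1])
        assert len(out) == 8  # identity + 2 flips + 3 rotations + 2 translations

    def test_hflip_is_involution(self, synth_records):
        img = synth_records[0].image
        assert np.array_equal(data._apply_geom(data._apply_geom(img, "hflip"), "hflip"), img)

    def test_label_transforms_with_image(self, synth_records):
        """Registration: transforming a coordinate grid shows image and
        label move identically."""
        rec = synth_records[0]
        out = data.augment([rec], seed=3)
        for aug in out:
            assert aug.image.shape[:2] == aug.label.shape
            assert set(np.unique(aug.label)) <= {0, 1}
        flipped = [a for a in out if "hflip" in a.id][0]
        assert np.array_equal(flipped.label, rec.label[:, ::-1])
        assert np.array_equal(flipped.image, rec.image[:, ::-1])

    def test_deterministic_given_seed(self, synth_records):
        a = data.augment(synth_records, seed=7)
        b = data.augment(synth_records, seed=7)
        assert [r.id for r in a] == [r.id for r in b]
        assert all(np.array_equal(x.image, y.image) for x, y in zip(a, b))


class TestExtractPatches:
    def test_default_protocol_counts(self, synth_records):
        ps = data.extract_patches(synth_records, n=200, size=64, seed=0)
        assert len(ps) == 200
        for p in ps.patches[:10]:
            assert p.image.shape == (64, 64) and p.label.shape == (64, 64)
            assert 0 <= p.image.min() and p.image.max() <= 1
            y, x = p.top_left
            assert y >= 0 and x >= 0

    def test_same_seed_bit_identical(self, synth_records):
        a = data.extract_patches(synth_records, n=50, seed=9)
        b = data.extract_patches(synth_records, n=50, seed=9)
        assert [p.top_left for p in a.patches] == [p.top_left for p in b.patches]
        assert all(np.array_equal(p.image, q.image) for p, q in zip(a.patches, b.patches))

    def test_single_valid_placement(self):
        rec = synthetic.generate_scene(synthetic.SceneParams(size=(64, 64)))
        ps = data.extract_patches([rec], n=10, size=64, seed=0)
        assert all(p.top_left == (0, 0) for p in ps.patches)

    def test_too_small_records_skipped_with_warning(self, synth_records):
        small = synthetic.generate_scene(synthetic.SceneParams(size=(64, 64)))
        small = data.FundusRecord(id="small", image=small.image[:32, :32],
                                  label=small.label[:32, :32])
        with pytest.warns(UserWarning, match="smaller than patch"):
            data.extract_patches([small] + synth_records, n=20, size=64, seed=0)
        with pytest.raises(ValueError, match="at least"):
            data.extract_patches([small], n=5, size=64, seed=0)


class TestPadForInference:
    def test_drive_resolution(self):
        """565x584 pads to 568x584 (the next multiples of 8) and crops back."""
        x = np.random.default_rng(0).random((565, 584))
        padded, spec = data.pad_for_inference(x)
        assert padded.shape == (568, 584)
        assert np.array_equal(data.crop_to(padded, spec), x)

    def test_already_divisible_unchanged(self):
        x = np.zeros((64, 64))
        padded, spec = data.pad_for_inference(x)
        assert padded.shape == (64, 64) and spec == (64, 64)

    def test_round_trip_random_sizes(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            h, w = rng.integers(16, 100, size=2)
            x = rng.random((h, w))
            padded, spec = data.pad_for_inference(x)
            assert padded.shape[0] % 8 == 0 and padded.shape[1] % 8 == 0
            assert np.array_equal(data.crop_to(padded, spec), x)


class TestLayouts:
    def test_flat_write_read_round_trip(self, tmp_path, synth_records):
        data.write_flat_dataset(tmp_path / "ds", synth_records)
        ds = data.load_dataset(tmp_path / "ds", "flat")
        assert [r.id for r in ds.records] == [r.id for r in synth_records]
        for got, orig in zip(ds.records, synth_records):
            assert np.array_equal(got.label, orig.label)
            assert np.array_equal(got.fov, orig.fov)
            assert np.abs(got.image - orig.image).max() < 1 / 254  # 8-bit raster
        assert ds.train_ids == [r.id for r in synth_records] and ds.test_ids == []

    def test_drive_layout_split(self, tmp_path):
        import imageio.v3 as iio

        root = tmp_path / "drive"
        for sub in ("images", "1st_manual", "mask"):
            (root / sub).mkdir(parents=True)
        rng = np.random.default_rng(0)
        for i in range(21, 61):  # 40 pairs, numbered like the real archive
            img = (rng.random((32, 32, 3)) * 255).astype(np.uint8)
            lab = (rng.random((32, 32)) > 0.9).astype(np.uint8) * 255
            iio.imwrite(root / "images" / f"{i}_test.png", img)
            iio.imwrite(root / "1st_manual" / f"{i}_manual1.png", lab)
            iio.imwrite(root / "mask" / f"{i}_mask.png", np.full((32, 32), 255, np.uint8))
        ds = data.load_dataset(root, "drive")
        assert len(ds.records) == 40
        assert len(ds.train_ids) == 20 and len(ds.test_ids) == 20
        assert ds.train_ids == sorted(ds.train_ids)

    def test_chase_layout_split(self, tmp_path):
        import imageio.v3 as iio

        root = tmp_path / "chase"
        root.mkdir()
        rng = np.random.default_rng(0)
        for i in range(1, 15):
            for side in "LR":
                stem = f"Image_{i:02d}{side}"
                iio.imwrite(root / f"{stem}.jpg",
                            (rng.random((32, 32, 3)) * 255).astype(np.uint8))
                lab = (rng.random((32, 32)) > 0.9).astype(np.uint8) * 255
                iio.imwrite(root / f"{stem}_1stHO.png", lab)
                iio.imwrite(root / f"{stem}_2ndHO.png", lab)
        ds = data.load_dataset(root, "chase")
        assert len(ds.records) == 28
        assert len(ds.train_ids) == 20 and len(ds.test_ids) == 8
        assert all(r.label2 is not None for r in ds.records)

    def test_unpaired_files_listed(self, tmp_path):
        import imageio.v3 as iio

        root = tmp_path / "ds"
        (root / "images").mkdir(parents=True)
        (root / "labels").mkdir()
        iio.imwrite(root / "images" / "a.png", np.zeros((8, 8), np.uint8))
        with pytest.raises(ValueError, match="a"):
            data.load_dataset(root, "flat")

    def test_flat_explicit_split(self, tmp_path, synth_records):
        data.write_flat_dataset(tmp_path / "ds", synth_records)
        ids = [r.id for r in synth_records]
        ds = data.load_dataset(tmp_path / "ds", "flat", train_ids=ids[:1], test_ids=ids[1:])
        assert len(ds.train) == 1 and len(ds.test) == 1
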