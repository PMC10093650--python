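"""Segmentation chain: each stage against an independent oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dryvision import imaging
from dryvision.imaging import (
    DegenerateHistogramError,
    binarize,
    fill_holes,
    filter_particles,
    histogram,
    label_particles,
    metric_threshold,
    segment_frame,
    to_display,
    to_grayscale,
    total_area,
)

from conftest import (
    border_flood_fill_holes,
    brute_force_threshold,
    flood_fill_label,
    random_histogram,
)


class TestGrayscale:
    @pytest.mark.parametrize("rgb,expected", [
        ((0, 0, 0), 0),
        ((255, 255, 255), 255),
        ((30, 60, 90), 60),
        ((1, 1, 0), 1),    # mean 2/3 rounds half-up to 1
        ((1, 0, 0), 0),    # mean 1/3 rounds down
        ((128, 127, 128), 128),  # mean 127.67
    ])
    def test_channel_mean_rounding(self, rgb, expected):
        img = np.array([[rgb]], dtype=np.uint8)
        assert to_grayscale(img)[0, 0] == expected

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((0, 3, 3), dtype=np.uint8))
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4), dtype=np.uint8))

    def test_shape_preserved(self, rng):
        img = rng.integers(0, 256, size=(7, 9, 3)).astype(np.uint8)
        assert to_grayscale(img).shape == (7, 9)


class TestHistogram:
    def test_small_examples(self):
        h = histogram(np.array([[0, 0], [255, 255]], dtype=np.uint8))
        assert h[0] == 2 and h[255] == 2 and h.sum() == 4
        h = histogram(np.full((3, 3), 7, dtype=np.uint8))
        assert h[7] == 9 and h.sum() == 9

    def test_matches_direct_tally(self, rng):
        img = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
        h = histogram(img)
        for level in range(256):
            assert h[level] == int((img == level).sum())


class TestMetricThreshold:
    def test_two_spike_histogram_zero_cost(self):
        h = np.zeros(256, dtype=int)
        h[20], h[220] = 10, 10
        res = metric_threshold(h)
        # any k in [20, 219] is cost-0; the smallest wins
        assert res.k == 20
        assert res.cost == pytest.approx(0.0)
        assert res.mu1 == pytest.approx(20.0)
        assert res.mu2 == pytest.approx(220.0)

    def test_single_level_is_degenerate(self):
        h = np.zeros(256, dtype=int)
        h[100] = 50
        with pytest.raises(DegenerateHistogramError):
            metric_threshold(h)

    def test_class_mean_ordering(self, rng):
        for _ in range(20):
            res = metric_threshold(random_histogram(rng))
            assert res.mu1 <= res.k < res.mu2

    def test_matches_exhaustive_minimization(self, rng):
        for _ in range(50):
            h = random_histogram(rng, n_pixels=int(rng.integers(10, 2000)))
            k_oracle, cost_oracle = brute_force_threshold(h)
            res = metric_threshold(h)
            assert res.k == k_oracle
            assert res.cost == pytest.approx(cost_oracle, rel=1e-12)

    def test_rejects_bad_histograms(self):
        with pytest.raises(ValueError):
            metric_threshold(np.zeros(100))
        with pytest.raises(ValueError):
            metric_threshold(np.zeros(256))
        h = np.zeros(256)
        h[3] = -1
        with pytest.raises(ValueError):
            metric_threshold(h)


class TestBinarize:
    def test_examples(self):
        assert binarize(np.array([[10, 200]]), 20).tolist() == [[0, 1]]
        assert binarize(np.full((2, 2), 255), 255).sum() == 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 255), st.integers(1, 1000))
    def test_classes_partition_image(self, k, seed):
        img = np.random.default_rng(seed).integers(0, 256, size=(6, 6))
        mask = binarize(img, k)
        h = histogram(img.astype(np.uint8))
        assert int((mask == 0).sum()) == int(h[:k + 1].sum())
        assert int(mask.sum()) == int(h[k + 1:].sum())

    def test_display_round_trip(self, rng):
        mask = (rng.random((5, 8)) > 0.5).astype(np.uint8)
        disp = to_display(mask)
        assert set(np.unique(disp)) <= {0, 255}
        assert np.array_equal(binarize(disp, 128), mask)


class TestParticles:
    def test_two_blocks(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[1:3, 1:3] = 1      # 4 px
        mask[5:8, 5:8] = 1      # 9 px
        ps = label_particles(mask)
        assert ps.n_particles == 2
        assert sorted(ps.counts.tolist()) == [4, 9]

    def test_empty_mask(self):
        ps = label_particles(np.zeros((4, 4), dtype=np.uint8))
        assert ps.n_particles == 0
        assert total_area(ps) == 0

    def test_diagonal_pixels_are_one_particle(self):
        mask = np.eye(5, dtype=np.uint8)
        assert label_particles(mask).n_particles == 1

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(10):
            mask = (rng.random((20, 20)) > 0.6).astype(np.uint8)
            ps = label_particles(mask)
            oracle_labels, u = flood_fill_label(mask)
            assert ps.n_particles == u
            # same partition up to label permutation
            for lab in range(1, u + 1):
                region = oracle_labels == lab
                got = np.unique(ps.labels[region])
                assert got.size == 1 and got[0] > 0

    def test_counts_sum_to_foreground(self, rng):
        mask = (rng.random((30, 30)) > 0.5).astype(np.uint8)
        ps = label_particles(mask)
        assert ps.counts.sum() == mask.sum()


class TestFillHoles:
    def test_ring_center_filled(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[1:4, 1:4] = 1
        mask[2, 2] = 0
        filled = fill_holes(mask)
        assert filled[2, 2] == 1
        assert filled.sum() == 9

    def test_border_stripe_unchanged(self):
        mask = np.ones((5, 5), dtype=np.uint8)
        mask[:, 2] = 0  # background stripe touching the border
        assert np.array_equal(fill_holes(mask), mask)

    def test_matches_border_flood_fill_and_idempotent(self, rng):
        for _ in range(20):
            mask = (rng.random((24, 24)) > 0.55).astype(np.uint8)
            filled = fill_holes(mask)
            assert np.array_equal(filled, border_flood_fill_holes(mask))
            assert np.array_equal(fill_holes(filled), filled)
            # monotone: foreground never shrinks
            assert filled.sum() >= mask.sum()
            assert (filled[mask > 0] == 1).all()

    def test_accepts_particle_set(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[1:4, 1:4] = 1
        mask[2, 2] = 0
        assert fill_holes(label_particles(mask))[2, 2] == 1


class TestFilterAndArea:
    def test_filter_example(self):
        mask = np.zeros((100, 120), dtype=np.uint8)
        mask[5:55, 5:105] = 1            # 5000 px
        mask[70, 0:3] = 1                # 3 px
        mask[80:87, 110] = 1             # 7 px
        ps = filter_particles(label_particles(mask), 100)
        assert ps.counts.tolist() == [5000]
        assert sorted(np.unique(ps.labels).tolist()) == [0, 1]
        assert total_area(ps) == 5000

    def test_min_pixels_zero_is_identity(self, rng):
        mask = (rng.random((15, 15)) > 0.5).astype(np.uint8)
        ps = label_particles(mask)
        out = filter_particles(ps, 0)
        assert np.array_equal(out.labels, ps.labels)

    def test_matches_direct_filter(self, rng):
        for _ in range(10):
            mask = (rng.random((40, 40)) > 0.45).astype(np.uint8)
            thr = int(rng.integers(1, 12))
            ps = label_particles(mask)
            kept = filter_particles(ps, thr)
            expected = sorted(c for c in ps.counts.tolist() if c >= thr)
            assert sorted(kept.counts.tolist()) == expected
            assert total_area(kept) == int(kept.mask.sum())

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_particles(label_particles(np.ones((2, 2), dtype=np.uint8)), -1)


class TestFullChain:
    def test_ideal_disk_area_within_3pct(self):
        for r in (20, 45, 90):
            h = w = 2 * r + 21
            yy, xx = np.ogrid[:h, :w]
            disk = (yy - h // 2) ** 2 + (xx - w // 2) ** 2 <= r * r
            gray = np.where(disk, 210, 25).astype(np.uint8)
            rgb = np.repeat(gray[:, :, None], 3, axis=2)
            seg = segment_frame(rgb, min_pixels=50)
            assert seg.n_particles == 1
            assert seg.area == pytest.approx(np.pi * r * r, rel=0.03)

    def test_flat_frame_is_unsegmentable(self):
        rgb = np.full((8, 8, 3), 40, dtype=np.uint8)
        with pytest.raises(DegenerateHistogramError):
            segment_frame(rgb)

    def test_bubble_and_dust_removed(self):
        gray = np.full((120, 120), 30, dtype=np.uint8)
        yy, xx = np.ogrid[:120, :120]
        disk = (yy - 60) ** 2 + (xx - 60) ** 2 <= 40 * 40
        gray[disk] = 200
        clean = segment_frame(np.repeat(gray[:, :, None], 3, axis=2)).area
        bubble = (yy - 55) ** 2 + (xx - 65) ** 2 <= 6 * 6
        gray[bubble] = 35            # dark bubble inside the sample
        gray[5:8, 5:8] = 190         # 9 px dust speck
        seg = segment_frame(np.repeat(gray[:, :, None], 3, axis=2))
        assert seg.area == clean
        assert seg.n_particles == 1
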