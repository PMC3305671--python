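"""Circle fitting, circular sampling, and wrap-aware run extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mosaicstripes as ms
from mosaicstripes.circular import (
    BACKGROUND,
    NEGATIVE,
    POSITIVE,
    EmptyImageError,
    GeometryError,
    QualityError,
)

from conftest import linear_rle_oracle, profile_from_classes


class TestFitCornealCircle:
    def test_recovers_synthetic_disc_geometry(self):
        ring = ms.simulate_clone_ring(6, 0.5, seed=1)
        cornea = ms.render_cornea(ring, image_size=512, corneal_radius=200,
                                  center=(256.0, 256.0))
        center, radius = ms.fit_corneal_circle(cornea.image)
        assert abs(center[0] - 256.0) < 0.5 and abs(center[1] - 256.0) < 0.5
        assert abs(radius - 200.0) < 1.0

    def test_manual_mode_is_identity(self):
        img = ms.MosaicImage(np.full((10, 10), NEGATIVE, dtype=np.uint8))
        center, radius = ms.fit_corneal_circle(img, mode="manual",
                                               center=(3.5, 4.5), radius=2.0)
        assert center == (3.5, 4.5) and radius == 2.0

    def test_all_background_image_rejected(self):
        img = ms.MosaicImage(np.zeros((20, 20), dtype=np.uint8))
        with pytest.raises(EmptyImageError):
            ms.fit_corneal_circle(img)


class TestSampleCircle:
    def test_half_disc_profile_is_half_positive(self):
        ring = ms.CloneRing(boundaries=np.array([0.0, np.pi]),
                            labels=np.array([1, 0], dtype=np.uint8), p_true=0.5)
        cornea = ms.render_cornea(ring, image_size=256)
        circle = ms.SamplingCircle.at_fraction(cornea.center,
                                               cornea.corneal_radius,
                                               n_samples=720)
        profile = ms.sample_circle(cornea.image, circle)
        assert abs(profile.classes.mean() - 0.5) <= 2 / 720

    def test_run_count_stable_across_resolution(self, rendered_cornea):
        center, radius = ms.fit_corneal_circle(rendered_cornea.image)
        counts = []
        for n_samples in (360, 3600):
            circle = ms.SamplingCircle.at_fraction(center, radius,
                                                   n_samples=n_samples)
            runs = ms.extract_runs(ms.sample_circle(rendered_cornea.image, circle),
                                   min_run_width=0)
            counts.append(len(runs))
        assert counts[0] == counts[1]

    def test_circle_outside_image_rejected(self):
        img = ms.MosaicImage(np.full((64, 64), NEGATIVE, dtype=np.uint8))
        circle = ms.SamplingCircle(center=(32.0, 32.0), radius=60.0, n_samples=360)
        with pytest.raises(GeometryError):
            ms.sample_circle(img, circle)

    def test_background_samples_reclassified_from_nearest_tissue(self):
        # a thin background gouge crossing the circle gets patched over
        px = np.full((128, 128), NEGATIVE, dtype=np.uint8)
        px[:, :64] = POSITIVE
        px[63:66, :] = BACKGROUND  # thin gouge: < 5% of circle samples
        circle = ms.SamplingCircle(center=(64.0, 64.0), radius=40.0, n_samples=360)
        profile = ms.sample_circle(ms.MosaicImage(px), circle)
        assert profile.flagged.sum() > 0
        # flagged samples took the class of nearby tissue, not background
        assert set(np.unique(profile.classes)) <= {0, 1}

    def test_too_much_background_raises_quality_error(self):
        px = np.full((128, 128), BACKGROUND, dtype=np.uint8)
        px[60:68, :] = NEGATIVE  # tissue only on a thin band
        circle = ms.SamplingCircle(center=(64.0, 64.0), radius=40.0, n_samples=360)
        with pytest.raises(QualityError):
            ms.sample_circle(ms.MosaicImage(px), circle)

    def test_rgb_blue_dominance_rule(self):
        rgb = np.zeros((32, 32, 3), dtype=np.uint8)
        rgb[:, :16] = (40, 40, 200)   # X-gal blue -> positive
        rgb[:, 16:] = (200, 120, 110)  # counterstain -> negative
        classes = ms.MosaicImage(rgb).classes()
        assert np.all(classes[:, :16] == POSITIVE)
        assert np.all(classes[:, 16:] == NEGATIVE)


class TestExtractRuns:
    def test_uniform_profile_is_single_full_run(self):
        profile = profile_from_classes(np.ones(360))
        runs = ms.extract_runs(profile)
        assert len(runs) == 1
        assert runs[0].positive and runs[0].width == 1.0

    def test_wrap_spanning_run_reported_once(self):
        # positive on [0, pi/4) and [7pi/4, 2pi): one wrapped positive run
        angles = np.arange(360) * (2 * np.pi / 360)
        classes = ((angles < np.pi / 4) | (angles >= 7 * np.pi / 4)).astype(np.uint8)
        runs = ms.extract_runs(ms.CircularProfile(angles=angles, classes=classes),
                               min_run_width=0)
        assert len(runs) == 2
        widths = {r.positive: r.width for r in runs}
        assert np.isclose(widths[True], 0.25)
        assert np.isclose(widths[False], 0.75)

    def test_matches_linear_scan_oracle_on_random_profiles(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = rng.integers(4, 120)
            classes = (rng.random(n) < rng.uniform(0.1, 0.9)).astype(np.uint8)
            runs = ms.extract_runs(profile_from_classes(classes), min_run_width=0)
            got = sorted((r.positive, round(r.width, 12)) for r in runs)
            want = sorted((c, round(w, 12)) for c, w in linear_rle_oracle(classes))
            assert got == want

    @given(st.lists(st.integers(0, 1), min_size=4, max_size=80))
    @settings(derandomize=True, max_examples=200)
    def test_widths_always_sum_to_one(self, classes):
        runs = ms.extract_runs(profile_from_classes(classes), min_run_width=0)
        assert abs(sum(r.width for r in runs) - 1.0) < 1e-9
        # runs alternate in class around the circle
        for a, b in zip(runs, runs[1:]):
            assert a.positive != b.positive

    @given(st.lists(st.integers(0, 1), min_size=4, max_size=60),
           st.integers(0, 59))
    @settings(derandomize=True, max_examples=200)
    def test_rotation_preserves_run_multiset(self, classes, shift):
        rotated = np.roll(np.asarray(classes, dtype=np.uint8), shift % len(classes))
        a = ms.extract_runs(profile_from_classes(classes), min_run_width=0)
        b = ms.extract_runs(profile_from_classes(rotated), min_run_width=0)
        key = lambda runs: sorted((r.positive, round(r.width, 12)) for r in runs)
        assert key(a) == key(b)

    def test_min_width_filter_is_monotone(self):
        rng = np.random.default_rng(5)
        classes = (rng.random(720) < 0.5).astype(np.uint8)
        profile = profile_from_classes(classes)
        counts = [
            len(ms.extract_runs(profile, min_run_width=w))
            for w in (0.0, 0.002, 0.005, 0.01, 0.05)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_narrow_run_absorbed_into_neighbours(self):
        # 1-sample positive blip inside a negative stretch disappears
        classes = np.zeros(360, dtype=np.uint8)
        classes[100] = 1
        classes[200:260] = 1
        runs = ms.extract_runs(profile_from_classes(classes), min_run_width=3 / 360)
        assert sum(r.positive for r in runs) == 1
        assert abs(sum(r.width for r in runs) - 1.0) < 1e-9


class TestRunsFromRing:
    def test_adjacent_same_label_clones_merge(self):
        ring = ms.CloneRing(
            boundaries=np.array([0.0, 1.0, 2.0, 4.0]),
            labels=np.array([1, 1, 0, 0], dtype=np.uint8),
            p_true=0.5,
        )
        runs = ms.runs_from_ring(ring)
        assert len(runs) == 2
        widths = {r.positive: r.width for r in runs}
        assert np.isclose(widths[True], 2.0 / (2 * np.pi))

    def test_matches_sampled_extraction_on_fine_profile(self):
        ring = ms.simulate_clone_ring(15, 0.5, width_model="dirichlet", seed=8)
        exact = ms.runs_from_ring(ring)
        n = 36_000
        angles = np.arange(n) * (2 * np.pi / n)
        profile = ms.CircularProfile(angles=angles,
                                     classes=ring.label_at(angles).astype(np.uint8))
        sampled = ms.extract_runs(profile, min_run_width=0)
        assert len(exact) == len(sampled)
        a = sorted((r.positive, r.width) for r in exact)
        b = sorted((r.positive, r.width) for r in sampled)
        for (ca, wa), (cb, wb) in zip(a, b):
            assert ca == cb and abs(wa - wb) < 2 / n
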