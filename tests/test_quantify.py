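"""Tracer quantification: thresholding, spot labelling, association, reports."""

import numpy as np
import pytest

from tjperm.datatypes import JunctionSet
from tjperm.quantify import (
    ThresholdParams,
    adaptive_threshold,
    associate,
    compute_report,
    label_spots,
    quantify_image,
    total_accumulation,
)
from tjperm.synthetic import FieldSpec, TracerParams, generate_tessellation, render_tracer_channel


def spot_image(shape=(512, 512), centres=((130, 140), (390, 380)), amp=0.7, sigma=2.0,
               background=0.1):
    img = np.full(shape, background)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for x, y in centres:
        img += amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
    return img


class TestAdaptiveThreshold:
    def test_constant_image_empty_foreground(self):
        assert not adaptive_threshold(np.full((64, 64), 0.4)).any()
        assert not adaptive_threshold(np.zeros((64, 64))).any()

    @pytest.mark.parametrize("sensitivity", [0.1, 0.5, 0.9])
    def test_single_bright_pixel_detected(self, sensitivity):
        img = np.zeros((64, 64))
        img[30, 30] = 1.0
        fg = adaptive_threshold(img, ThresholdParams(sensitivity=sensitivity))
        assert fg[30, 30]

    def test_spots_covered_background_clean(self):
        img = spot_image(amp=0.7, sigma=2.0, background=0.1)
        fg = adaptive_threshold(img)
        # half-maximum support of each spot: distance <= sigma*sqrt(2 ln 2)
        yy, xx = np.mgrid[:512, :512]
        half_r = 2.0 * np.sqrt(2 * np.log(2))
        support = np.zeros_like(fg)
        for x, y in ((130, 140), (390, 380)):
            support |= (xx - x) ** 2 + (yy - y) ** 2 <= half_r**2
        assert fg[support].mean() >= 0.90
        far = ~support & (
            (np.hypot(xx - 130, yy - 140) > 15) & (np.hypot(xx - 390, yy - 380) > 15)
        )
        assert fg[far].mean() < 0.01

    def test_rule_matches_independent_evaluation(self):
        # recompute the documented rule directly: v > local_gauss_mean * (1 + k)
        from scipy.ndimage import gaussian_filter

        img = spot_image()
        params = ThresholdParams(neighbourhood_px=15, sensitivity=0.5)
        fg = adaptive_threshold(img, params)
        expected = img > gaussian_filter(img, 15 / 6.0, mode="reflect") * 2.0
        np.testing.assert_array_equal(fg, expected)

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            ThresholdParams(neighbourhood_px=4)
        with pytest.raises(ValueError):
            ThresholdParams(sensitivity=1.5)


class TestTotalAccumulation:
    def test_empty_foreground_zero(self):
        assert total_accumulation(np.ones((10, 10)), np.zeros((10, 10), bool)) == 0.0

    def test_all_foreground_sums_everything(self):
        assert total_accumulation(np.ones((10, 10)), np.ones((10, 10), bool)) == 100.0

    def test_matches_spot_integral_oracle(self):
        img = spot_image(background=0.0)
        fg = img > 1e-6
        # direct discrete Gaussian sums over their supports
        expected = img[fg].sum()
        assert total_accumulation(img, fg) == pytest.approx(expected)


class TestLabelSpots:
    def test_two_separated_blobs(self):
        fg = np.zeros((32, 32), bool)
        fg[4:6, 4:6] = True
        fg[20:22, 20:22] = True
        spots = label_spots(fg, np.ones((32, 32)))
        assert len(spots) == 2
        assert sorted(len(p) for p in spots.pixels) == [4, 4]
        np.testing.assert_allclose(spots.intensities, [4.0, 4.0])

    def test_diagonal_touch_is_one_spot(self):
        fg = np.zeros((16, 16), bool)
        fg[4, 4] = True
        fg[5, 5] = True
        assert len(label_spots(fg, np.ones((16, 16)))) == 1

    def test_empty_foreground_empty_spotset(self):
        assert len(label_spots(np.zeros((8, 8), bool), np.zeros((8, 8)))) == 0

    def test_generated_spots_recovered_with_truth_intensities(self):
        tess = generate_tessellation(FieldSpec(512, 512, 100, rng_seed=21), 2)
        params = TracerParams(permeable_fraction=0.25, background_level=0.0,
                              background_noise_sd=0.0, n_offjunction_spots=5)
        img, truth = render_tracer_channel(tess, params, rng_seed=4)
        fg = img > 1e-4
        spots = label_spots(fg, img)
        # may merge a couple of close junctions; require near-exhaustive match
        assert abs(len(spots) - len(truth.spots)) <= 2
        assert spots.intensities.sum() == pytest.approx(
            truth.total_signal, rel=0.01
        )


class TestAssociate:
    def _spotset(self, pixel_lists):
        from tjperm.datatypes import SpotSet

        return SpotSet(
            pixels=[np.asarray(p) for p in pixel_lists],
            intensities=np.ones(len(pixel_lists)),
            centroids=np.array(
                [np.mean(np.asarray(p)[:, ::-1], axis=0) for p in pixel_lists]
            ),
        )

    def test_sqrt2_distance_is_permeable(self):
        junctions = JunctionSet([[10.0, 10.0]])
        spots = self._spotset([[(11, 11)]])          # pixel (row=11, col=11)
        flags, assignment = associate(junctions, spots, 2.0)
        assert flags[0]
        assert assignment == [0]

    def test_three_pixels_away_is_not_permeable(self):
        junctions = JunctionSet([[10.0, 10.0]])
        spots = self._spotset([[(10, 13)]])          # distance 3 in x
        flags, assignment = associate(junctions, spots, 2.0)
        assert not flags[0]
        assert assignment == [None]

    def test_boundary_distance_inclusive(self):
        junctions = JunctionSet([[10.0, 10.0]])
        spots = self._spotset([[(10, 12)]])          # exactly 2.0
        flags, _ = associate(junctions, spots, 2.0)
        assert flags[0]

    def test_spot_near_two_junctions_assigned_to_nearest_only(self):
        junctions = JunctionSet([[10.0, 10.0], [16.0, 10.0]])
        # spot spans pixels so both junctions are within 2 px of some pixel,
        # but the nearest distance favours junction 0
        spots = self._spotset([[(10, 11), (10, 12), (10, 13), (10, 14)]])
        flags, assignment = associate(junctions, spots, 2.0)
        assert flags.tolist() == [True, True]
        assert assignment == [0]
        # brute-force check of the rule
        d0 = min(np.hypot(c - 10.0, r - 10.0) for r, c in spots.pixels[0])
        d1 = min(np.hypot(c - 16.0, r - 10.0) for r, c in spots.pixels[0])
        assert d0 < d1 and d1 <= 2.0

    def test_tie_goes_to_lowest_index(self):
        junctions = JunctionSet([[8.0, 10.0], [12.0, 10.0]])
        spots = self._spotset([[(10, 10)]])          # equidistant (2.0 / 2.0)
        flags, assignment = associate(junctions, spots, 2.0)
        assert flags.all()
        assert assignment == [0]


class TestComputeReport:
    def test_fraction_arithmetic(self):
        tess = generate_tessellation(FieldSpec(512, 512, 60, rng_seed=2), 2)
        n = len(tess.vertices)
        junctions = JunctionSet(tess.vertices)
        flags = np.zeros(n, bool)
        flags[:38] = True
        from tjperm.datatypes import SpotSet

        spots = SpotSet(pixels=[], intensities=np.empty(0), centroids=np.empty((0, 2)))
        report = compute_report(junctions, spots, flags, [], np.zeros((8, 8)),
                                np.zeros((8, 8), bool))
        assert report.fraction_permeable == pytest.approx(38 / n)

    def test_all_spots_assigned_gives_unit_tj_fraction(self):
        img = spot_image(background=0.0, centres=((30, 40),))
        fg = img > 1e-6
        spots = label_spots(fg, img)
        junctions = JunctionSet([[30.0, 40.0]])
        flags, assignment = associate(junctions, spots, 2.0)
        report = compute_report(junctions, spots, flags, assignment, img, fg)
        assert report.tj_fraction == pytest.approx(1.0)
        assert report.mean_per_permeable == pytest.approx(report.tj_accumulation)

    def test_zero_junctions_rejected(self):
        from tjperm.datatypes import SpotSet

        spots = SpotSet(pixels=[], intensities=np.empty(0), centroids=np.empty((0, 2)))
        with pytest.raises(ValueError, match="unanalysable"):
            compute_report(JunctionSet(np.empty((0, 2))), spots, np.empty(0, bool),
                           [], np.zeros((8, 8)), np.zeros((8, 8), bool))

    def test_mean_per_permeable_nan_when_none(self):
        junctions = JunctionSet([[5.0, 5.0]])
        from tjperm.datatypes import SpotSet

        spots = SpotSet(pixels=[], intensities=np.empty(0), centroids=np.empty((0, 2)))
        report = compute_report(junctions, spots, np.zeros(1, bool), [],
                                np.zeros((8, 8)), np.zeros((8, 8), bool))
        assert np.isnan(report.mean_per_permeable)
        assert report.tj_fraction == 0.0


class TestPipelineProperties:
    def test_preset_image_recovers_ground_truth(self):
        tess = generate_tessellation(FieldSpec(512, 512, 100, rng_seed=31), 2)
        params = TracerParams(permeable_fraction=0.381, tj_signal_share=0.85)
        img, truth = render_tracer_channel(tess, params, rng_seed=6)
        report, *_ = quantify_image(img, truth.junctions)
        assert abs(report.fraction_permeable - truth.fraction_permeable) <= 0.05
        assert abs(report.tj_fraction - truth.tj_signal_share) <= 0.05
        assert report.tj_accumulation <= report.total_accumulation

    def test_report_is_rotation_invariant(self):
        tess = generate_tessellation(FieldSpec(256, 256, 40, rng_seed=17), 2)
        params = TracerParams(permeable_fraction=0.4)
        img, truth = render_tracer_channel(tess, params, rng_seed=9)
        report, *_ = quantify_image(img, truth.junctions)
        w = tess.field.width_px - 1.0
        rot_junctions = JunctionSet(
            np.column_stack([truth.junctions.coords[:, 1], w - truth.junctions.coords[:, 0]])
        )
        rot_report, *_ = quantify_image(np.rot90(img), rot_junctions)
        assert rot_report.n_permeable == report.n_permeable
        assert rot_report.total_accumulation == pytest.approx(
            report.total_accumulation, abs=1e-9
        )
        assert rot_report.tj_accumulation == pytest.approx(
            report.tj_accumulation, abs=1e-9
        )

    def test_reports_are_deterministic(self):
        tess = generate_tessellation(FieldSpec(256, 256, 40, rng_seed=18), 2)
        img, truth = render_tracer_channel(tess, TracerParams(), rng_seed=3)
        r1, *_ = quantify_image(img, truth.junctions)
        r2, *_ = quantify_image(img, truth.junctions)
        assert r1.to_dict() == r2.to_dict()
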