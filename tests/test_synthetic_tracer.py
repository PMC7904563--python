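"""Tracer-channel generation: ground truth, presets, time series, diffusion."""


import numpy as np
import pytest

from tjperm.synthetic import (
    CONDITION_PRESETS,
    FieldSpec,
    TimeSeriesParams,
    TracerParams,
    condition_preset,
    free_diffusion_radius,
    generate_tessellation,
    generate_timeseries,
    render_tracer_channel,
    sample_opening_frames,
)


@pytest.fixture(scope="module")
def tess100():
    """~165 junctions, enough for share statistics."""
    return generate_tessellation(FieldSpec(512, 512, 100, rng_seed=3), relaxation_steps=2)


def discrete_spot_sum(shape, x, y, sigma, amplitude):
    """Independent direct summation of a generated spot's pixel integral."""
    h, w = shape
    ext = int(np.ceil(5 * sigma))
    r0, r1 = max(int(np.floor(y)) - ext, 0), min(int(np.ceil(y)) + ext, h - 1)
    c0, c1 = max(int(np.floor(x)) - ext, 0), min(int(np.ceil(x)) + ext, w - 1)
    total = 0.0
    for r in range(r0, r1 + 1):
        for c in range(c0, c1 + 1):
            total += amplitude * np.exp(-((c - x) ** 2 + (r - y) ** 2) / (2 * sigma**2))
    return total


def test_zero_permeable_fraction_gives_flat_background(tess100):
    params = TracerParams(permeable_fraction=0.0, tj_signal_share=0.0,
                          n_offjunction_spots=0, background_noise_sd=0.0)
    img, truth = render_tracer_channel(tess100, params, rng_seed=0)
    assert np.all(img == params.background_level)
    assert truth.n_permeable == 0


def test_all_signal_at_junctions_when_no_off_spots(tess100):
    params = TracerParams(permeable_fraction=1.0, n_offjunction_spots=0)
    _, truth = render_tracer_channel(tess100, params, rng_seed=0)
    assert truth.tj_signal_share == 1.0
    assert truth.fraction_permeable == 1.0


def test_realised_share_matches_setpoint_and_direct_summation(tess100):
    params = TracerParams(permeable_fraction=0.4, tj_signal_share=0.5,
                          n_offjunction_spots=40)
    img, truth = render_tracer_channel(tess100, params, rng_seed=5)
    assert abs(truth.tj_signal_share - 0.5) <= 0.05
    # recompute the share from per-spot parameters by direct summation
    shape = tess100.field.shape
    tj = sum(
        discrete_spot_sum(shape, sp.x, sp.y, sp.sigma, sp.amplitude)
        for sp in truth.spots
        if sp.junction_index is not None
    )
    tot = sum(
        discrete_spot_sum(shape, sp.x, sp.y, sp.sigma, sp.amplitude)
        for sp in truth.spots
    )
    assert abs(tj / tot - truth.tj_signal_share) < 1e-9


def test_realised_permeable_count_is_exact_round(tess100):
    n_j = len(tess100.vertices)
    for pf in (0.2, 0.381, 0.6):
        _, truth = render_tracer_channel(
            tess100, TracerParams(permeable_fraction=pf), rng_seed=1
        )
        assert truth.n_permeable == int(np.floor(pf * n_j + 0.5))


def test_every_permeable_junction_has_spot_within_2px(tess100):
    _, truth = render_tracer_channel(
        tess100, TracerParams(permeable_fraction=0.5), rng_seed=2
    )
    coords = truth.junctions.coords
    for sp in truth.spots:
        if sp.junction_index is not None:
            d = np.hypot(*(coords[sp.junction_index] - [sp.x, sp.y]))
            assert d <= 2.0


def test_offjunction_spots_respect_clearance(tess100):
    _, truth = render_tracer_channel(
        tess100, TracerParams(permeable_fraction=0.4, n_offjunction_spots=30), rng_seed=3
    )
    coords = truth.junctions.coords
    for sp in truth.spots:
        if sp.junction_index is None:
            d = np.hypot(coords[:, 0] - sp.x, coords[:, 1] - sp.y).min()
            assert d > 5.0


def test_tracer_bit_reproducible(tess100):
    params = condition_preset("untreated")
    a, _ = render_tracer_channel(tess100, params, rng_seed=9)
    b, _ = render_tracer_channel(tess100, params, rng_seed=9)
    np.testing.assert_array_equal(a, b)


def test_zero_permeable_warns_when_share_positive():
    tess = generate_tessellation(FieldSpec(128, 128, 4, rng_seed=2), relaxation_steps=0)
    params = TracerParams(permeable_fraction=0.05, tj_signal_share=0.85,
                          n_offjunction_spots=5)
    with pytest.warns(UserWarning, match="zero permeable"):
        _, truth = render_tracer_channel(tess, params, rng_seed=0)
    assert truth.n_permeable == 0


class TestPresets:
    def test_setpoints(self):
        assert condition_preset("untreated").permeable_fraction == 0.381
        assert condition_preset("s1p").permeable_fraction == 0.203
        thrombin = condition_preset("thrombin")
        untreated = condition_preset("untreated")
        assert thrombin.permeable_fraction == 0.473
        assert thrombin.spot_amplitude_mean == pytest.approx(
            1.25 * untreated.spot_amplitude_mean
        )
        assert condition_preset("multidirectional").permeable_fraction == 0.407
        uniaxial = condition_preset("uniaxial")
        assert uniaxial.permeable_fraction == 0.289
        assert uniaxial.spot_amplitude_mean == pytest.approx(
            0.69 * untreated.spot_amplitude_mean
        )

    def test_share_band(self):
        for name in CONDITION_PRESETS:
            assert 0.80 <= condition_preset(name).tj_signal_share <= 0.87

    def test_unknown_name_lists_valid_ones(self):
        with pytest.raises(ValueError, match="untreated"):
            condition_preset("nonsense")


@pytest.fixture(scope="module")
def tess():
    return generate_tessellation(FieldSpec(256, 256, 30, rng_seed=4), relaxation_steps=1)


class TestTimeSeries:
    def test_all_open_at_start_constant_count_growing_integrals(self, tess):
        ts = TimeSeriesParams(n_frames=6, spot_growth_rate=0.3,
                              junction_opening_rate=0.0, initial_open=True)
        params = TracerParams(permeable_fraction=0.4, background_noise_sd=0.0)
        frames, truth = generate_timeseries(tess, params, ts, rng_seed=0)
        assert np.all(truth.spot_counts == truth.spot_counts[0])
        diffs = np.diff(truth.spot_integrals, axis=0)
        assert np.all(diffs >= -1e-12)
        # total above-background intensity nondecreasing
        totals = [f.sum() - params.background_level * f.size for f in frames]
        assert np.all(np.diff(totals) >= -1e-9)

    def test_rate_one_opens_all_by_frame_one(self, tess):
        ts = TimeSeriesParams(n_frames=4, junction_opening_rate=1.0)
        params = TracerParams(permeable_fraction=0.5, background_noise_sd=0.0)
        _, truth = generate_timeseries(tess, params, ts, rng_seed=1)
        assert np.all(truth.open_frame == 1)
        assert truth.spot_counts[0] == 0

    def test_spot_radii_nondecreasing(self, tess):
        ts = TimeSeriesParams(n_frames=8, junction_opening_rate=0.4)
        params = TracerParams(permeable_fraction=0.5, background_noise_sd=0.0)
        _, truth = generate_timeseries(tess, params, ts, rng_seed=2)
        diffs = np.diff(truth.spot_sigmas, axis=0)
        assert np.all((diffs >= -1e-12) | np.isnan(diffs))

    def test_opening_schedule_matches_closed_form_expectation(self):
        # cumulative open count: E[open by frame k] = n * (1 - (1-rate)^k)
        n, rate, frames = 100, 0.3, 10
        counts = np.zeros(frames)
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            of = sample_opening_frames(n, rate, frames, rng)
            for k in range(frames):
                counts[k] += np.sum((of >= 0) & (of <= k))
        counts /= n_rep
        expected = n * (1 - (1 - rate) ** np.arange(frames))
        np.testing.assert_allclose(counts, expected, atol=2.0)

    def test_opening_replay_deterministic(self):
        rng1 = np.random.default_rng(42)
        rng2 = np.random.default_rng(42)
        a = sample_opening_frames(50, 0.3, 10, rng1)
        b = sample_opening_frames(50, 0.3, 10, rng2)
        np.testing.assert_array_equal(a, b)


class TestFreeDiffusion:
    def test_unit_cases(self):
        assert free_diffusion_radius(1.0, 1.0) == pytest.approx(2.0)
        assert free_diffusion_radius(0.25, 1.0) == pytest.approx(1.0)

    def test_illustrative_tracer_reaches_350um_scale_in_12min(self):
        # D = 4.2e-7 cm^2/s for 720 s -> ~348 um: free diffusion would spread
        # a spot to ~350 um, far beyond observed bound-spot growth
        r_cm = free_diffusion_radius(4.2e-7, 720.0)
        assert r_cm * 1e4 == pytest.approx(348, abs=1)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            free_diffusion_radius(0.0, 10.0)
        with pytest.raises(ValueError):
            free_diffusion_radius(1.0, -1.0)
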