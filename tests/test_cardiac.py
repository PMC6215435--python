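import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import zfcardio as z
from zfcardio.cardiac import _complete_beats
from zfcardio.errors import (
    DegenerateRegionError,
    GeometryError,
    NoBeatError,
    NoObjectError,
)


def _disc_mask(shape, centre, radius):
    rr = np.arange(shape[0])[:, None] - centre[0]
    cc = np.arange(shape[1])[None, :] - centre[1]
    return rr**2 + cc**2 <= radius**2


def _dice(a, b):
    return 2 * (a & b).sum() / (a.sum() + b.sum())


class TestSegmentVentricle:
    def test_noiseless_frame_matches_generator_mask(self, clean_heart_video):
        _, video, gt = clean_heart_video
        m = z.segment_ventricle(video.frames[0])
        assert _dice(m.mask, gt.mask(0)) >= 0.98

    def test_noisy_frame_dice(self, heart_video):
        p, video, gt = heart_video
        # noise s.d. 6 ≈ 4% of the 150-unit object/background contrast
        m = z.segment_ventricle(video.frames[0])
        assert _dice(m.mask, gt.mask(0)) >= 0.95

    def test_blank_frame_raises(self):
        with pytest.raises(NoObjectError):
            z.segment_ventricle(np.full((32, 32), 17, dtype=np.uint8))

    def test_dark_polarity_mirror(self, clean_heart_video):
        _, video, gt = clean_heart_video
        inverted = 255 - video.frames[0]
        m = z.segment_ventricle(inverted, z.SegmentationSettings(polarity="dark"))
        assert _dice(m.mask, gt.mask(0)) >= 0.98

    def test_largest_component_kept(self):
        img = np.full((64, 64), 10, dtype=np.uint8)
        img[_disc_mask((64, 64), (32, 32), 15)] = 200
        img[2:5, 2:5] = 200  # small distractor
        m = z.segment_ventricle(img)
        assert not m.mask[3, 3]
        assert m.pixel_count == pytest.approx(math.pi * 15**2, rel=0.05)


class TestFitEllipse:
    def test_disc_axes_and_orientation_tiebreak(self):
        mask = _disc_mask((128, 128), (64, 64), 50)
        fit = z.fit_ellipse(mask, pixel_size=1.0)
        assert fit.a == pytest.approx(100, rel=0.02)
        assert fit.b == pytest.approx(100, rel=0.02)
        assert fit.theta == 0.0
        assert fit.centre == pytest.approx((64, 64))

    @pytest.mark.parametrize("theta_deg", [0, 30, 75, 120])
    def test_rotated_ellipse_recovery(self, theta_deg):
        from zfcardio.simulate import _ellipse_mask

        theta = math.radians(theta_deg)
        mask = _ellipse_mask((256, 256), (127.5, 127.5), 50, 25, theta)
        fit = z.fit_ellipse(mask, pixel_size=1.0)
        assert fit.a == pytest.approx(100, rel=0.02)
        assert fit.b == pytest.approx(50, rel=0.02)
        err = abs(fit.theta - theta % math.pi)
        assert min(err, math.pi - err) < math.radians(2)

    def test_area_consistency(self, clean_heart_video):
        # equal-moments convention: π·a·b/4 reproduces the calibrated mask area
        _, video, _ = clean_heart_video
        m = z.segment_ventricle(video.frames[0])
        fit = z.fit_ellipse(m, video.pixel_size)
        assert math.pi * fit.a * fit.b / 4 == pytest.approx(
            m.pixel_count * video.pixel_size**2, rel=0.02
        )

    def test_calibration_scales_axes(self):
        mask = _disc_mask((64, 64), (32, 32), 20)
        f1 = z.fit_ellipse(mask, pixel_size=1.0)
        f2 = z.fit_ellipse(mask, pixel_size=0.5)
        assert f2.a == pytest.approx(f1.a / 2)

    def test_degenerate_masks_rejected(self):
        with pytest.raises(DegenerateRegionError):
            z.fit_ellipse(np.zeros((8, 8), dtype=bool), 1.0)  # < 5 px
        line = np.zeros((16, 16), dtype=bool)
        line[8, 2:14] = True
        with pytest.raises(DegenerateRegionError):
            z.fit_ellipse(line, 1.0)


class TestBeatDetection:
    def test_pure_cosine_series_finds_all_diastoles(self):
        # 3 Hz raised cosine, 10 s at 150 fps → 30 diastoles, 30 systoles
        t = np.arange(1500) / 150.0
        area = 3000 + 500 * np.cos(2 * math.pi * 3 * t)
        series = z.BeatSeries(areas=area, long_axes=np.sqrt(area), short_axes=np.sqrt(area) / 2)
        out = z.detect_beats(series, fps=150.0)
        assert len(out.diastole_idx) == 30
        assert len(out.systole_idx) == 30
        # alternation
        merged = np.sort(np.concatenate([out.diastole_idx, out.systole_idx]))
        kinds = np.isin(merged, out.diastole_idx)
        assert np.all(kinds[:-1] != kinds[1:])

    def test_constant_series_raises(self):
        series = z.BeatSeries(areas=np.full(600, 100.0), long_axes=np.full(600, 10.0),
                              short_axes=np.full(600, 10.0))
        with pytest.raises(NoBeatError):
            z.detect_beats(series, fps=150.0)

    def test_simulated_series_beat_count(self, heart_video):
        p, video, _ = heart_video
        series = z.detect_beats(z.area_series(video), fps=p.fps)
        expected = int(p.duration * p.heart_rate / 60)
        n_beats = len(_complete_beats(series.diastole_idx, series.systole_idx))
        assert abs(n_beats - (expected - 1)) <= 1  # last diastole lies at the clip edge


class TestHeartRate:
    def test_three_beat_window(self):
        series = z.BeatSeries(
            areas=np.zeros(1), long_axes=np.zeros(1), short_axes=np.zeros(1),
            diastole_idx=np.array([0, 50, 100, 150]), systole_idx=np.array([25, 75, 125]),
        )
        assert z.heart_rate(series, fps=150.0) == pytest.approx(180.0)

    def test_half_second_period_gives_120(self):
        series = z.BeatSeries(
            areas=np.zeros(1), long_axes=np.zeros(1), short_axes=np.zeros(1),
            diastole_idx=np.array([10, 85, 160, 235]), systole_idx=np.array([40, 120, 200]),
        )
        assert z.heart_rate(series, fps=150.0) == pytest.approx(120.0)

    def test_too_few_diastoles(self):
        series = z.BeatSeries(areas=np.zeros(1), long_axes=np.zeros(1), short_axes=np.zeros(1),
                              diastole_idx=np.array([0, 50, 100]))
        with pytest.raises(NoBeatError):
            z.heart_rate(series, fps=150.0)

    def test_recovery_within_quantisation(self):
        p = z.HeartSimParams(image_shape=(96, 96), pixel_size=2.0, duration=2.4,
                             heart_rate=150.0, noise_sd=6.0, seed=13)
        video, gt = z.simulate_heart_video(p)
        rep = z.cardiac_report(video)
        assert abs(rep.hr_bpm - gt.hr_bpm) <= 3.0


class TestEllipsoidVolume:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (2.0, 1.0, 4 / 3 * math.pi * 0.25),       # 1.0472
            (2.0, 2.0, 4 / 3 * math.pi),              # sphere of diameter 2
            (120.0, 80.0, 402123.8596594935),
        ],
    )
    def test_formula(self, a, b, expected):
        assert z.ellipsoid_volume(a, b) == pytest.approx(expected, rel=1e-9)

    def test_rejects_bad_axes(self):
        with pytest.raises(ValueError):
            z.ellipsoid_volume(0.0, 0.0)
        with pytest.raises(ValueError):
            z.ellipsoid_volume(1.0, 2.0)

    @given(
        a=st.floats(1.0, 500.0),
        b=st.floats(1.0, 500.0),
        k=st.floats(1.01, 3.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_scaling_laws(self, a, b, k):
        a, b = max(a, b), min(a, b)
        v = z.ellipsoid_volume(a, b)
        # linear in the long axis, quadratic in the short axis
        assert z.ellipsoid_volume(a * k, b) == pytest.approx(v * k, rel=1e-9)
        if b * k <= a:
            assert z.ellipsoid_volume(a, b * k) == pytest.approx(v * k**2, rel=1e-9)


class TestCardiacReport:
    def test_no_contraction_gives_zero_function(self):
        p = z.HeartSimParams(a_d=100, b_d=60, a_s=100, b_s=60,
                             image_shape=(96, 96), pixel_size=2.0, duration=1.0, noise_sd=0)
        video, _ = z.simulate_heart_video(p)
        rep = z.cardiac_report(video)
        assert rep.flat_series
        assert rep.sv == 0 and rep.co == 0
        assert rep.sf_pct == 0 and rep.ef_pct == 0 and rep.fac_pct == 0

    def test_recovery_against_ground_truth(self, heart_video):
        p, video, gt = heart_video
        rep = z.cardiac_report(video)
        assert rep.edv == pytest.approx(gt.edv, rel=0.05)
        assert rep.esv == pytest.approx(gt.esv, rel=0.05)
        assert rep.co == pytest.approx(gt.co, rel=0.07)
        assert abs(rep.sf_pct - gt.sf_pct) <= 2.0

    def test_definitional_invariants(self, heart_video):
        _, video, _ = heart_video
        rep = z.cardiac_report(video)
        per_beat_sv = np.subtract(rep.edv_per_beat, rep.esv_per_beat)
        assert rep.sv == pytest.approx(per_beat_sv.mean(), rel=1e-12)
        assert rep.co == pytest.approx(rep.hr_bpm * rep.sv * 1e-6, rel=1e-12)
        assert rep.ef_pct == pytest.approx(rep.sv / rep.edv * 100, rel=1e-12)
        assert rep.edv >= rep.esv >= 0
        assert 0 <= rep.ef_pct <= 100 and 0 <= rep.sf_pct <= 100
        assert rep.n_beats_used == 3 and len(rep.edv_per_beat) == 3


class TestMorphometrics:
    def test_edema_area_subtracts_ventricle(self):
        frame = np.zeros((100, 100), dtype=np.uint8)
        # square pericardial outline 70×70, disc ventricle inside
        poly = np.array([(10, 10), (10, 80), (80, 80), (80, 10)], dtype=float)
        vent = _disc_mask((100, 100), (45, 45), 20)
        area = z.pericardial_edema_area(frame, poly, vent, pixel_size=1.0)
        # rows/cols 10..80 inclusive rasterise to a 71×71 square
        assert area == pytest.approx(71 * 71 - vent.sum(), rel=0.01)

    def test_ventricle_filling_polygon_gives_zero(self):
        from skimage.draw import polygon2mask

        frame = np.zeros((60, 60), dtype=np.uint8)
        poly = np.array([(5, 5), (5, 50), (50, 50), (50, 5)], dtype=float)
        vent = polygon2mask((60, 60), poly)
        assert z.pericardial_edema_area(frame, poly, vent, 1.0) == 0.0

    def test_annulus_fixture(self):
        # pericardium = disc r=30, ventricle = disc r=15 → annulus area
        frame = np.zeros((100, 100), dtype=np.uint8)
        angles = np.linspace(0, 2 * math.pi, 400, endpoint=False)
        poly = np.column_stack([50 + 30 * np.sin(angles), 50 + 30 * np.cos(angles)])
        vent = _disc_mask((100, 100), (50, 50), 15)
        area = z.pericardial_edema_area(frame, poly, vent, pixel_size=1.0)
        # half-pixel rasterisation rim on both circles → a few percent
        assert area == pytest.approx(math.pi * (30**2 - 15**2), rel=0.03)

    def test_ventricle_outside_polygon_rejected(self):
        frame = np.zeros((60, 60), dtype=np.uint8)
        poly = np.array([(5, 5), (5, 20), (20, 20), (20, 5)], dtype=float)
        vent = _disc_mask((60, 60), (40, 40), 10)
        with pytest.raises(GeometryError):
            z.pericardial_edema_area(frame, poly, vent, 1.0)

    @pytest.mark.parametrize(
        "p1,p2,px,expected",
        [((0, 0), (3, 4), 1.0, 5.0), ((2, 2), (2, 2), 1.0, 0.0), ((0, 0), (3, 4), 0.5, 2.5)],
    )
    def test_linear_measure(self, p1, p2, px, expected):
        assert z.linear_measure(p1, p2, px) == pytest.approx(expected)


class TestAreaSeries:
    def test_matches_per_frame_operations(self, heart_video):
        p, video, _ = heart_video
        short = z.VideoSequence(video.frames[:5], video.fps, video.pixel_size)
        series = z.area_series(short)
        for t in range(5):
            m = z.segment_ventricle(video.frames[t])
            fit = z.fit_ellipse(m, video.pixel_size)
            assert series.areas[t] == pytest.approx(m.pixel_count * video.pixel_size**2, abs=1e-9)
            assert series.long_axes[t] == pytest.approx(fit.a, abs=1e-9)
            assert series.short_axes[t] == pytest.approx(fit.b, abs=1e-9)

    def test_constant_axes_give_constant_areas(self):
        p = z.HeartSimParams(a_d=100, b_d=60, a_s=100, b_s=60,
                             image_shape=(96, 96), pixel_size=2.0, duration=0.5, noise_sd=0)
        video, _ = z.simulate_heart_video(p)
        series = z.area_series(video)
        assert np.ptp(series.areas) / series.areas.mean() < 0.01

    def test_single_frame_video(self, clean_heart_video):
        _, video, _ = clean_heart_video
        one = z.VideoSequence(video.frames[:1], video.fps, video.pixel_size)
        assert len(z.area_series(one).areas) == 1

    def test_failing_frame_index_reported(self):
        frames = np.full((3, 32, 32), 50, dtype=np.uint8)
        frames[0, 10:20, 10:20] = 200
        frames[2, 10:20, 10:20] = 200  # frame 1 is blank
        video = z.VideoSequence(frames, fps=150, pixel_size=1.0)
        with pytest.raises(NoObjectError, match="frame 1"):
            z.area_series(video)
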