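"""Contraction-metric pipeline: thresholding, segmentation, CT definitions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coldtrace as ct
from coldtrace.behavior import PercentTrace
from coldtrace.errors import (DegenerateImageError, EmptyCohortError,
                              ParameterError)
from oracles import li_oracle, triangle_oracle

from coldtrace.thresholds import image_histogram


def make_percent_trace(values, frame_rate=30.0, onset=0.0):
    values = np.asarray(values, dtype=float)
    times = np.arange(values.size) / frame_rate
    return PercentTrace(times=times, values=values, reference_area=1000.0,
                        onset=onset, frame_rate=frame_rate)


class TestBinarize:
    def test_separated_bimodal_selects_bright_mode(self):
        rng = np.random.default_rng(0)
        img = np.zeros((100, 100), dtype=np.uint8)
        bright = rng.random((100, 100)) < 0.1
        img[bright] = 200
        for method in ("triangle", "li"):
            mask, thr = ct.binarize_frame(img, method)
            assert 0 < thr < 200
            assert np.array_equal(mask, bright)

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateImageError):
            ct.binarize_frame(np.full((10, 10), 7.0))

    @pytest.mark.parametrize("method,oracle", [("triangle", triangle_oracle),
                                               ("li", li_oracle)])
    def test_threshold_equals_exhaustive_search(self, method, oracle):
        """Two-Gaussian-mixture 8-bit images: the selected threshold equals a
        brute-force search over all 256 candidates of the method criterion."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            img = _mixture_image(rng)
            _, thr = ct.binarize_frame(img, method)
            hist, centers = image_histogram(img)
            assert thr == oracle(hist, centers)


def _mixture_image(rng):
    n_bg = rng.integers(3000, 8000)
    n_fg = rng.integers(300, 3000)
    bg = rng.normal(rng.uniform(30, 80), rng.uniform(5, 15), n_bg)
    fg = rng.normal(rng.uniform(140, 220), rng.uniform(5, 20), n_fg)
    img = np.clip(np.concatenate([bg, fg]), 0, 255).astype(np.uint8)
    side = int(np.sqrt(img.size))
    return img[: side * side].reshape(side, side)


class TestSegmentation:
    def test_two_ellipse_centroids_recovered(self):
        trs = [ct.simulate_area_trace(responder=False, noise_sd=0.0,
                                      total_s=0.3, frame_rate=10)
               for _ in range(2)]
        positions = [(150.0, 160.0), (430.0, 440.0)]
        frames, _ = ct.simulate_larva_frames(trs, arena=(600, 600),
                                             positions=positions)
        clips = ct.segment_larvae(frames, frame_rate=10)
        found = sorted(c.center for c in clips)
        for (cy, cx), (ty, tx) in zip(found, sorted(positions)):
            assert abs(cy - ty) <= 1 and abs(cx - tx) <= 1

    def test_small_blob_excluded(self):
        frame = np.zeros((300, 300))
        frame[100:102, 100:102] = 200    # 4 px, below filter
        frame[200:220, 200:240] = 200    # 800 px
        clips = ct.segment_larvae(frame[None], min_area=100, frame_rate=10)
        assert len(clips) == 1

    def test_no_component_passing_filter_gives_empty_list(self):
        frame = np.zeros((100, 100))
        frame[50, 50] = 200.0
        assert ct.segment_larvae(frame[None], min_area=50, frame_rate=10) == []

    def test_measured_areas_match_ground_truth(self):
        """Three noise-free larvae: per-clip areas within 2% of the
        rasterized truth."""
        trs = [ct.simulate_area_trace(responder=False, noise_sd=0.0,
                                      baseline_area=1500 + 400 * i,
                                      total_s=0.5, frame_rate=10)
               for i in range(3)]
        frames, truth = ct.simulate_larva_frames(
            trs, arena=(700, 700),
            positions=[(150, 150), (350, 400), (550, 170)])
        clips = ct.segment_larvae(frames, frame_rate=10)
        assert len(clips) == 3
        measured = sorted(float(ct.behavior.area_series(c).areas.mean())
                          for c in clips)
        expected = sorted(truth["raster_areas"].mean(axis=1))
        for m, e in zip(measured, expected):
            assert m == pytest.approx(e, rel=0.02)


class TestAreaSeries:
    def test_solid_square_area(self):
        masks = np.zeros((3, 60, 60), dtype=bool)
        masks[:, 10:50, 10:50] = True
        clip = ct.LarvaClip("a", masks.astype(float), masks, frame_rate=30)
        trace = ct.behavior.area_series(clip)
        assert np.all(trace.areas == 1600)

    def test_empty_mask_flagged_as_zero(self):
        masks = np.zeros((2, 20, 20), dtype=bool)
        masks[0, 5:10, 5:10] = True
        clip = ct.LarvaClip("a", masks.astype(float), masks, frame_rate=30)
        trace = ct.behavior.area_series(clip)
        assert trace.areas[1] == 0 and trace.flags[1]


class TestPercentChange:
    def test_arithmetic(self):
        tr = ct.AreaTrace(frame_rate=10, areas=[1000.0] * 5 + [850.0] * 5,
                          onset=0.3)
        pt = ct.percent_change_trace(tr, reference="frame_at_onset")
        assert pt.values[-1] == pytest.approx(-15.0)

    def test_noise_bounded_reference(self):
        tr = ct.simulate_area_trace(responder=False, noise_sd=0.01,
                                    frame_rate=30, total_s=6, onset=2, seed=5)
        pt = ct.percent_change_trace(tr, window=0.5)
        assert np.max(np.abs(pt.values)) <= 100 * 0.01 * 5  # generous 5 sigma

    def test_zero_reference_raises(self):
        tr = ct.AreaTrace(frame_rate=10, areas=[0.0] * 10 + [5.0] * 10,
                          onset=0.0)
        with pytest.raises(Exception):
            ct.percent_change_trace(tr, reference="frame_at_onset")


class TestCTMetrics:
    def test_closed_form_example(self):
        """-15% for 2 s of a 5 s window at 30 Hz: responded, duration 2.0 s,
        magnitude (-15 * 2) / 5 = -6.0%."""
        v = np.zeros(150)
        v[30:90] = -15.0
        m = ct.ct_metrics(make_percent_trace(v))
        assert m.responded
        assert m.duration == pytest.approx(2.0, abs=1 / 30)
        assert m.magnitude == pytest.approx(-6.0, abs=0.2)

    def test_never_below_threshold(self):
        m = ct.ct_metrics(make_percent_trace(np.full(150, -8.0)))
        assert not m.responded and m.duration == 0.0

    def test_short_dip_counts_duration_but_not_response(self):
        v = np.zeros(150)
        v[30:42] = -15.0                 # 0.4 s at 30 Hz
        m = ct.ct_metrics(make_percent_trace(v))
        assert not m.responded
        assert m.duration == pytest.approx(0.4, abs=1 / 30)

    def test_boundary_exactly_threshold_and_min_duration(self):
        v = np.zeros(150)
        v[30:45] = -10.0                 # exactly -10%, exactly 0.5 s
        m = ct.ct_metrics(make_percent_trace(v))
        assert m.responded
        assert m.duration == pytest.approx(0.5, abs=1e-9)

    def test_window_longer_than_trace_raises(self):
        with pytest.raises(ParameterError):
            ct.ct_metrics(make_percent_trace(np.zeros(30)), window=5.0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_threshold_monotonicity(self, seed):
        """A looser (less negative) threshold never reduces duration or
        flips a responder to non-responder."""
        rng = np.random.default_rng(seed)
        v = rng.normal(-8, 6, size=150)
        strict = ct.ct_metrics(make_percent_trace(v), threshold=-10)
        loose = ct.ct_metrics(make_percent_trace(v), threshold=-5)
        assert loose.duration >= strict.duration
        assert loose.responded or not strict.responded


class TestSummary:
    def test_responder_fraction(self):
        ms = [ct.CTMetrics(f"a{i}", responded=i < 6, duration=0.0,
                           magnitude=0.0) for i in range(10)]
        s = ct.summarize_behavior(ms)
        assert s.pct_ct == 60.0

    def test_excluded_animals_dropped(self):
        ms = [ct.CTMetrics("a", True, 1.0, -12.0),
              ct.CTMetrics("b", True, 1.0, -12.0, excluded=True)]
        s = ct.summarize_behavior(ms)
        assert s.n_analyzed == 1

    def test_empty_cohort_raises(self):
        with pytest.raises(EmptyCohortError):
            ct.summarize_behavior([])
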