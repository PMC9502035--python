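"""dF/F identities, soma detection, ratiometry, and radial profiles."""

import numpy as np
import pytest

import coldtrace as ct
from coldtrace.errors import DegenerateTraceError, ParameterError
from coldtrace.imaging import FluorescenceTrace
from coldtrace.thresholds import image_histogram, moments_threshold
from oracles import moments_oracle, radial_profile_oracle


def make_trace(F, rate=13.0, baseline_end=2.0):
    F = np.asarray(F, dtype=float)
    t = np.arange(F.size) / rate
    return FluorescenceTrace(times=t, F=F, baseline_window=(0.0, baseline_end),
                             onset=baseline_end)


class TestDFF:
    def test_constant_F_gives_zero(self):
        d = ct.dff(make_trace(np.full(100, 50.0)))
        assert np.allclose(d.values, 0.0) and d.peak == 0.0

    def test_formula_arithmetic(self):
        F = np.full(100, 50.0)
        F[60:] = 75.0
        d = ct.dff(make_trace(F))
        assert d.values[-1] == pytest.approx(50.0)

    def test_doubling_gives_plus_100(self):
        F = np.full(100, 40.0)
        F[50:] = 80.0
        d = ct.dff(make_trace(F))
        assert d.peak == pytest.approx(100.0)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(1)
        F = 50 + rng.random(120) * 20
        a = ct.dff(make_trace(F)).values
        b = ct.dff(make_trace(3.7 * F)).values
        assert np.allclose(a, b)

    def test_nonpositive_baseline_raises(self):
        with pytest.raises(DegenerateTraceError):
            ct.dff(make_trace(np.zeros(50)))


class TestDetectSomata:
    def test_single_disk_found(self):
        img = ct.simulate_neuron_image(n_dendrites=0, soma_radius=8,
                                       soma_center=(60.0, 70.0),
                                       shape=(128, 128))
        rois = ct.detect_somata(img.green, opening_radius=2)
        assert len(rois) == 1
        cy, cx = rois[0].centroid
        assert abs(cy - 60) <= 1 and abs(cx - 70) <= 1

    def test_opening_removes_thin_branches(self):
        img = ct.simulate_neuron_image(n_dendrites=8, dendrite_width=1.0,
                                       soma_radius=8, dendrite_level=200.0)
        rois = ct.detect_somata(img.green, opening_radius=2)
        assert len(rois) == 1
        # ROI stays close to the disk: opening stripped the 1-px branches
        assert rois[0].area <= 1.3 * np.pi * 8 ** 2

    def test_area_filter_straddling_disks(self):
        img = np.zeros((120, 120))
        yy, xx = np.mgrid[0:120, 0:120]
        img[np.hypot(yy - 30, xx - 30) <= 10] = 200   # ~314 px
        img[np.hypot(yy - 90, xx - 90) <= 4] = 200    # ~50 px
        rois = ct.detect_somata(img, opening_radius=1, area_range=(100, 1000))
        assert len(rois) == 1 and rois[0].area > 100

    def test_moments_threshold_equals_exhaustive_search(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n_bg, n_fg = rng.integers(2000, 6000), rng.integers(200, 2000)
            img = np.clip(np.concatenate([
                rng.normal(rng.uniform(30, 70), 10, n_bg),
                rng.normal(rng.uniform(150, 220), 12, n_fg)]),
                0, 255).astype(np.uint8)
            hist, centers = image_histogram(img)
            assert moments_threshold(hist, centers) == moments_oracle(hist, centers)


class TestCampariRatio:
    def test_identity_and_doubling(self):
        for rho, expect in [(1.0, 1.0), (2.0, 2.0)]:
            img = ct.simulate_neuron_image(rho=rho)
            roi = ct.detect_somata(img.green)[0]
            assert ct.campari_ratio(img, roi) == pytest.approx(expect)

    def test_noise_propagation(self):
        img = ct.simulate_neuron_image(rho=0.5, noise_sd=2.0, seed=4)
        roi = ct.detect_somata(img.green)[0]
        assert 0.49 <= ct.campari_ratio(img, roi) <= 0.51

    def test_channel_scaling_invariance(self):
        img = ct.simulate_neuron_image(rho=1.5)
        roi = ct.detect_somata(img.green)[0]
        scaled = ct.TwoChannelImage(green=3.0 * img.green, red=3.0 * img.red)
        assert ct.campari_ratio(scaled, roi) == pytest.approx(
            ct.campari_ratio(img, roi))


class TestRadialProfile:
    def test_uniform_rho_flat_profile(self):
        img = ct.simulate_neuron_image(rho=2.0)
        prof = ct.radial_intensity_profile(img, img.mask, img.soma_centers[0])
        ok = prof.area > 0
        assert np.allclose(prof.ratio[ok], 2.0)

    def test_matches_pixel_oracle(self):
        rho = lambda r: 1.0 + r / 50.0
        img = ct.simulate_neuron_image(shape=(128, 128),
                                       soma_center=(64.0, 64.0), rho=rho)
        prof = ct.radial_intensity_profile(img, img.mask, (64.0, 64.0))
        radii, red_s, green_s, area, ratio = radial_profile_oracle(
            img.red, img.green, img.mask, (64.0, 64.0))
        assert np.array_equal(prof.radii, radii)
        assert np.array_equal(prof.area, area)
        assert np.allclose(prof.red_sum, red_s)
        assert np.allclose(prof.green_sum, green_s)
        assert np.allclose(prof.ratio, ratio, equal_nan=True)

    def test_step_rho_straddle_zone(self):
        """rho steps 1 -> 3 at r = 20: pure ratios outside the 5-px straddle
        band, intermediate inside it."""
        yy, xx = np.mgrid[0:128, 0:128]
        r = np.hypot(yy - 64, xx - 64)
        rho = np.where(r < 20, 1.0, 3.0)
        img = ct.simulate_neuron_image(shape=(128, 128),
                                       soma_center=(64.0, 64.0),
                                       soma_radius=40, n_dendrites=0, rho=rho)
        prof = ct.radial_intensity_profile(img, img.mask, (64.0, 64.0),
                                           max_radius=39)
        for rr, ratio in zip(prof.radii, prof.ratio):
            if rr <= 17:
                assert ratio == pytest.approx(1.0)
            elif 23 <= rr <= 37:
                assert ratio == pytest.approx(3.0)
            elif 18 <= rr <= 22 and np.isfinite(ratio):
                assert 1.0 < ratio < 3.0

    def test_nonoverlapping_annuli_conserve_area(self):
        img = ct.simulate_neuron_image()
        mask = img.mask
        prof = ct.radial_intensity_profile(img, mask, img.soma_centers[0],
                                           annulus_width=5, step=5)
        # [0 - 2.5, max + 2.5] annuli tile the mask; boundary pixels at
        # half-integer distances could double-count, so allow tiny slack
        assert abs(int(prof.area.sum()) - int(mask.sum())) <= 0.01 * mask.sum()

    def test_center_outside_raises(self):
        img = ct.simulate_neuron_image()
        with pytest.raises(ParameterError):
            ct.radial_intensity_profile(img, img.mask, (999.0, 0.0))


class TestShollIntersections:
    def test_four_rays(self):
        img = ct.simulate_neuron_image(n_dendrites=4, dendrite_length=50,
                                       soma_radius=5)
        radii, counts = ct.sholl_intersections(img.mask, img.soma_centers[0])
        probe = (radii > 10) & (radii < 45)
        assert np.all(counts[probe] == 4)

    def test_empty_mask(self):
        radii, counts = ct.sholl_intersections(np.zeros((32, 32), bool),
                                               (16.0, 16.0))
        assert radii.size == 0 and counts.size == 0

    def test_known_topology_tree(self):
        """Two straight branches that each bifurcate at r = 30: counts go
        2 inside, 4 outside the bifurcation."""
        mask = np.zeros((200, 200), bool)
        cy = cx = 100
        for dy, dx in [(0, 1), (0, -1)]:            # trunks along x
            for t in range(31):
                mask[cy, cx + dx * t] = True
        for sy in (1, -1):                           # four oblique tips
            for sx in (1, -1):
                for t in range(40):
                    y = cy + sy * int(round(t * 0.6))
                    x = cx + sx * (30 + t)
                    if 0 <= y < 199 and 0 <= x < 200:
                        mask[y, x] = True
                        mask[y + 1, x] = True  # 2 px thick: no diagonal gaps
        radii, counts = ct.sholl_intersections(mask, (float(cy), float(cx)))
        inner = (radii > 5) & (radii < 28)
        outer = (radii > 40) & (radii < 60)
        assert np.all(counts[inner] == 2)
        assert np.all(counts[outer] == 4)
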