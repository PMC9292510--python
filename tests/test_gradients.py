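"""Waveform synthesis: limits, time-optimality, validation, EPI trains."""

import math

import numpy as np
import pytest

from thex.gradients import (
    GAMMA_BAR_1H,
    SystemLimits,
    epi_train,
    min_curvature_radius,
    time_optimal_waveform,
    validate_waveform,
)
from thex.spiral import archimedean_path


class TestSystemLimits:
    def test_derived_quantities(self):
        lim = SystemLimits(gmax=31.0, smax=200.0)
        assert lim.gmax_si == pytest.approx(0.031)
        assert lim.kspeed == pytest.approx(GAMMA_BAR_1H * 0.031)
        assert lim.kslew == pytest.approx(GAMMA_BAR_1H * 200.0)

    @pytest.mark.parametrize("kw", [{"gmax": 0}, {"smax": -1}, {"raster": 0}])
    def test_positivity(self, kw):
        base = {"gmax": 31.0, "smax": 200.0}
        base.update(kw)
        with pytest.raises(ValueError):
            SystemLimits(**base)


class TestMinCurvatureRadius:
    def test_reference_system(self, scanner_limits):
        # gamma_bar * Gmax^2 / Smax = 42.577478e6 * 0.031^2 / 200
        assert min_curvature_radius(scanner_limits) == pytest.approx(204.585, rel=1e-4)

    def test_quadratic_in_gmax(self):
        r1 = min_curvature_radius(SystemLimits(gmax=20.0, smax=200.0))
        r2 = min_curvature_radius(SystemLimits(gmax=40.0, smax=200.0))
        assert r2 == pytest.approx(4 * r1)

    def test_same_order_as_kmax(self, scanner_limits):
        """The feasible radius is of the same order as the k-space extent of
        a sub-millimeter protocol (kmax = 833 1/m at 0.6 mm)."""
        r = min_curvature_radius(scanner_limits)
        assert 0.1 < r / 833.3 < 1.0


def straight_path(length: float, n: int = 2001) -> np.ndarray:
    x = np.linspace(0.0, length, n)
    return np.column_stack([x, np.zeros(n)])


class TestTimeOptimalWaveform:
    def test_straight_line_matches_trapezoid(self, scanner_limits):
        """A straight segment is a textbook trapezoidal ramp: K/v + v/a."""
        K = 2000.0
        wf = time_optimal_waveform(straight_path(K), scanner_limits)
        v = scanner_limits.kspeed
        a = scanner_limits.kslew
        analytic = K / v + v / a
        assert wf.duration == pytest.approx(analytic, rel=0.02)

    def test_short_line_is_triangular(self, scanner_limits):
        """Below the trapezoid threshold: t = 2*sqrt(K/a)."""
        K = 50.0
        wf = time_optimal_waveform(straight_path(K), scanner_limits)
        analytic = 2.0 * math.sqrt(K / scanner_limits.kslew)
        # short ramps are dominated by raster quantization: allow margin +
        # one raster interval on each side
        assert abs(wf.duration - analytic) <= 0.01 * analytic + 2 * scanner_limits.raster

    def test_spiral_matches_two_regime_analytic(self, scanner_limits):
        """Archimedean spiral: slew-limited core + amplitude-limited body.

        t1 = (2*pi/(d*sqrt(a))) * (2/3) * r*^{3/2} with r* = v^2/a,
        t2 = (arc length beyond r*) / v.
        """
        d, kmax = 50.0, 600.0
        path = archimedean_path(d, kmax)
        wf = time_optimal_waveform(path, scanner_limits)
        v = scanner_limits.kspeed
        a = scanner_limits.kslew
        rstar = v * v / a
        t1 = (2 * math.pi / (d * math.sqrt(a))) * (2.0 / 3.0) * rstar**1.5
        t2 = math.pi * (kmax**2 - rstar**2) / d / v
        assert wf.duration == pytest.approx(t1 + t2, rel=0.10)
        # hard physical lower bound: arc length / max speed
        assert wf.duration >= path.arc_length / v

    def test_limits_respected(self, scanner_limits):
        path = archimedean_path(50.0, 600.0)
        wf = time_optimal_waveform(path, scanner_limits)
        assert wf.peak_amplitude() <= scanner_limits.gmax * (1 + 1e-9)
        assert wf.peak_slew() <= scanner_limits.smax * (1 + 1e-9)

    def test_waveform_integrates_to_path_nodes(self, scanner_limits):
        wf = time_optimal_waveform(archimedean_path(50.0, 300.0), scanner_limits)
        k_int = wf.k[0] + np.vstack(
            [np.zeros(2), np.cumsum(wf.G * 1e-3, axis=0) * wf.gamma_bar * wf.raster]
        )
        assert np.allclose(k_int, wf.k, atol=1e-8)

    def test_duration_monotone_in_gmax(self):
        path = archimedean_path(50.0, 600.0)
        durs = [
            time_optimal_waveform(path, SystemLimits(gmax=g, smax=200.0)).duration
            for g in (15.0, 31.0, 60.0)
        ]
        assert durs[0] > durs[1] > durs[2]

    def test_duration_monotone_in_smax(self):
        path = archimedean_path(50.0, 600.0)
        durs = [
            time_optimal_waveform(path, SystemLimits(gmax=31.0, smax=s)).duration
            for s in (80.0, 200.0, 500.0)
        ]
        assert durs[0] > durs[1] > durs[2]

    def test_corner_rejected(self, scanner_limits):
        x = np.linspace(0.0, 100.0, 200)
        leg1 = np.column_stack([x, np.zeros_like(x)])
        leg2 = np.column_stack([np.full_like(x, 100.0), x])
        with pytest.raises(ValueError, match="cusp|corner"):
            time_optimal_waveform(np.vstack([leg1, leg2[1:]]), scanner_limits)

    def test_too_short_path_rejected(self, scanner_limits):
        with pytest.raises(ValueError, match="path"):
            time_optimal_waveform(np.array([[0.0, 0.0], [1.0, 0.0]]), scanner_limits)


class TestValidateWaveform:
    @pytest.fixture(scope="class")
    def spiral_case(self, scanner_limits):
        path = archimedean_path(50.0, 600.0)
        return path, time_optimal_waveform(path, scanner_limits)

    def test_good_waveform_passes(self, spiral_case, scanner_limits):
        path, wf = spiral_case
        rep = validate_waveform(wf, path, scanner_limits, k_tol=50.0 / 100.0)
        assert rep.ok
        assert rep.max_k_deviation < 0.5

    def test_overdriven_amplitude_flagged(self, spiral_case, scanner_limits):
        import copy

        path, wf = spiral_case
        bad = copy.deepcopy(wf)
        bad.G = bad.G * 1.2
        rep = validate_waveform(bad, path, scanner_limits, k_tol=0.5)
        assert not rep.amplitude_ok
        assert not rep.ok

    def test_path_deviation_flagged(self, spiral_case, scanner_limits):
        path, wf = spiral_case
        shifted = path.samples + np.array([5.0, 0.0])
        rep = validate_waveform(wf, shifted, scanner_limits, k_tol=0.5)
        assert not rep.k_ok

    def test_raster_mismatch_rejected(self, spiral_case):
        path, wf = spiral_case
        with pytest.raises(ValueError, match="raster"):
            validate_waveform(wf, path, SystemLimits(gmax=31.0, smax=200.0, raster=4e-6))


class TestEpiTrain:
    KMAX = 714.3  # 0.7 mm in-plane
    SPACING = 55.0

    @pytest.fixture(scope="class")
    def train(self, scanner_limits):
        return epi_train(5, self.KMAX, self.SPACING, scanner_limits)

    def test_limits_respected(self, train, scanner_limits):
        assert train.wf.peak_amplitude() <= scanner_limits.gmax * (1 + 1e-9)
        assert train.wf.peak_slew() <= scanner_limits.smax * (1 + 1e-9)

    def test_lines_span_kmax(self, train):
        for j in range(train.n_lines):
            kx = train.k_samples[train.line_of_sample == j, 0]
            assert kx.min() == pytest.approx(-self.KMAX, rel=1e-3)
            assert kx.max() == pytest.approx(self.KMAX, rel=1e-3)
        assert np.abs(train.k_samples[:, 0]).max() <= self.KMAX * (1 + 1e-6)

    def test_serpentine_direction_alternates(self, train):
        for j in range(train.n_lines):
            kx = train.k_samples[train.line_of_sample == j, 0]
            sign = 1.0 if j % 2 == 0 else -1.0
            assert np.all(sign * np.diff(kx) > 0)

    def test_blips_step_ky_by_line_spacing(self, train):
        # flat-top samples of line j sit exactly at ky = j * spacing
        for j in range(train.n_lines):
            sel = train.line_of_sample == j
            ky = train.k_samples[sel, 1]
            mid = ky[len(ky) // 2]  # mid-line sample is on the flat top
            assert mid == pytest.approx(j * self.SPACING, abs=1e-6)

    def test_timing_identities(self, train):
        assert train.esp == pytest.approx(train.t_flat + train.t_turn)
        assert train.t_aq == pytest.approx(train.n_lines * train.esp)
        # last-sample time is within one esp of t_aq
        assert train.t_samples[-1] <= train.t_aq + 1e-12

    def test_flat_top_only_mode(self, scanner_limits):
        tr = epi_train(4, self.KMAX, self.SPACING, scanner_limits, ramp_sampling=False)
        # every sample on a flat top: exact ky plateau values only
        ky = tr.k_samples[:, 1]
        frac = ky / self.SPACING
        assert np.abs(frac - np.round(frac)).max() < 1e-9
        # turnarounds overshoot beyond kmax, samples do not
        assert np.abs(tr.wf.k[:, 0]).max() > self.KMAX * (1 + 1e-6)
        assert np.abs(tr.k_samples[:, 0]).max() <= self.KMAX * (1 + 1e-9)
        # flat-only train is longer per covered line extent
        assert tr.t_aq > 0

    def test_adc_dwell_refines_sampling(self, scanner_limits):
        coarse = epi_train(3, self.KMAX, self.SPACING, scanner_limits)
        fine = epi_train(3, self.KMAX, self.SPACING, scanner_limits, adc_dwell=2.5e-6)
        assert len(fine.t_samples) > 3 * len(coarse.t_samples)
        assert np.allclose(np.diff(fine.t_samples[:10]), 2.5e-6)

    def test_single_line_no_blip(self, scanner_limits):
        tr = epi_train(1, self.KMAX, self.SPACING, scanner_limits)
        assert np.allclose(tr.wf.G[:, 1], 0.0)
        assert tr.t_aq == pytest.approx(tr.esp)

    def test_ky_start_offsets_train(self, scanner_limits):
        tr = epi_train(2, self.KMAX, self.SPACING, scanner_limits, ky_start=17.0)
        ky0 = tr.k_samples[tr.line_of_sample == 0, 1]
        assert ky0[len(ky0) // 2] == pytest.approx(17.0, abs=1e-6)

    @pytest.mark.parametrize(
        "args", [(0, 100.0, 10.0), (3, -1.0, 10.0), (3, 100.0, 0.0)]
    )
    def test_invalid_args(self, args, scanner_limits):
        with pytest.raises(ValueError):
            epi_train(*args, scanner_limits)

    def test_esp_close_to_amplitude_limited_bound(self, train, scanner_limits):
        """Echo spacing exceeds the ideal flat-top-at-Gmax time but not by
        much more than the turnaround."""
        ideal_flat = 2 * self.KMAX / scanner_limits.kspeed
        assert train.esp > ideal_flat
        assert train.esp < 1.5 * ideal_flat
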