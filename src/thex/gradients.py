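"""Hardware-constrained gradient waveform synthesis.

Converts geometric k-space paths into time-stamped gradient waveforms of
(near-)minimal duration under the two scanner limits that matter for
trajectory speed: peak gradient amplitude Gmax (caps the k-space velocity
at gamma_bar*Gmax) and peak slew rate Smax (caps the k-space acceleration
at gamma_bar*Smax, and hence the curvature the path can have at speed: at
full velocity the smallest feasible radius of curvature is
gamma_bar*Gmax^2/Smax).

Smooth paths (spirals) are handled by the classic arc-length speed-profile
method: a per-position velocity ceiling from the amplitude and curvature
limits, then forward/backward sweeps that enforce tangential-acceleration
feasibility, then integration of t(s) and resampling onto the gradient
raster.  Piecewise-linear EPI readouts have corners of infinite curvature,
which the generic method must reject; :func:`epi_train` builds them
analytically from flat tops and minimal-time turnarounds that combine the
frequency-encode reversal with the phase-encode blip.

Units: k in cycles/m (1/m), G in mT/m, slew in T/m/s, time in s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq
from scipy.spatial import cKDTree

__all__ = [
    "GAMMA_BAR_1H",
    "SystemLimits",
    "GradientWaveform",
    "WaveformReport",
    "EpiReadout",
    "time_optimal_waveform",
    "validate_waveform",
    "min_curvature_radius",
    "epi_train",
]

#: gyromagnetic ratio of 1H over 2*pi, Hz/T
GAMMA_BAR_1H = 42.577478e6

# design safety margins absorbing raster discretization so that the
# synthesized staircase waveform respects the stated limits exactly
_G_MARGIN = 0.998
_S_MARGIN = 0.995


@dataclass(frozen=True)
class SystemLimits:
    """Gradient system limits.

    Attributes
    ----------
    gmax : float
        Peak gradient amplitude, mT/m.
    smax : float
        Peak slew rate, T/m/s.
    raster : float
        Gradient raster interval, s (10 us default).
    gamma_bar : float
        Gyromagnetic ratio over 2*pi, Hz/T (1H default).
    """

    gmax: float
    smax: float
    raster: float = 10e-6
    gamma_bar: float = GAMMA_BAR_1H

    def __post_init__(self) -> None:
        for name in ("gmax", "smax", "raster", "gamma_bar"):
            if not getattr(self, name) > 0:
                raise ValueError(f"SystemLimits.{name} must be strictly positive")

    @property
    def gmax_si(self) -> float:
        """Peak amplitude in T/m."""
        return self.gmax * 1e-3

    @property
    def kspeed(self) -> float:
        """Max k-space speed gamma_bar*Gmax, (1/m)/s."""
        return self.gamma_bar * self.gmax_si

    @property
    def kslew(self) -> float:
        """Max k-space acceleration gamma_bar*Smax, (1/m)/s^2."""
        return self.gamma_bar * self.smax


def min_curvature_radius(limits: SystemLimits) -> float:
    """Smallest k-space radius of curvature feasible at full speed, 1/m.

    At speed v = gamma_bar*Gmax the centripetal acceleration v^2/r may not
    exceed gamma_bar*Smax, giving r >= gamma_bar*Gmax^2/Smax.  For typical
    systems this is of the same order as the sampled k-space extent, which
    is why in-readout oscillatory excursions buy little extra encoding.
    """
    return limits.gamma_bar * limits.gmax_si**2 / limits.smax


@dataclass
class GradientWaveform:
    """Raster-sampled multi-axis gradient waveform and its k-space path.

    ``k`` holds n+1 trajectory nodes (1/m) at times ``t`` (s, spacing
    ``raster``); ``G`` holds the n staircase amplitudes between nodes
    (mT/m), so k[i+1] = k[i] + gamma_bar * G[i] * 1e-3 * raster exactly.
    The waveform is preceded and followed by zero amplitude.
    """

    G: np.ndarray
    k: np.ndarray
    t: np.ndarray
    raster: float
    gamma_bar: float = GAMMA_BAR_1H

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def ndim(self) -> int:
        return self.k.shape[1]

    def peak_amplitude(self) -> float:
        """Peak vector amplitude, mT/m."""
        return float(np.linalg.norm(self.G, axis=1).max()) if len(self.G) else 0.0

    def peak_slew(self) -> float:
        """Peak vector slew rate, T/m/s, including the steps from/to zero."""
        Gpad = np.vstack([np.zeros((1, self.G.shape[1])), self.G, np.zeros((1, self.G.shape[1]))])
        return float(
            (np.linalg.norm(np.diff(Gpad, axis=0), axis=1) * 1e-3 / self.raster).max()
        )


@dataclass
class WaveformReport:
    peak_amplitude: float
    peak_slew: float
    max_k_deviation: float
    amplitude_ok: bool
    slew_ok: bool
    k_ok: bool

    @property
    def ok(self) -> bool:
        return self.amplitude_ok and self.slew_ok and self.k_ok


def _as_samples(path) -> np.ndarray:
    samples = getattr(path, "samples", path)
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] < 3 or samples.shape[1] not in (2, 3):
        raise ValueError("path must be an (N>=3, 2|3) array of k-space samples")
    return samples


def time_optimal_waveform(
    path,
    limits: SystemLimits,
    corner_angle_deg: float = 25.0,
) -> GradientWaveform:
    """Minimal-duration waveform traversing a smooth k-space path.

    Parameters
    ----------
    path : array_like or object with ``.samples``
        Finely sampled (N, 2|3) k-space path with (approximately) monotone
        arc-length parameterization.  The sampling must resolve the local
        curvature (turn angle below ``corner_angle_deg`` per step), which a
        properly oversampled spiral does; paths with cusps or corners are
        rejected.

    Returns
    -------
    GradientWaveform
        Starting and ending at zero gradient amplitude, with
        |G| <= Gmax and vector slew <= Smax at every raster step.
    """
    pts = _as_samples(path)
    seg = np.diff(pts, axis=0)
    ds = np.linalg.norm(seg, axis=1)
    good = ds > 0
    if not good.all():  # drop exactly duplicated samples
        pts = np.vstack([pts[:1], pts[1:][good]])
        seg = np.diff(pts, axis=0)
        ds = np.linalg.norm(seg, axis=1)
    tang = seg / ds[:, None]
    # corner / cusp detection
    cosang = np.clip(np.einsum("ij,ij->i", tang[:-1], tang[1:]), -1.0, 1.0)
    max_turn = math.degrees(float(np.arccos(cosang).max())) if len(cosang) else 0.0
    if max_turn > corner_angle_deg:
        raise ValueError(
            f"path turns by {max_turn:.1f} deg within one step: cusp/corner or "
            "insufficient sampling. Round the corners (EPI readouts: use "
            "epi_train, which builds turnarounds analytically)."
        )
    s = np.concatenate([[0.0], np.cumsum(ds)])

    # curvature at interior nodes from tangent change per arc length
    kappa = np.zeros(len(pts))
    dtang = np.linalg.norm(np.diff(tang, axis=0), axis=1)
    kappa[1:-1] = dtang / (0.5 * (ds[:-1] + ds[1:]))
    kappa[0], kappa[-1] = kappa[1], kappa[-2]

    vamp = _G_MARGIN * limits.kspeed
    aslew = _S_MARGIN * limits.kslew
    with np.errstate(divide="ignore"):
        vcurv = np.sqrt(np.where(kappa > 0, aslew / np.maximum(kappa, 1e-300), np.inf))
    vmax2 = np.minimum(vamp, vcurv) ** 2

    v2 = _speed_sweeps(vmax2, kappa, ds, aslew)
    v = np.sqrt(v2)
    # segment durations for linear-in-time speed (constant tangential
    # acceleration within each segment): dt = 2*ds/(v_i + v_{i+1}), which is
    # exact and integrable at the zero-speed endpoints
    vsum = np.maximum(v[:-1] + v[1:], 2.0 * math.sqrt(0.5 * aslew * ds.min()))
    dt = 2.0 * ds / vsum
    tnode = np.concatenate([[0.0], np.cumsum(dt)])
    duration = tnode[-1]

    n = int(math.ceil(duration / limits.raster))
    tr = np.arange(n + 1) * limits.raster
    # resample arc length onto the raster with the exact per-segment
    # kinematics s(tau) = s_i + v_i*tau + a_i*tau^2/2 (piecewise-linear
    # interpolation would make the speed piecewise constant and put large
    # slew jumps wherever a segment outlasts the raster, e.g. the final
    # deceleration of a spiral)
    idx = np.clip(np.searchsorted(tnode, tr, side="right") - 1, 0, len(dt) - 1)
    # clamp to the segment end: the final raster node may nominally fall
    # past the zero-speed vertex, where the quadratic would backtrack
    tau = np.minimum(tr - tnode[idx], dt[idx])
    accel = (v[idx + 1] - v[idx]) / dt[idx]
    s_of_t = s[idx] + v[idx] * tau + 0.5 * accel * tau**2
    spline = CubicSpline(s, pts, axis=0)
    k = spline(np.clip(s_of_t, s[0], s[-1]))
    G = np.diff(k, axis=0) / (limits.gamma_bar * limits.raster) * 1e3  # mT/m
    return GradientWaveform(G=G, k=k, t=tr, raster=limits.raster, gamma_bar=limits.gamma_bar)


def _speed_sweeps(vmax2: np.ndarray, kappa: np.ndarray, ds: np.ndarray, aslew: float) -> np.ndarray:
    """Forward/backward velocity-limit sweeps (squared speeds)."""
    n = len(vmax2)
    v2 = vmax2.copy()
    v2[0] = 0.0
    for i in range(n - 1):  # forward: acceleration feasibility
        at2 = aslew * aslew - (kappa[i] * v2[i]) ** 2
        at = math.sqrt(at2) if at2 > 0 else 0.0
        cap = v2[i] + 2.0 * at * ds[i]
        if v2[i + 1] > cap:
            v2[i + 1] = cap
    v2[-1] = 0.0
    for i in range(n - 1, 0, -1):  # backward: deceleration feasibility
        at2 = aslew * aslew - (kappa[i] * v2[i]) ** 2
        at = math.sqrt(at2) if at2 > 0 else 0.0
        cap = v2[i] + 2.0 * at * ds[i - 1]
        if v2[i - 1] > cap:
            v2[i - 1] = cap
    return v2


def validate_waveform(
    wf: GradientWaveform,
    path,
    limits: SystemLimits,
    k_tol: float | None = None,
) -> WaveformReport:
    """Check a waveform against the limits and its requested path.

    The k deviation is the maximum distance from each integrated-trajectory
    node to the requested path (nearest point on the reference polyline,
    with segment projection), plus the endpoint mismatch — i.e. the
    geometric distance the realized sampling pattern strays from the
    design.  ``k_tol`` defaults to 1/100 of the path's mean sample spacing
    scaled conservatively when no lattice spacing is supplied.
    """
    if abs(wf.raster - limits.raster) > 1e-12:
        raise ValueError(
            f"raster mismatch: waveform {wf.raster} s vs limits {limits.raster} s"
        )
    if len(wf.G) == 0:
        raise ValueError("empty waveform")
    pts = _as_samples(path)
    # integrate the staircase, then measure point-to-polyline distances
    k_int = wf.k[0] + np.vstack(
        [np.zeros(wf.ndim), np.cumsum(wf.G * 1e-3, axis=0) * wf.gamma_bar * wf.raster]
    )
    tree = cKDTree(pts)
    _, nearest = tree.query(k_int)
    dist2 = np.full(len(k_int), np.inf)
    for off in (-1, 0):  # project onto the segments adjacent to the hit
        i0 = np.clip(nearest + off, 0, len(pts) - 2)
        a = pts[i0]
        ab = pts[i0 + 1] - a
        denom = np.einsum("ij,ij->i", ab, ab)
        t = np.clip(np.einsum("ij,ij->i", k_int - a, ab) / np.maximum(denom, 1e-300), 0.0, 1.0)
        closest = a + t[:, None] * ab
        dist2 = np.minimum(dist2, np.einsum("ij,ij->i", k_int - closest, k_int - closest))
    dev = float(np.sqrt(dist2.max()))
    # the ends must be reached, not just approached
    dev = max(dev, float(np.linalg.norm(k_int[0] - pts[0])), float(np.linalg.norm(k_int[-1] - pts[-1])))
    if k_tol is None:
        s_total = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        k_tol = 0.01 * s_total / len(pts) * 20.0

    amp = wf.peak_amplitude()
    slew = wf.peak_slew()
    return WaveformReport(
        peak_amplitude=amp,
        peak_slew=slew,
        max_k_deviation=dev,
        amplitude_ok=amp <= limits.gmax * (1 + 1e-9),
        slew_ok=slew <= limits.smax * (1 + 1e-9),
        k_ok=dev <= k_tol,
    )


# ---------------------------------------------------------------------------
# EPI readout trains


@dataclass
class EpiReadout:
    """Analytic EPI readout train.

    ``t_samples``/``k_samples`` are the ADC events (times within the train,
    positions in 1/m); ``line_of_sample`` maps each ADC event to its readout
    line.  ``esp`` is the echo spacing (line period), ``t_aq`` the
    acquisition duration from first to last sample.
    """

    wf: GradientWaveform
    t_samples: np.ndarray
    k_samples: np.ndarray
    line_of_sample: np.ndarray
    n_lines: int
    t_flat: float
    t_turn: float
    esp: float
    t_aq: float
    ramp_sampling: bool


def _turnaround_time(G: float, blip_area: float, smax: float) -> float:
    """Minimal time to reverse Gx (+G -> -G) while playing a ky blip.

    The Gx ramp uses constant slew 2G/T; the triangular ky blip of area
    ``blip_area`` (T*s/m) uses slew 4*area/T^2; the vector slew norm must
    stay within ``smax``.
    """

    def excess(T: float) -> float:
        return (2.0 * G / T) ** 2 + (4.0 * blip_area / T**2) ** 2 - smax**2

    lo, hi = 1e-7, 1.0
    if excess(hi) > 0:
        raise ValueError("blip area infeasible within 1 s: check limits")
    return brentq(excess, lo, hi, xtol=1e-12)


def epi_train(
    n_lines: int,
    kmax_x: float,
    line_spacing: float,
    limits: SystemLimits,
    ramp_sampling: bool = True,
    adc_dwell: float | None = None,
    ky_start: float = 0.0,
) -> EpiReadout:
    """Time-optimal serpentine EPI readout train.

    Lines span kx in [-kmax_x, +kmax_x] with alternating direction and are
    separated by ``line_spacing`` in ky, stepped by a triangular blip played
    during each turnaround.  With ``ramp_sampling`` (default) the turnaround
    apex touches the line end exactly, so the outer kx range is covered on
    the ramps and the flat tops only span the interior; this is the
    shortest feasible train.  With ``ramp_sampling=False`` the flat tops
    cover the full line and the turnarounds overshoot beyond kmax_x
    (samples are then taken on flat tops only).

    ADC events are placed every ``adc_dwell`` seconds (gradient raster by
    default) wherever |kx| <= kmax_x.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if kmax_x <= 0 or line_spacing <= 0:
        raise ValueError("kmax_x and line_spacing must be positive")
    raster = limits.raster
    gb = limits.gamma_bar
    smax_eff = _S_MARGIN * limits.smax
    blip_area = line_spacing / gb  # T*s/m

    # Size the flat amplitude so the line coverage closes exactly on the
    # raster.  t_turn is fixed from the Gmax-margin amplitude (rounding up to
    # an even raster count); lowering G below that only relaxes the
    # turnaround, so the chosen n_turn stays feasible.
    G = _G_MARGIN * limits.gmax_si
    t_turn = _turnaround_time(G, blip_area, smax_eff)
    n_turn = 2 * int(math.ceil(t_turn / (2 * raster)))  # even raster count
    t_turn = n_turn * raster
    if ramp_sampling:
        # apex touches the line end: gamma_bar*G*(t_flat + t_turn/2) = 2*kmax
        n_half = n_turn // 2
        n_flat = int(math.ceil(2.0 * kmax_x / (gb * G * raster) - n_half))
        if n_flat < 1:
            raise ValueError(
                "line shorter than the turnaround coverage: lower Gmax or raise kmax_x"
            )
        G = 2.0 * kmax_x / (gb * (n_flat + n_half) * raster)
        k_over = gb * G * t_turn / 4.0
    else:
        n_flat = int(math.ceil(2.0 * kmax_x / (gb * G * raster)))
        G = 2.0 * kmax_x / (gb * n_flat * raster)
        k_over = 0.0
    t_flat = n_flat * raster
    esp = t_flat + t_turn
    t_aq = n_lines * esp if ramp_sampling else n_lines * t_flat + (n_lines - 1) * t_turn

    # --- assemble staircase amplitudes (T/m) on the raster ---------------
    sy = 4.0 * blip_area / t_turn**2  # blip slew
    half = n_turn // 2
    if sy * t_turn / 2.0 > limits.gmax_si * (1 + 1e-9):
        raise ValueError("ky blip peak exceeds Gmax: line spacing too large for limits")

    def ramp(g0: float, g1: float, nsteps: int) -> np.ndarray:
        """Staircase from g0 to g1 in nsteps raster intervals (midpoints)."""
        return g0 + (g1 - g0) * (np.arange(nsteps) + 0.5) / nsteps

    Gx: list[np.ndarray] = []
    Gy: list[np.ndarray] = []
    blip_half_peak = sy * t_turn / 2.0
    blip = np.concatenate([ramp(0.0, blip_half_peak, half), ramp(blip_half_peak, 0.0, half)])

    # entry ramp (half turnaround, no blip)
    Gx.append(ramp(0.0, G, half))
    Gy.append(np.zeros(half))
    sign = 1.0
    for line in range(n_lines):
        Gx.append(np.full(n_flat, sign * G))
        Gy.append(np.zeros(n_flat))
        if line < n_lines - 1:
            Gx.append(ramp(sign * G, -sign * G, n_turn))
            Gy.append(blip)
            sign = -sign
    Gx.append(ramp(sign * G, 0.0, half))
    Gy.append(np.zeros(half))
    gx = np.concatenate(Gx)
    gy = np.concatenate(Gy)
    Gsi = np.column_stack([gx, gy])

    # integrate k; start such that line 0 spans [-kmax_x, ...]
    k = np.vstack([np.zeros(2), np.cumsum(Gsi, axis=0) * gb * raster])
    entry_cover = gb * G * (half * raster) / 2.0  # kx covered on the entry ramp
    if ramp_sampling:
        k0x = -kmax_x
    else:
        k0x = -kmax_x - entry_cover
    k += np.array([k0x, ky_start])
    t = np.arange(len(k)) * raster

    # --- ADC events -------------------------------------------------------
    dwell = raster if adc_dwell is None else float(adc_dwell)
    ts = np.arange(0.0, t[-1] + 0.5 * dwell, dwell)
    ts = ts[ts <= t[-1] + 1e-12]
    kx_s = np.interp(ts, t, k[:, 0])
    ky_s = np.interp(ts, t, k[:, 1])
    tol = 1e-9 * kmax_x
    if ramp_sampling:
        mask = np.abs(kx_s) <= kmax_x + tol
    else:
        # flat tops only
        line_starts = half * raster + np.arange(n_lines) * (n_flat + n_turn) * raster
        mask = np.zeros(len(ts), dtype=bool)
        for ls in line_starts:
            mask |= (ts >= ls - 1e-12) & (ts <= ls + t_flat + 1e-12)
    ts, kx_s, ky_s = ts[mask], kx_s[mask], ky_s[mask]
    # line index from elapsed time past the entry ramp; with ramp sampling,
    # lines hand over at the turnaround apex (where kx = +-kmax), so each
    # line's samples sweep monotonically across the full kx range
    rel = np.clip(ts - half * raster, 0.0, None)
    if ramp_sampling:
        line_idx = np.minimum(((rel + t_turn / 2.0) / esp).astype(int), n_lines - 1)
    else:
        line_idx = np.minimum((rel / (t_flat + t_turn)).astype(int), n_lines - 1)
    # re-reference sample times to the first sample
    ts = ts - ts[0]

    wf = GradientWaveform(G=Gsi * 1e3, k=k, t=t, raster=raster, gamma_bar=gb)
    return EpiReadout(
        wf=wf,
        t_samples=ts,
        k_samples=np.column_stack([kx_s, ky_s]),
        line_of_sample=line_idx,
        n_lines=n_lines,
        t_flat=t_flat,
        t_turn=t_turn,
        esp=esp,
        t_aq=float(t_aq),
        ramp_sampling=ramp_sampling,
    )
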