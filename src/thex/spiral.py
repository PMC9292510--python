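"""Mono-planar T-Hex stacks of Archimedean spirals.

A single Archimedean spiral (constant radial increment d per revolution) is
designed once; shot j is that spiral rotated about kz by the linearly
progressing angle 2*pi*(j*c/d mod 1) and placed at the stack position
kz_j = j*h.  Because a rotation by phi shifts every revolution radius by
(phi/2pi)*d at any fixed azimuth, the revolution-radius/kz cross-section of
the full stack is exactly the tilted hexagonal pattern of
:mod:`thex.hexlattice` — uniform density with a per-shot increment d that
need not be an integer multiple of the lattice constant.  All shots share
one radial progression, so signal decay maps onto a smooth radial k-space
filter instead of interleave-to-interleave jumps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .gradients import GradientWaveform, SystemLimits, time_optimal_waveform
from .hexlattice import ShotGeometry, TiltIndex, shot_geometry, shot_offsets, tilt_norm

__all__ = [
    "SQRT3",
    "PlanarPath",
    "SequenceGeometry",
    "TrajectorySet",
    "archimedean_path",
    "cross_section_scales",
    "build_spiral_stack",
]

SQRT3 = math.sqrt(3.0)


@dataclass
class PlanarPath:
    """Geometric (untimed) planar k-space path.

    ``samples`` is an (N, 2) array in 1/m with (approximately) uniform and
    monotone arc-length progression; timing is assigned later by the
    gradients module.
    """

    samples: np.ndarray
    kmax: float
    d: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.linalg.norm(self.samples, axis=1)

    @property
    def n_revolutions(self) -> float:
        return self.kmax / self.d

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.samples, axis=0), axis=1).sum())


def archimedean_path(
    d: float, kmax: float, angular_oversampling: int = 512
) -> PlanarPath:
    """Archimedean spiral r(theta) = d*theta/(2*pi) from r = 0 to r = kmax.

    ``angular_oversampling`` is the number of samples per revolution; the
    default resolves the outermost turn to well below 1% of typical lattice
    constants for spline interpolation during waveform design.
    """
    if d <= 0 or kmax <= 0:
        raise ValueError("d and kmax must be positive")
    if d > 2.0 * kmax:
        raise ValueError(
            f"radial increment d = {d} exceeds 2*kmax = {2 * kmax}: the spiral "
            "would end within half a revolution (degenerate)"
        )
    theta_max = 2.0 * math.pi * kmax / d
    n = max(int(math.ceil(theta_max / (2.0 * math.pi) * angular_oversampling)), 16)
    theta = np.linspace(0.0, theta_max, n + 1)
    r = d * theta / (2.0 * math.pi)
    return PlanarPath(
        samples=np.column_stack([r * np.cos(theta), r * np.sin(theta)]),
        kmax=kmax,
        d=d,
    )


@dataclass
class SequenceGeometry:
    """Imaging protocol geometry.

    Attributes
    ----------
    fov : tuple of 3 floats
        Field of view (x, y, z) in m; the in-plane FOV must be isotropic
        for spiral readouts.
    resolution : tuple of 3 floats
        Voxel size (x, y, z) in m.
    R : float
        Net undersampling factor relative to the fully sampled density of
        this FOV (with the elliptical-FOV convention when
        ``elliptical_fov`` is set).
    TE : float
        Echo time, s.
    overhead : float
        Per-shot non-acquisition time (excitation, fat suppression,
        spoiling), s.
    TR : float, optional
        Repetition time, s.  When omitted, TR = T_AQ + overhead.
    elliptical_fov : bool
        Reconstruction support is the ellipse inscribed in the in-plane/
        through-plane FOV rectangle of each PE cross-section.  A hexagonal
        image-domain replica cell containing that ellipse has area
        sqrt(3)/2 * FOV1 * FOV2, so the k-space cell may be 2/sqrt(3)
        larger than the Cartesian one at equal R (the packing advantage of
        hexagonal sampling).
    n_shots : int, optional
        Pin the number of shots (protocol bookkeeping); the through-plane
        scale then follows from the kz extent and the in-plane scale from
        the density constraint.
    anisotropy : float
        Ratio (scale1/dk1_full)/(scale2/dk2_full) of the per-axis
        reductions when ``n_shots`` is not given; 1 = isotropic split.
    """

    fov: tuple[float, float, float]
    resolution: tuple[float, float, float]
    R: float = 1.0
    TE: float = 0.0
    overhead: float = 0.0
    TR: Optional[float] = None
    elliptical_fov: bool = True
    n_shots: Optional[int] = None
    anisotropy: float = 1.0

    def __post_init__(self) -> None:
        self.fov = tuple(float(v) for v in self.fov)
        self.resolution = tuple(float(v) for v in self.resolution)
        if len(self.fov) != 3 or len(self.resolution) != 3:
            raise ValueError("fov and resolution must have 3 components")
        if any(v <= 0 for v in self.fov + self.resolution):
            raise ValueError("fov and resolution must be positive")
        if self.R < 1.0:
            raise ValueError("undersampling factor R must be >= 1")
        if self.anisotropy <= 0:
            raise ValueError("anisotropy must be positive")

    @property
    def kmax(self) -> tuple[float, float, float]:
        """Per-axis k-space extent 1/(2*resolution), 1/m."""
        return tuple(1.0 / (2.0 * r) for r in self.resolution)

    @property
    def delta(self) -> tuple[float, float, float]:
        """Fully sampled PE spacing 1/FOV per axis, 1/m."""
        return tuple(1.0 / f for f in self.fov)

    @property
    def hex_cell_gain(self) -> float:
        """Allowed k-space cell enlargement of hexagonal vs Cartesian."""
        return 2.0 / SQRT3 if self.elliptical_fov else 1.0


def cross_section_scales(
    geometry: SequenceGeometry, tilt: TiltIndex
) -> tuple[ShotGeometry, float, float]:
    """Unit-lattice shot geometry and the per-axis rescale factors.

    The cross-section pattern is the dk = 1 tilted hexagonal lattice with
    axis 1 scaled by ``s1`` and axis 2 (the stack axis) by ``s2``, chosen so
    that the cell area equals R * hex_cell_gain * dk1_full * dk2_full.
    """
    geom = shot_geometry(tilt, dk=1.0)
    d1, d2 = geometry.delta[1], geometry.delta[2]  # 1st PE (in-plane), stack
    target_cell = geometry.R * geometry.hex_cell_gain * d1 * d2
    s1s2 = target_cell / (SQRT3 / 2.0)
    if geometry.n_shots is not None:
        if geometry.n_shots < 1:
            raise ValueError("n_shots must be >= 1")
        h_eff = 2.0 * geometry.kmax[2] / geometry.n_shots
        s2 = h_eff / geom.h
        s1 = s1s2 / s2
    else:
        x = math.sqrt(s1s2 / (geometry.anisotropy * d1 * d2))
        s1 = geometry.anisotropy * d1 * x
        s2 = d2 * x
    return geom, s1, s2


@dataclass
class TrajectorySet:
    """A full mono-planar T-Hex trajectory: congruent shots on a stack.

    Every shot shares ``base_k``/``base_t`` (the sample positions and times
    of the base readout); shot j is the base rotated by ``rotations[j]``
    about kz (spiral) or translated by ``shifts[j]`` along ky (EPI), placed
    at ``kz[j]``, and — for EPI — delayed by ``te_shifts[j]`` so that the
    k-space-time weighting stays smooth across the stack.
    """

    kind: Literal["spiral", "epi"]
    geometry: SequenceGeometry
    tilt: TiltIndex
    shot_geom: ShotGeometry  # unit-lattice (dk = 1) geometry
    limits: SystemLimits
    d: float  # per-shot PE increment, 1/m
    h: float  # shot-to-shot kz increment, 1/m
    scale1: float
    scale2: float
    base_k: np.ndarray  # (n_samples, 2)
    base_t: np.ndarray  # (n_samples,)
    rotations: np.ndarray  # (n_shots,) rad
    shifts: np.ndarray  # (n_shots,) 1/m along ky
    kz: np.ndarray  # (n_shots,) 1/m
    te_shifts: np.ndarray  # (n_shots,) s
    waveform: GradientWaveform
    t_aq: float
    esp: Optional[float] = None
    line_of_sample: Optional[np.ndarray] = None

    @property
    def n_shots(self) -> int:
        return len(self.kz)

    @property
    def n_samples_per_shot(self) -> int:
        return len(self.base_t)

    @property
    def offset_fractions(self) -> np.ndarray:
        """Per-shot in-plane offset as a fraction of d (period L sequence)."""
        if self.kind == "spiral":
            return (self.rotations / (2.0 * math.pi)) % 1.0
        return (self.shifts / self.d) % 1.0

    def shot_samples(self, j: int) -> np.ndarray:
        """(n_samples, 3) k-space positions of shot j, 1/m."""
        if self.kind == "spiral":
            a = self.rotations[j]
            rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
            xy = self.base_k @ rot.T
        else:
            xy = self.base_k + np.array([0.0, self.shifts[j]])
        out = np.empty((len(xy), 3))
        out[:, :2] = xy
        out[:, 2] = self.kz[j]
        return out

    def shot_times(self, j: int) -> np.ndarray:
        """Sample times of shot j relative to its nominal readout start, s."""
        return self.base_t + self.te_shifts[j]

    def all_samples(self) -> np.ndarray:
        return np.concatenate([self.shot_samples(j) for j in range(self.n_shots)])

    def all_times(self) -> np.ndarray:
        return np.concatenate([self.shot_times(j) for j in range(self.n_shots)])

    def cross_section(self) -> np.ndarray:
        """(N, 2) tilted-lattice points (k1, kz) realized by the stack.

        For spirals k1 is the revolution radius at the reference azimuth
        (theta = 0 of the unrotated spiral); for EPI it is the ky line
        position.  This is the point set that must coincide with the
        :func:`thex.hexlattice.build_cross_section` pattern.
        """
        pts = []
        fr = self.offset_fractions
        if self.kind == "spiral":
            kmax = self.base_k[-1]  # end radius
            rmax = float(np.linalg.norm(kmax))
            for j in range(self.n_shots):
                n_i = int(math.floor(rmax / self.d - fr[j] + 1e-9)) + 1
                r = (np.arange(n_i) + fr[j]) * self.d
                pts.append(np.column_stack([r, np.full(n_i, self.kz[j])]))
        else:
            ky0 = float(self.base_k[:, 1].min())
            n_lines = int(round((self.base_k[:, 1].max() - ky0) / self.d)) + 1
            for j in range(self.n_shots):
                ky = ky0 + self.shifts[j] + np.arange(n_lines) * self.d
                pts.append(np.column_stack([ky, np.full(n_lines, self.kz[j])]))
        return np.concatenate(pts)


def _stack_positions(
    geometry: SequenceGeometry, geom: ShotGeometry, s1: float, s2: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-shot (offset fraction of d, centered kz) for the whole stack."""
    h_eff = geom.h * s2
    kz_extent = 2.0 * geometry.kmax[2]
    if geometry.n_shots is not None:
        n = geometry.n_shots
    else:
        n = int(math.ceil(kz_extent / h_eff - 1e-9))
    offs_unit, k2_unit = shot_offsets(geom, n)
    fr = offs_unit / geom.d  # offset fractions, independent of scaling
    kz = k2_unit * s2
    kz = kz - 0.5 * (kz[0] + kz[-1])  # symmetric about kz = 0
    return fr, kz, n


def build_spiral_stack(
    geometry: SequenceGeometry,
    tilt: TiltIndex,
    limits: SystemLimits,
    angular_oversampling: int = 512,
    adc_dwell: Optional[float] = None,
) -> TrajectorySet:
    """Design the full mono-planar T-Hex stack of spirals.

    The base Archimedean spiral is designed once with radial increment
    d = |v| * scale1 out to kmax = 1/(2*in-plane resolution) and converted
    to a time-optimal waveform; shot j is that waveform rotated by
    2*pi*(j*c/d mod 1) and shifted to kz_j.  Rotation angles progress
    linearly and repeat with period L; the kz prephaser is bookkeeping
    (generated by the scanner before the readout) and not part of T_AQ.
    """
    if abs(geometry.fov[0] - geometry.fov[1]) > 1e-12 or abs(
        geometry.resolution[0] - geometry.resolution[1]
    ) > 1e-15:
        raise ValueError("spiral readouts assume isotropic in-plane FOV/resolution")
    geom, s1, s2 = cross_section_scales(geometry, tilt)
    d_eff = geom.d * s1
    kmax = geometry.kmax[0]
    if d_eff > 2.0 * kmax:
        raise ValueError(
            f"effective radial increment {d_eff:.1f} 1/m exceeds 2*kmax = "
            f"{2 * kmax:.1f} 1/m: tilt too coarse for this resolution/R"
        )
    path = archimedean_path(d_eff, kmax, angular_oversampling)
    wf = time_optimal_waveform(path, limits)

    dwell = limits.raster if adc_dwell is None else float(adc_dwell)
    t_s = np.arange(0.0, wf.duration + 0.5 * dwell, dwell)
    t_s = t_s[t_s <= wf.duration + 1e-12]
    base_k = np.column_stack(
        [np.interp(t_s, wf.t, wf.k[:, 0]), np.interp(t_s, wf.t, wf.k[:, 1])]
    )

    fr, kz, n = _stack_positions(geometry, geom, s1, s2)
    rotations = 2.0 * math.pi * fr
    return TrajectorySet(
        kind="spiral",
        geometry=geometry,
        tilt=tilt,
        shot_geom=geom,
        limits=limits,
        d=d_eff,
        h=geom.h * s2,
        scale1=s1,
        scale2=s2,
        base_k=base_k,
        base_t=t_s,
        rotations=rotations,
        shifts=np.zeros(n),
        kz=kz,
        te_shifts=np.zeros(n),
        waveform=wf,
        t_aq=wf.duration,
    )
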