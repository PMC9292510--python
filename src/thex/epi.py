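"""Mono-planar T-Hex EPI readouts.

The EPI variant of the tilted-hexagonal stack: a serpentine echo-planar
readout with line spacing d covers each shot's kz plane; successive shots
are shifted by (j*c mod d) along ky (instead of the spiral's rotation) and
stepped by h along kz.  The echo-time shift of shot j equals the echo
spacing times the fractional in-plane shift, Delta_TE_j = esp * (c_j/d),
exactly as in conventional segmented EPI — it makes the acquisition time an
affine function of the global ky row index across the whole stack, i.e. a
smooth effective T2* filter with no interleave discontinuities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .gradients import SystemLimits, epi_train
from .hexlattice import TiltIndex
from .spiral import SequenceGeometry, TrajectorySet, _stack_positions, cross_section_scales

__all__ = ["EpiPath", "epi_path", "build_epi_stack"]


@dataclass
class EpiPath:
    """Geometric serpentine echo-planar path.

    ``samples`` traces the line vertices (alternating kx direction);
    ``esp`` is assigned after gradient design.
    """

    samples: np.ndarray
    n_lines: int
    d: float
    esp: Optional[float] = None

    @property
    def ky_extent(self) -> float:
        return (self.n_lines - 1) * self.d


def epi_path(d: float, kmax_x: float, kmax_y: float) -> EpiPath:
    """Serpentine line set covering [-kmax_y, +kmax_y] with spacing d.

    The number of lines is floor(2*kmax_y/d) + 1; lines start at
    ky = -kmax_y, so the topmost line may fall short of +kmax_y by less
    than d (the stack convention rounds coverage outward elsewhere).
    """
    if kmax_x <= 0 or kmax_y <= 0:
        raise ValueError("k-space extents must be positive")
    if d <= 0:
        raise ValueError("line spacing d must be positive")
    if d > 2.0 * kmax_y:
        raise ValueError(
            f"line spacing d = {d} exceeds the full ky extent {2 * kmax_y}"
        )
    n_lines = int(math.floor(2.0 * kmax_y / d + 1e-9)) + 1
    ky = -kmax_y + np.arange(n_lines) * d
    verts = []
    for i, y in enumerate(ky):
        x0, x1 = (-kmax_x, kmax_x) if i % 2 == 0 else (kmax_x, -kmax_x)
        verts.append((x0, y))
        verts.append((x1, y))
    return EpiPath(samples=np.array(verts, dtype=float), n_lines=n_lines, d=d)


def build_epi_stack(
    geometry: SequenceGeometry,
    tilt: TiltIndex,
    limits: SystemLimits,
    ramp_sampling: bool = True,
    adc_dwell: Optional[float] = None,
) -> TrajectorySet:
    """Design the full mono-planar T-Hex EPI stack.

    The base train is built once by :func:`thex.gradients.epi_train`; shot j
    is that train shifted by (j*c mod d) along ky, placed at kz_j, and its
    acquisition start delayed by Delta_TE_j = esp * frac(j*c/d) relative to
    the common echo-center reference.  Shifts and TE shifts repeat with
    period L.
    """
    geom, s1, s2 = cross_section_scales(geometry, tilt)
    d_eff = geom.d * s1
    kmax_x = geometry.kmax[0]
    kmax_y = geometry.kmax[1]
    if d_eff > 2.0 * kmax_y:
        raise ValueError(
            f"effective line spacing {d_eff:.1f} 1/m exceeds the ky extent "
            f"{2 * kmax_y:.1f} 1/m: tilt too coarse for this resolution/R"
        )
    n_lines = int(math.floor(2.0 * kmax_y / d_eff + 1e-9)) + 1
    readout = epi_train(
        n_lines,
        kmax_x,
        d_eff,
        limits,
        ramp_sampling=ramp_sampling,
        adc_dwell=adc_dwell,
        ky_start=-kmax_y,
    )

    fr, kz, n = _stack_positions(geometry, geom, s1, s2)
    shifts = fr * d_eff
    te_shifts = readout.esp * fr
    return TrajectorySet(
        kind="epi",
        geometry=geometry,
        tilt=tilt,
        shot_geom=geom,
        limits=limits,
        d=d_eff,
        h=geom.h * s2,
        scale1=s1,
        scale2=s2,
        base_k=readout.k_samples,
        base_t=readout.t_samples,
        rotations=np.zeros(n),
        shifts=shifts,
        kz=kz,
        te_shifts=te_shifts,
        waveform=readout.wf,
        t_aq=readout.t_aq,
        esp=readout.esp,
        line_of_sample=readout.line_of_sample,
    )
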