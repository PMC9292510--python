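"""Speed/flexibility analysis and sampling-uniformity metrics.

Reproduces the scan-time study behind the method's central claim: for a
whole-brain protocol (FOV 24 x 24 x 12 cm^3, net R = 8, 13 ms per-shot
overhead) the per-shot acquisition time T_AQ and the total scan time
n_shots * (T_AQ + overhead) are tabulated for every tilted-hexagonal stack
with d up to ~7.6 lattice constants and for conventional Cartesian-grid
stacks with integer plane segmentation N.  Hexagonal stacks encode the same
elliptical image support with a 2/sqrt(3) larger k-space cell, and the tilt
menu makes T_AQ quasi-continuous where integer N takes coarse steps.

Also provides Voronoi-based density uniformity metrics and the protocol
arithmetic (total scan time, voxel volume) used for bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError, Voronoi

from .gradients import SystemLimits
from .hexlattice import CrossSectionPattern, TiltIndex, tilt_norm
from .spiral import (
    SequenceGeometry,
    TrajectorySet,
    archimedean_path,
    cross_section_scales,
)

__all__ = [
    "StudyRecord",
    "scan_time_study",
    "study_frame",
    "density_uniformity",
    "DensityMetrics",
    "voxel_volume",
    "total_scan_time",
    "plane_time_spread",
    "cartesian_plane_time_spread",
    "epi_time_affinity",
]


@dataclass(frozen=True)
class StudyRecord:
    """One stack design evaluated by the scan-time study."""

    tilt: Optional[TiltIndex]  # None for Cartesian comparators
    cartesian_N: Optional[int]  # None for T-Hex stacks
    d_rel: float  # per-shot increment in units of the lattice constant
    n_shots: int
    t_aq: float  # per-shot acquisition time, s
    overhead: float  # per-shot overhead, s
    tr: float  # t_aq + overhead, s
    total: float  # n_shots * tr, s
    resolution: float  # in-plane voxel size, m
    feasible: bool = True

    def __post_init__(self) -> None:
        if self.feasible:
            assert abs(self.total - self.n_shots * self.tr) < 1e-12


def total_scan_time(n_shots: int, tr: float) -> float:
    """Total scan duration n_shots * TR, s (exact protocol arithmetic)."""
    if n_shots < 1 or tr <= 0:
        raise ValueError("need n_shots >= 1 and TR > 0")
    return n_shots * tr


def voxel_volume(resolution: Sequence[float]) -> float:
    """Voxel volume in nanoliters for voxel edge lengths in meters.

    1 mm^3 = 1000 nl, so e.g. 0.6 x 0.6 x 2 mm^3 -> 720 nl.
    """
    res = tuple(float(r) for r in resolution)
    if len(res) != 3 or any(r <= 0 for r in res):
        raise ValueError("resolution must be 3 positive edge lengths in m")
    return float(np.prod(res)) * 1e12  # m^3 -> nl


def _traversal_time(path, limits: SystemLimits) -> float:
    """Minimal traversal time of a smooth path (no raster resampling)."""
    from .gradients import _G_MARGIN, _S_MARGIN, _speed_sweeps

    pts = np.asarray(getattr(path, "samples", path), dtype=float)
    seg = np.diff(pts, axis=0)
    ds = np.linalg.norm(seg, axis=1)
    tang = seg / ds[:, None]
    kappa = np.zeros(len(pts))
    dtang = np.linalg.norm(np.diff(tang, axis=0), axis=1)
    kappa[1:-1] = dtang / (0.5 * (ds[:-1] + ds[1:]))
    kappa[0], kappa[-1] = kappa[1], kappa[-2]
    vamp = _G_MARGIN * limits.kspeed
    aslew = _S_MARGIN * limits.kslew
    with np.errstate(divide="ignore"):
        vcurv = np.sqrt(np.where(kappa > 0, aslew / np.maximum(kappa, 1e-300), np.inf))
    vmax2 = np.minimum(vamp, vcurv) ** 2
    v = np.sqrt(_speed_sweeps(vmax2, kappa, ds, aslew))
    vmid = np.maximum(0.5 * (v[:-1] + v[1:]), math.sqrt(0.5 * aslew * ds.min()))
    return float(np.sum(ds / vmid))


def scan_time_study(
    geometry: SequenceGeometry,
    tilts: Iterable[TiltIndex],
    cartesian_Ns: Iterable[int],
    limits: SystemLimits,
    overhead: Optional[float] = None,
    resolutions: Optional[Sequence[float]] = None,
) -> list[StudyRecord]:
    """Tabulate (T_AQ, total scan time) for T-Hex and Cartesian stacks.

    For each in-plane resolution and each tilt, the hexagonal stack is laid
    out with the isotropic density split of :func:`cross_section_scales`
    and its spiral readout duration computed under the gradient limits.
    Cartesian comparators segment each fully-stacked plane into N
    interleaves on a rectangular PE grid with the same net R but without
    the elliptical-support cell gain (a rectangular image-domain cell
    containing the FOV ellipse cannot be smaller than the FOV rectangle).
    Infeasible designs are flagged, not dropped.
    """
    oh = geometry.overhead if overhead is None else float(overhead)
    if oh < 0:
        raise ValueError("overhead must be non-negative")
    res_list = (
        [geometry.resolution[0]] if resolutions is None else [float(r) for r in resolutions]
    )
    records: list[StudyRecord] = []
    for res in res_list:
        geo = replace(
            geometry, resolution=(res, res, geometry.resolution[2]), overhead=oh
        )
        kmax = geo.kmax[0]
        kz_extent = 2.0 * geo.kmax[2]
        for tilt in tilts:
            geom, s1, s2 = cross_section_scales(geo, tilt)
            d_eff = geom.d * s1
            h_eff = geom.h * s2
            if d_eff > 2.0 * kmax:
                records.append(
                    StudyRecord(tilt, None, tilt_norm(tilt), 0, math.nan, oh,
                                math.nan, math.nan, res, feasible=False)
                )
                continue
            t_aq = _traversal_time(archimedean_path(d_eff, kmax, 128), limits)
            n_shots = int(math.ceil(kz_extent / h_eff - 1e-9))
            tr = t_aq + oh
            records.append(
                StudyRecord(tilt, None, tilt_norm(tilt), n_shots, t_aq, oh, tr,
                            total_scan_time(n_shots, tr), res)
            )
        # Cartesian comparators: rectangular PE grid, isotropic split of R
        d1, d2 = geo.delta[1], geo.delta[2]
        delta1 = math.sqrt(geo.R) * d1
        delta2 = math.sqrt(geo.R) * d2
        planes = int(math.ceil(kz_extent / delta2 - 1e-9))
        for N in cartesian_Ns:
            if N < 1:
                raise ValueError("Cartesian segmentation N must be >= 1")
            d_eff = N * delta1
            if d_eff > 2.0 * kmax:
                records.append(
                    StudyRecord(None, N, d_eff / d1, 0, math.nan, oh, math.nan,
                                math.nan, res, feasible=False)
                )
                continue
            t_aq = _traversal_time(archimedean_path(d_eff, kmax, 128), limits)
            n_shots = N * planes
            tr = t_aq + oh
            records.append(
                StudyRecord(None, N, d_eff / d1, n_shots, t_aq, oh, tr,
                            total_scan_time(n_shots, tr), res)
            )
    return records


def study_frame(records: Sequence[StudyRecord]):
    """Study records as a pandas DataFrame (one record per row)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "family": ["thex" if r.tilt is not None else "cartesian" for r in records],
            "M1": [r.tilt.m1 if r.tilt else None for r in records],
            "M2": [r.tilt.m2 if r.tilt else None for r in records],
            "N": [r.cartesian_N for r in records],
            "d_rel": [r.d_rel for r in records],
            "resolution_m": [r.resolution for r in records],
            "n_shots": [r.n_shots for r in records],
            "t_aq_s": [r.t_aq for r in records],
            "overhead_s": [r.overhead for r in records],
            "tr_s": [r.tr for r in records],
            "total_s": [r.total for r in records],
            "feasible": [r.feasible for r in records],
        }
    )


@dataclass(frozen=True)
class DensityMetrics:
    mean_area: float
    cv: float
    n_interior: int


def density_uniformity(pattern: CrossSectionPattern | np.ndarray) -> DensityMetrics:
    """Mean and coefficient of variation of interior Voronoi cell areas.

    Interior cells are those whose Voronoi vertices all lie strictly inside
    the convex hull of the point set, so boundary-truncated cells do not
    contaminate the uniformity estimate.  A perfect (tilted, rescaled)
    lattice has CV ~ 0 to machine precision — tilting is an isometry and
    rescaling a linear map, neither of which perturbs relative cell areas.
    """
    pts = pattern.points if isinstance(pattern, CrossSectionPattern) else np.asarray(pattern)
    if len(pts) < 10:
        raise ValueError("need at least 10 points for uniformity metrics")
    try:
        vor = Voronoi(pts)
        tri = Delaunay(pts)
    except QhullError as err:
        raise ValueError(f"degenerate (collinear?) pattern: {err}") from err
    areas = []
    for p_idx, r_idx in enumerate(vor.point_region):
        region = vor.regions[r_idx]
        if not region or -1 in region:
            continue
        verts = vor.vertices[region]
        if np.any(tri.find_simplex(verts) < 0):
            continue  # cell pokes outside the hull: boundary cell
        # convex cell: order vertices by angle for the shoelace formula
        ctr = verts.mean(axis=0)
        order = np.argsort(np.arctan2(verts[:, 1] - ctr[1], verts[:, 0] - ctr[0]))
        v = verts[order]
        x, y = v[:, 0], v[:, 1]
        areas.append(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    if len(areas) < 10:
        raise ValueError(
            f"only {len(areas)} interior Voronoi cells; pattern too small"
        )
    areas = np.asarray(areas)
    mean = float(areas.mean())
    return DensityMetrics(mean_area=mean, cv=float(areas.std() / mean), n_interior=len(areas))


# ---------------------------------------------------------------------------
# T2*-filter smoothness


def plane_time_spread(traj: TrajectorySet, tr: Optional[float] = None) -> float:
    """Largest acquisition-time spread within any single kz position, s.

    Shot j starts at j*TR; each cross-section point's absolute acquisition
    time is the shot start plus the within-shot time at its radius (spiral)
    or line (EPI).  Mono-planar T-Hex visits every kz exactly once, so the
    spread within a kz group is at most one readout duration — the smooth
    T2* filter.  Integer-N interleaved stacks revisit each plane N times,
    spreading a plane's weighting over ~N*TR (see
    :func:`cartesian_plane_time_spread`).
    """
    if tr is None:
        tr = traj.t_aq + traj.geometry.overhead
    # group shots that share a kz position (non-primitive tilts)
    kz_round = np.round(traj.kz / max(traj.h, 1e-300) * 1e6)
    spread_by_kz: dict[float, list[float]] = {}
    for j in range(traj.n_shots):
        spread_by_kz.setdefault(kz_round[j], []).append(j)
    worst = 0.0
    for shots in spread_by_kz.values():
        tmin = min(j * tr + traj.shot_times(j).min() for j in shots)
        tmax = max(j * tr + traj.shot_times(j).max() for j in shots)
        worst = max(worst, tmax - tmin)
    return worst


def cartesian_plane_time_spread(
    geometry: SequenceGeometry, N: int, limits: SystemLimits, tr: Optional[float] = None
) -> float:
    """Within-plane acquisition-time spread of an N-interleave stack, s.

    Negative control for the smooth-filter property: a plane covered by N
    consecutive interleaved shots (radial increment N * delta1) collects
    samples over (N-1)*TR plus one readout, so for N >= 2 the spread
    exceeds one shot duration.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    delta1 = math.sqrt(geometry.R) * geometry.delta[1]
    d_eff = N * delta1
    kmax = geometry.kmax[0]
    t_aq = _traversal_time(archimedean_path(d_eff, kmax, 128), limits)
    if tr is None:
        tr = t_aq + geometry.overhead
    return (N - 1) * tr + t_aq


def epi_time_affinity(traj: TrajectorySet) -> float:
    """Max deviation of line acquisition times from an affine law in ky, s.

    With the echo-time shifts applied, the time at which a ky lattice row is
    crossed is esp*(ky - ky0)/d across the entire stack — an exactly affine
    k-space-time relation (the EPI analog of the smooth T2* filter).
    Returns the largest absolute residual of the affine fit.
    """
    if traj.kind != "epi" or traj.esp is None:
        raise ValueError("requires an EPI trajectory")
    ky0 = float(traj.base_k[:, 1].min())
    n_lines = int(round((traj.base_k[:, 1].max() - ky0) / traj.d)) + 1
    kys, ts = [], []
    for j in range(traj.n_shots):
        for i in range(n_lines):
            kys.append(ky0 + traj.shifts[j] + i * traj.d)
            ts.append(traj.te_shifts[j] + i * traj.esp)
    kys = np.asarray(kys)
    ts = np.asarray(ts)
    coeff = np.polyfit(kys, ts, 1)
    return float(np.abs(ts - np.polyval(coeff, kys)).max())
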