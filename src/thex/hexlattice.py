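"""Tilted hexagonal phase-encode lattices.

Fast 3D sequences stack planar readouts (spirals, EPI) along a second
phase-encode (PE) axis; the readout increments (spiral radii, EPI line
positions) together with the stack positions form a 2D lattice in the
cross-section spanned by the 1st PE axis (k1, the in-plane increment
direction) and the 2nd PE axis (k2, the stack axis).  Sampling that
cross-section on a hexagonal lattice is denser-packing than Cartesian
sampling, and *tilting* the hexagonal lattice so that an arbitrary lattice
vector v = M1*e1 + M2*e2 is orthogonal to the stack axis makes the per-shot
increment d = |v| a free, non-integer multiple of the lattice constant.
That converts the integer choice "N interleaves per plane" into a dense
menu of fractional segmentations while keeping exactly uniform density.

Conventions
-----------
* Basis: e1 = dk*(1, 0), e2 = dk*(1/2, sqrt(3)/2); dk is the
  nearest-neighbor spacing, so the primitive cell area is dk^2*sqrt(3)/2.
* Tilt indices live in the first dodecant, M1 >= M2 >= 0, (M1, M2) != (0, 0);
  all pairwise lattice distances are realized there.
* After tilting, shot lines run along the k1 axis with per-shot spacing d,
  successive shots step h = dk^2*sqrt(3)/(2*d) along k2 (primitive-cell area
  divided by d, which preserves density), and the in-plane offset advances
  by c per shot, canonicalized to [0, d).  The offset sequence
  (j*c mod d) repeats with period L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from math import gcd, sqrt
import numpy as np

__all__ = [
    "HexLattice",
    "TiltIndex",
    "ShotGeometry",
    "CrossSectionPattern",
    "RectSupport",
    "EllipseSupport",
    "lattice_vector",
    "tilt_norm",
    "enumerate_tilts",
    "repetition_length",
    "shot_geometry",
    "shot_offsets",
    "build_cross_section",
    "rescale_crop",
    "pattern_to_frame",
    "write_pattern_csv",
    "read_pattern_csv",
]

#: relative tolerance for on-boundary decisions, in units of the local spacing
BOUNDARY_RTOL = 1e-9


@dataclass(frozen=True)
class HexLattice:
    """Hexagonal lattice in the PE cross-section plane.

    Parameters
    ----------
    dk : float
        Lattice constant (nearest-neighbor spacing), 1/m.
    """

    dk: float

    def __post_init__(self) -> None:
        if not self.dk > 0:
            raise ValueError(f"lattice constant dk must be positive, got {self.dk}")

    @property
    def e1(self) -> np.ndarray:
        return self.dk * np.array([1.0, 0.0])

    @property
    def e2(self) -> np.ndarray:
        return self.dk * np.array([0.5, sqrt(3.0) / 2.0])

    @property
    def cell_area(self) -> float:
        """Primitive cell area dk^2*sqrt(3)/2 (one point per this area)."""
        return self.dk**2 * sqrt(3.0) / 2.0


@dataclass(frozen=True, order=True)
class TiltIndex:
    """Integer pair selecting the tilt vector v = M1*e1 + M2*e2.

    Valid tilts lie in the first dodecant of the lattice: M1 >= M2 >= 0 and
    (M1, M2) != (0, 0); by symmetry every pairwise lattice distance is
    realized by exactly one such pair.
    """

    m1: int
    m2: int

    def __post_init__(self) -> None:
        if self.m1 != int(self.m1) or self.m2 != int(self.m2):
            raise ValueError("tilt indices must be integers")
        if self.m2 < 0 or self.m1 < self.m2 or (self.m1, self.m2) == (0, 0):
            raise ValueError(
                f"tilt ({self.m1}, {self.m2}) outside the first dodecant: "
                "require M1 >= M2 >= 0 and (M1, M2) != (0, 0)"
            )

    @property
    def g(self) -> int:
        """gcd of the indices; g > 1 marks a non-primitive tilt."""
        return gcd(self.m1, self.m2)

    @property
    def is_primitive(self) -> bool:
        return self.g == 1


def tilt_norm(tilt: TiltIndex) -> float:
    """|v|/dk = sqrt(M1^2 + M1*M2 + M2^2) (hexagonal quadratic form)."""
    return sqrt(tilt.m1**2 + tilt.m1 * tilt.m2 + tilt.m2**2)


def lattice_vector(tilt: TiltIndex, dk: float) -> tuple[np.ndarray, float]:
    """Tilt vector v = M1*e1 + M2*e2 in Cartesian cross-section coordinates.

    Returns
    -------
    v : ndarray, shape (2,)
    d : float
        Its length, dk*sqrt(M1^2 + M1*M2 + M2^2); this is the per-shot PE
        increment after tilting.
    """
    lat = HexLattice(dk)
    v = tilt.m1 * lat.e1 + tilt.m2 * lat.e2
    return v, dk * tilt_norm(tilt)


def enumerate_tilts(dmax_rel: float) -> list[TiltIndex]:
    """All dodecant tilts with |v| <= dmax_rel * dk, sorted by distance.

    Ties are broken by ascending M2.  ``dmax_rel`` must admit at least the
    nearest-neighbor tilt (1, 0).
    """
    if dmax_rel < 1.0:
        raise ValueError(
            f"dmax_rel = {dmax_rel} < 1 admits no tilt: the shortest lattice "
            "vector has length 1 dk (tilt (1, 0))"
        )
    mmax = int(math.floor(dmax_rel)) + 1
    out: list[TiltIndex] = []
    for m1 in range(1, mmax + 1):
        for m2 in range(0, m1 + 1):
            t = TiltIndex(m1, m2)
            if tilt_norm(t) <= dmax_rel * (1.0 + BOUNDARY_RTOL):
                out.append(t)
    out.sort(key=lambda t: (tilt_norm(t), t.m2))
    return out


def repetition_length(tilt: TiltIndex) -> int:
    """Number of shots after which the in-plane offset sequence repeats.

    L = 2*(M1^2 + M2^2 + M1*M2) / gcd(2*M2 + M1, 2*M1 + M2).  This equals
    the period of the sequence ((j*c) mod d), j = 0, 1, 2, ...
    """
    num = 2 * (tilt.m1**2 + tilt.m2**2 + tilt.m1 * tilt.m2)
    den = gcd(2 * tilt.m2 + tilt.m1, 2 * tilt.m1 + tilt.m2)
    L, rem = divmod(num, den)
    assert rem == 0, "repetition length is integral by construction"
    return L


def _extended_gcd(a: int, b: int) -> tuple[int, int, int]:
    """Return (g, x, y) with a*x + b*y = g = gcd(a, b)."""
    old_r, r = a, b
    old_x, x = 1, 0
    old_y, y = 0, 1
    while r != 0:
        q = old_r // r
        old_r, r = r, old_r - q * r
        old_x, x = x, old_x - q * x
        old_y, y = y, old_y - q * y
    return old_r, old_x, old_y


@dataclass(frozen=True)
class ShotGeometry:
    """Derived per-shot cross-section geometry for a tilted lattice.

    Attributes
    ----------
    tilt : TiltIndex
    dk : float
        Lattice constant, 1/m.
    d : float
        Per-shot PE increment |v| (spiral radial increment per revolution /
        EPI line spacing), 1/m.
    h : float
        Shot-to-shot increment along the stack (2nd PE) axis, 1/m.  Equals
        the primitive cell area divided by d, which keeps the sampling
        density exactly one point per dk^2*sqrt(3)/2.
    c : float
        In-plane shift per shot along the 1st PE axis, canonical in [0, d).
    L : int
        Repetition length of the offset sequence (j*c mod d).
    phase_increment : float
        2*pi*c/d, the spiral rotation increment per shot, rad.
    """

    tilt: TiltIndex
    dk: float
    d: float
    h: float
    c: float
    L: int
    phase_increment: float

    @property
    def g(self) -> int:
        return self.tilt.g

    @property
    def frac(self) -> float:
        """Offset fraction c/d (a rational with denominator L)."""
        return self.c / self.d


def shot_geometry(tilt: TiltIndex, dk: float) -> ShotGeometry:
    """Compute (d, h, c, L) for a tilt.

    The shift ``c`` is the 1st-PE projection of a lattice vector ``w`` whose
    projection onto the axis normal to v equals -g*h (the smallest normal
    step the lattice admits; g = gcd(M1, M2) = 1 for the primitive tilts the
    method uses in practice).  ``w`` is found by solving the Bezout identity
    M1*b - M2*a = -g over integer combinations w = a*e1 + b*e2.

    For non-primitive tilts (g > 1) the lattice rows orthogonal to v sit at
    spacing g*h and carry g interleaved shots each, with points along a
    single shot line spaced d/g; such tilts are supported for completeness
    but are redundant designs (equivalent to their primitive part, rescaled).
    """
    if dk <= 0:
        raise ValueError(f"lattice constant dk must be positive, got {dk}")
    lat = HexLattice(dk)
    v, d = lattice_vector(tilt, dk)
    h = lat.cell_area / d
    g = tilt.g
    # Solve m1*b - m2*a = -g  <=>  (-m2)*a + m1*b = -g.
    gg, x, y = _extended_gcd(-tilt.m2, tilt.m1)
    # gg = +-g; scale the Bezout pair to hit -g exactly.
    s = -g // gg
    a, b = x * s, y * s
    assert tilt.m1 * b - tilt.m2 * a == -g
    w = a * lat.e1 + b * lat.e2
    c = float(np.dot(w, v) / d) % d
    L = repetition_length(tilt)
    return ShotGeometry(
        tilt=tilt,
        dk=dk,
        d=d,
        h=h,
        c=c,
        L=L,
        phase_increment=2.0 * math.pi * c / d,
    )


def shot_offsets(geom: ShotGeometry, n_shots: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-shot (k1 offset, k2 position) for ``n_shots`` consecutive shots.

    For primitive tilts shot j sits at k2 = j*h with in-plane offset
    (j*c) mod d.  For non-primitive tilts (g > 1) shots are grouped g per
    lattice row: row r at k2 = r*g*h carries g shots offset by multiples of
    d/g on top of the row offset (r*c) mod d, so that the union of shots is
    exactly the tilted hexagonal lattice.
    """
    if n_shots < 1:
        raise ValueError("n_shots must be >= 1")
    j = np.arange(n_shots)
    g = geom.g
    if g == 1:
        offs = (j * geom.c) % geom.d
        k2 = j * geom.h
    else:
        row, m = np.divmod(j, g)
        offs = (row * geom.c + m * geom.d / g) % geom.d
        k2 = row * (g * geom.h)
    return offs, k2


@dataclass(frozen=True)
class RectSupport:
    """Half-open rectangle [k1min, k1max) x [k2min, k2max)."""

    k1min: float
    k1max: float
    k2min: float
    k2max: float

    def contains(self, pts: np.ndarray, tol1: float, tol2: float) -> np.ndarray:
        k1, k2 = pts[:, 0], pts[:, 1]
        return (
            (k1 >= self.k1min - tol1)
            & (k1 < self.k1max - tol1)
            & (k2 >= self.k2min - tol2)
            & (k2 < self.k2max - tol2)
        )

    @property
    def area(self) -> float:
        return (self.k1max - self.k1min) * (self.k2max - self.k2min)


@dataclass(frozen=True)
class EllipseSupport:
    """Ellipse with semi-axes (a, b); boundary points are kept."""

    a: float
    b: float
    center: tuple[float, float] = (0.0, 0.0)

    def contains(self, pts: np.ndarray, tol1: float, tol2: float) -> np.ndarray:
        del tol1, tol2
        r2 = ((pts[:, 0] - self.center[0]) / self.a) ** 2 + (
            (pts[:, 1] - self.center[1]) / self.b
        ) ** 2
        return r2 <= 1.0 + BOUNDARY_RTOL

    @property
    def area(self) -> float:
        return math.pi * self.a * self.b


@dataclass
class CrossSectionPattern:
    """Point set of the (possibly rescaled/cropped) tilted cross-section.

    ``points[i]`` = (k1, k2) in 1/m, with ``shot_id[i]`` the shot it belongs
    to and ``within_shot_index[i]`` its index along the shot line.
    """

    points: np.ndarray
    shot_id: np.ndarray
    within_shot_index: np.ndarray
    geometry: ShotGeometry
    scale1: float = 1.0
    scale2: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.shot_id = np.asarray(self.shot_id, dtype=int)
        self.within_shot_index = np.asarray(self.within_shot_index, dtype=int)
        if not (len(self.points) == len(self.shot_id) == len(self.within_shot_index)):
            raise ValueError("points, shot_id, within_shot_index must align")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_shots(self) -> int:
        return int(self.shot_id.max()) + 1 if len(self) else 0

    @property
    def cell_area(self) -> float:
        """Area per point of the (rescaled) lattice."""
        return HexLattice(self.geometry.dk).cell_area * self.scale1 * self.scale2


def build_cross_section(
    geom: ShotGeometry,
    extent1: tuple[float, float],
    extent2: tuple[float, float],
) -> CrossSectionPattern:
    """Generate the tilted lattice restricted to half-open k-ranges.

    Shot lines are placed at k2 = j*h (grouped for non-primitive tilts, see
    :func:`shot_offsets`) for all shots falling in ``extent2``; each line
    holds points k1 = i*d + offset_j for i covering ``extent1``.  Ranges are
    half-open, [min, max), with a 1e-9*spacing boundary tolerance, so point
    counts are deterministic.
    """
    lo1, hi1 = map(float, extent1)
    lo2, hi2 = map(float, extent2)
    if not (hi1 > lo1 and hi2 > lo2):
        raise ValueError("extents must have positive length (degenerate range)")
    d, h = geom.d, geom.h
    tol1 = BOUNDARY_RTOL * d
    tol2 = BOUNDARY_RTOL * h
    # enumerate candidate shots: k2 = j*h (or grouped); generate a generous
    # j-range then filter by the half-open extent.
    jlo = int(math.floor((lo2 - tol2) / h)) - 2 * geom.g
    jhi = int(math.ceil((hi2 + tol2) / h)) + 2 * geom.g
    j_all = np.arange(jlo, jhi + 1)
    offs_all, k2_all = _offsets_for(geom, j_all)
    keep_shot = (k2_all >= lo2 - tol2) & (k2_all < hi2 - tol2)

    pts, sids, widx = [], [], []
    sid = 0
    for off, k2 in zip(offs_all[keep_shot], k2_all[keep_shot]):
        i_lo = int(math.ceil((lo1 - off - tol1) / d))
        # half-open upper edge: exclude k1 within tol of hi1
        i_hi = int(math.floor((hi1 - off - tol1) / d))
        i = np.arange(i_lo, i_hi + 1)
        k1 = i * d + off
        if len(i):
            pts.append(np.column_stack([k1, np.full(len(k1), k2)]))
            sids.append(np.full(len(k1), sid))
            widx.append(i - i[0])
        sid += 1
    if not pts:
        raise ValueError("no lattice points fall inside the requested extents")
    return CrossSectionPattern(
        points=np.concatenate(pts),
        shot_id=np.concatenate(sids),
        within_shot_index=np.concatenate(widx),
        geometry=geom,
    )


def g_step(geom: ShotGeometry) -> float:
    """k2 step between shot groups for non-primitive tilts (g*h)."""
    return geom.g * geom.h


def _offsets_for(geom: ShotGeometry, j: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Offsets/k2 for arbitrary (possibly negative) shot indices j."""
    g = geom.g
    if g == 1:
        return (j * geom.c) % geom.d, j * geom.h
    row, m = np.divmod(j, g)
    return (row * geom.c + m * geom.d / g) % geom.d, row * (g * geom.h)


def rescale_crop(
    pattern: CrossSectionPattern,
    scale1: float,
    scale2: float,
    support: RectSupport | EllipseSupport | None = None,
) -> CrossSectionPattern:
    """Anisotropically rescale the pattern and crop it to a support region.

    The sampling density requirement is generally anisotropic (FOV and coil
    acceleration differ between the two PE axes), so the tilted pattern is
    rescaled per-axis and then cropped to the k-space region the protocol
    needs.  Rectangular crops are half-open (lower/left boundary kept);
    elliptical crops keep boundary points.  Shots left without points are
    dropped and shot ids compacted in order.
    """
    if scale1 <= 0 or scale2 <= 0:
        raise ValueError("scales must be positive")
    pts = pattern.points * np.array([scale1, scale2])
    if support is None:
        keep = np.ones(len(pts), dtype=bool)
    else:
        tol1 = BOUNDARY_RTOL * pattern.geometry.d * scale1
        tol2 = BOUNDARY_RTOL * pattern.geometry.h * scale2
        keep = support.contains(pts, tol1, tol2)
    if not keep.any():
        raise ValueError("no points survive the crop: support smaller than one cell")
    pts = pts[keep]
    sid = pattern.shot_id[keep]
    widx = pattern.within_shot_index[keep]
    # compact shot ids preserving order
    uniq = np.unique(sid)
    remap = {int(s): i for i, s in enumerate(uniq)}
    sid = np.array([remap[int(s)] for s in sid])
    return CrossSectionPattern(
        points=pts,
        shot_id=sid,
        within_shot_index=widx,
        geometry=pattern.geometry,
        scale1=pattern.scale1 * scale1,
        scale2=pattern.scale2 * scale2,
    )


def pattern_to_frame(pattern: CrossSectionPattern):
    """Pattern as a pandas DataFrame (shot_id, within_shot_index, k1, k2)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "shot_id": pattern.shot_id,
            "within_shot_index": pattern.within_shot_index,
            "k1": pattern.points[:, 0],
            "k2": pattern.points[:, 1],
        }
    )


def write_pattern_csv(pattern: CrossSectionPattern, path) -> None:
    pattern_to_frame(pattern).to_csv(path, index=False, float_format="%.17g")


def read_pattern_csv(path, geometry: ShotGeometry) -> CrossSectionPattern:
    import pandas as pd

    df = pd.read_csv(path)
    return CrossSectionPattern(
        points=np.column_stack([df["k1"].to_numpy(), df["k2"].to_numpy()]),
        shot_id=df["shot_id"].to_numpy(),
        within_shot_index=df["within_shot_index"].to_numpy(),
        geometry=geometry,
    )
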