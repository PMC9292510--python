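"""Hand-written Kaiser-Bessel gridding NUFFT (type-2 forward / adjoint).

Implements the standard gridding pipeline — deapodization, oversampled FFT,
and Kaiser-Bessel interpolation onto/from arbitrary 3D k-space positions —
with a 2x oversampled grid and a width-10 kernel (aliasing error well below
1e-6 relative, verified against a brute-force DFT oracle in the tests).
The spreading/interpolation inner loops are JIT-compiled with numba.

Conventions
-----------
* Image array ``x`` has shape (nx, ny, nz); voxel indices are centered, so
  voxel n sits at position (n - N//2) in voxel units.
* k-space coordinates are given in *cycles per voxel-grid unit*, i.e. the
  dimensionless quantity k_phys * FOV / N in [-0.5, 0.5).  Use
  :func:`normalize_coords` to convert physical 1/m coordinates.
* The forward model is s(k) = sum_n x_n * exp(-2*pi*i * k . n_centered);
  ``adjoint`` applies the conjugate transpose exactly (dot-product test to
  machine precision), not a density-compensated inverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit, prange

__all__ = ["GriddingNufft", "direct_dft", "direct_dft_adjoint", "normalize_coords"]


def normalize_coords(k: np.ndarray, fov: Sequence[float], shape: Sequence[int]) -> np.ndarray:
    """Physical k-space (1/m) -> dimensionless cycles/grid-unit in [-0.5, 0.5).

    A Cartesian lattice at spacing 1/FOV maps to integer multiples of 1/N.
    """
    k = np.asarray(k, dtype=float)
    out = k * (np.asarray(fov, dtype=float) / np.asarray(shape, dtype=float))
    if np.any(np.abs(out) > 0.5 + 1e-9):
        raise ValueError("k-space coordinates exceed the Nyquist box [-0.5, 0.5)")
    return out


@njit(cache=True)
def _kb(u: float, beta: float, halfw: float) -> float:
    """Kaiser-Bessel kernel value at offset u (grid units), I0 via series."""
    if abs(u) >= halfw:
        return 0.0
    t = beta * math.sqrt(1.0 - (u / halfw) ** 2)
    # modified Bessel I0(t) by power series (t <= ~13 for our beta)
    s = 1.0
    term = 1.0
    for i in range(1, 120):
        term *= (t / (2.0 * i)) ** 2
        s += term
        if term < 1e-16 * s:
            break
    return s


@njit(cache=True)
def _weights_1d(g0: float, start: int, beta: float, width: int, out) -> None:
    """Separable kernel weights for the ``width`` grid lines nearest g0."""
    halfw = width / 2.0
    for i in range(width):
        out[i] = _kb(start + i - g0, beta, halfw)


@njit(cache=True)
def _spread(coords, vals, grid_r, grid_i, beta, width, nx, ny, nz):
    # serial over samples: neighborhoods overlap, so a parallel loop would
    # race on the accumulation grid
    halfw = width / 2.0
    wx = np.empty(width)
    wy = np.empty(width)
    wz = np.empty(width)
    for m in range(coords.shape[0]):
        gx = coords[m, 0]
        gy = coords[m, 1]
        gz = coords[m, 2]
        vr = vals[m].real
        vi = vals[m].imag
        x0 = int(math.ceil(gx - halfw))
        y0 = int(math.ceil(gy - halfw))
        z0 = int(math.ceil(gz - halfw))
        _weights_1d(gx, x0, beta, width, wx)
        _weights_1d(gy, y0, beta, width, wy)
        _weights_1d(gz, z0, beta, width, wz)
        for a in range(width):
            if wx[a] == 0.0:
                continue
            iix = (x0 + a) % nx
            for b in range(width):
                wxy = wx[a] * wy[b]
                if wxy == 0.0:
                    continue
                iiy = (y0 + b) % ny
                for c in range(width):
                    w = wxy * wz[c]
                    if w == 0.0:
                        continue
                    iiz = (z0 + c) % nz
                    grid_r[iix, iiy, iiz] += w * vr
                    grid_i[iix, iiy, iiz] += w * vi


@njit(parallel=True, cache=True)
def _interp(coords, grid, out, beta, width, nx, ny, nz):
    halfw = width / 2.0
    for m in prange(coords.shape[0]):
        gx = coords[m, 0]
        gy = coords[m, 1]
        gz = coords[m, 2]
        x0 = int(math.ceil(gx - halfw))
        y0 = int(math.ceil(gy - halfw))
        z0 = int(math.ceil(gz - halfw))
        wx = np.empty(width)
        wy = np.empty(width)
        wz = np.empty(width)
        _weights_1d(gx, x0, beta, width, wx)
        _weights_1d(gy, y0, beta, width, wy)
        _weights_1d(gz, z0, beta, width, wz)
        acc = 0.0 + 0.0j
        for a in range(width):
            if wx[a] == 0.0:
                continue
            iix = (x0 + a) % nx
            for b in range(width):
                wxy = wx[a] * wy[b]
                if wxy == 0.0:
                    continue
                iiy = (y0 + b) % ny
                for c in range(width):
                    if wz[c] == 0.0:
                        continue
                    acc += (wxy * wz[c]) * grid[iix, iiy, (z0 + c) % nz]
        out[m] = acc


@dataclass
class GriddingNufft:
    """Type-2 NUFFT (image -> nonuniform k) and its exact adjoint.

    Parameters
    ----------
    shape : image dimensions (nx, ny, nz)
    coords : (M, 3) dimensionless k coordinates in [-0.5, 0.5)
    oversamp : grid oversampling factor (default 2.0)
    width : kernel full width in oversampled grid units (default 10; wide
        enough that the aliasing error sits well below 1e-6 relative)
    """

    shape: tuple[int, int, int]
    coords: np.ndarray
    oversamp: float = 2.0
    width: int = 10

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        if len(self.shape) != 3:
            raise ValueError("shape must be 3D")
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError("coords must be (M, 3)")
        if np.any(np.abs(c) > 0.5 + 1e-9):
            raise ValueError("coords must lie in [-0.5, 0.5)")
        self.grid_shape = tuple(
            int(math.ceil(self.oversamp * n / 2) * 2) for n in self.shape
        )
        # standard beta choice for KB gridding at this oversampling
        a = self.oversamp
        self.beta = math.pi * math.sqrt(
            (self.width / a * (a - 0.5)) ** 2 - 0.8
        )
        # fractional grid coordinates on the oversampled grid
        self._gc = np.ascontiguousarray(c * np.asarray(self.grid_shape, dtype=float))
        self._deapod = self._deapodization()

    # -- internals ---------------------------------------------------------
    def _deapodization(self) -> np.ndarray:
        """Separable inverse kernel transform on the image grid."""
        facs = []
        halfw = self.width / 2.0
        for n, ng in zip(self.shape, self.grid_shape):
            # discrete FT of the sampled kernel, evaluated on image voxels
            u = np.arange(-int(math.floor(halfw)), int(math.floor(halfw)) + 1)
            w = np.array([_kb(float(ui), self.beta, halfw) for ui in u])
            x = (np.arange(n) - n // 2) / ng  # image coordinate / grid size
            ft = (w[None, :] * np.cos(2 * np.pi * np.outer(x, u))).sum(axis=1)
            facs.append(1.0 / ft)
        fx, fy, fz = facs
        return fx[:, None, None] * fy[None, :, None] * fz[None, None, :]

    # -- public ops --------------------------------------------------------
    def forward(self, image: np.ndarray) -> np.ndarray:
        """Sample s(k) = sum_n x_n exp(-2 pi i k.n) at the stored coords."""
        if image.shape != self.shape:
            raise ValueError(f"image shape {image.shape} != {self.shape}")
        nx, ny, nz = self.grid_shape
        x = image.astype(np.complex128) * self._deapod
        pad = np.zeros(self.grid_shape, dtype=np.complex128)
        sl = tuple(
            slice(ng // 2 - n // 2, ng // 2 - n // 2 + n)
            for n, ng in zip(self.shape, self.grid_shape)
        )
        pad[sl] = x
        spec = np.fft.fftn(np.fft.ifftshift(pad))
        out = np.empty(len(self._gc), dtype=np.complex128)
        _interp(self._gc, np.ascontiguousarray(spec), out, self.beta, self.width, nx, ny, nz)
        return out

    def adjoint(self, data: np.ndarray) -> np.ndarray:
        """Exact conjugate-transpose of :meth:`forward`."""
        data = np.asarray(data, dtype=np.complex128)
        if data.shape != (len(self._gc),):
            raise ValueError("data length mismatch")
        nx, ny, nz = self.grid_shape
        gr = np.zeros(self.grid_shape, dtype=np.float64)
        gi = np.zeros(self.grid_shape, dtype=np.float64)
        _spread(self._gc, data, gr, gi, self.beta, self.width, nx, ny, nz)
        grid = gr + 1j * gi
        img = np.fft.fftshift(np.fft.ifftn(grid)) * np.prod(self.grid_shape)
        sl = tuple(
            slice(ng // 2 - n // 2, ng // 2 - n // 2 + n)
            for n, ng in zip(self.shape, self.grid_shape)
        )
        return img[sl] * self._deapod


def direct_dft(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Brute-force type-2 DFT oracle: s(k) = sum_n x_n exp(-2 pi i k.n).

    O(M * N^3); intended for grids up to ~16^3 in tests.
    """
    image = np.asarray(image, dtype=np.complex128)
    coords = np.asarray(coords, dtype=float)
    grids = [np.arange(n) - n // 2 for n in image.shape]
    nx, ny, nz = np.meshgrid(*grids, indexing="ij")
    pos = np.stack([nx.ravel(), ny.ravel(), nz.ravel()], axis=1)  # (N, 3)
    phase = np.exp(-2j * np.pi * coords @ pos.T)  # (M, N)
    return phase @ image.ravel()


def direct_dft_adjoint(data: np.ndarray, coords: np.ndarray, shape: Sequence[int]) -> np.ndarray:
    """Brute-force adjoint of :func:`direct_dft`."""
    coords = np.asarray(coords, dtype=float)
    grids = [np.arange(n) - n // 2 for n in shape]
    nx, ny, nz = np.meshgrid(*grids, indexing="ij")
    pos = np.stack([nx.ravel(), ny.ravel(), nz.ravel()], axis=1)
    phase = np.exp(2j * np.pi * pos @ coords.T)  # (N, M)
    return (phase @ np.asarray(data, dtype=np.complex128)).reshape(tuple(shape))
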