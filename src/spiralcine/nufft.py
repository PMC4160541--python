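"""2-D non-uniform Fourier transforms for spiral sampling.

Two routes are provided:

* :class:`GriddingNufft2D` — Kaiser-Bessel gridding on a 2x oversampled FFT
  grid with deapodization.  Forward (image -> non-Cartesian samples) and
  adjoint are built from the same sparse interpolation operator, unitary
  FFTs and a shared real deapodization, so the pair is adjoint to machine
  precision by construction; approximation error relative to the exact
  transform is at the usual gridding level (~1e-3 with width 4, sigma 2).
* :class:`DirectNdft2D` — the exact (slow, dense-matrix) non-uniform DFT.
  The acquisition simulator uses this so that simulated raw data is not
  generated by the same approximate operator that reconstructs it.

Conventions: image arrays are (..., ny, nx) with the object centre at index
n//2; k-space coordinates are in cycles/grid ("normalized", |k| <= ~0.5);
the forward transform uses exp(-2*pi*i k.x) with x in pixels relative to the
centre.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def _kb_kernel(u: np.ndarray, width: float, beta: float) -> np.ndarray:
    """Kaiser-Bessel interpolation kernel on grid-unit offsets u."""
    x = 2.0 * u / width
    val = np.zeros_like(u, dtype=float)
    inside = np.abs(x) < 1.0
    val[inside] = np.i0(beta * np.sqrt(1.0 - x[inside] ** 2))
    return val


def _kb_apodization(n: int, grid: int, width: float, beta: float) -> np.ndarray:
    """Image-domain response of the KB kernel at the n retained pixels.

    Uses the continuous Fourier transform of the kernel (width * sinh(g)/g
    with g = sqrt(beta^2 - (pi*width*f)^2)), which carries the absolute scale
    so that deapodized gridding matches the exact non-uniform DFT."""
    x = (np.arange(n) - n // 2) / grid
    arg = np.sqrt((beta ** 2 - (np.pi * width * x) ** 2).astype(complex))
    with np.errstate(invalid="ignore"):
        c = np.where(np.abs(arg) > 1e-12, np.sinh(arg) / arg, 1.0).real
    return width * c


class GriddingNufft2D:
    """Kaiser-Bessel gridding NUFFT for a fixed set of sample locations.

    Parameters
    ----------
    k : complex or (M, 2) float array
        Sample coordinates in cycles/grid (|k| <= ~0.5).  Complex values are
        read as kx + i*ky.
    shape : (ny, nx)
        Image matrix size.
    oversamp, width
        Grid oversampling factor and kernel width (grid units).
    """

    def __init__(self, k: np.ndarray, shape: tuple[int, int],
                 oversamp: float = 2.0, width: int = 4) -> None:
        k = np.asarray(k)
        if np.iscomplexobj(k):
            kx, ky = k.real.ravel(), k.imag.ravel()
        else:
            kx, ky = k[..., 0].ravel(), k[..., 1].ravel()
        ny, nx = shape
        self.shape = (ny, nx)
        self.m = kx.size
        self.gy, self.gx = int(round(ny * oversamp)), int(round(nx * oversamp))
        self.width = width
        sigma = oversamp
        self.beta = np.pi * np.sqrt(
            (width / sigma) ** 2 * (sigma - 0.5) ** 2 - 0.8)

        self._interp = self._build_interp(kx, ky)
        cy = _kb_apodization(ny, self.gy, width, self.beta)
        cx = _kb_apodization(nx, self.gx, width, self.beta)
        # sqrt(N) folds the unitary-FFT normalization into the deapodization
        # so forward/adjoint match the exact NDFT scale (and stay an exact
        # adjoint pair, sharing one real factor).
        self._deapod = np.sqrt(self.gy * self.gx) / np.outer(cy, cx)

    def _build_interp(self, kx: np.ndarray, ky: np.ndarray) -> sp.csr_matrix:
        w = self.width
        offs = np.arange(-(w // 2) + 1, w // 2 + 1)  # w integer offsets
        px = kx * self.gx / 1.0 + self.gx // 2  # fractional grid position
        py = ky * self.gy / 1.0 + self.gy // 2
        # nearest grid points and kernel values, separable in x and y
        bx = np.floor(px).astype(int)[:, None] + offs[None, :]
        by = np.floor(py).astype(int)[:, None] + offs[None, :]
        wx = _kb_kernel(px[:, None] - bx, w, self.beta)
        wy = _kb_kernel(py[:, None] - by, w, self.beta)
        bx = np.mod(bx, self.gx)
        by = np.mod(by, self.gy)
        # outer products -> w*w entries per sample
        rows = np.repeat(np.arange(self.m), w * w)
        cols = (by[:, :, None] * self.gx + bx[:, None, :]).reshape(-1)
        vals = (wy[:, :, None] * wx[:, None, :]).reshape(-1)
        mat = sp.csr_matrix((vals, (rows, cols)),
                            shape=(self.m, self.gy * self.gx))
        return mat

    # -- padding helpers ----------------------------------------------------

    def _pad(self, img: np.ndarray) -> np.ndarray:
        ny, nx = self.shape
        out = np.zeros(img.shape[:-2] + (self.gy, self.gx), img.dtype)
        y0, x0 = self.gy // 2 - ny // 2, self.gx // 2 - nx // 2
        out[..., y0:y0 + ny, x0:x0 + nx] = img
        return out

    def _crop(self, img: np.ndarray) -> np.ndarray:
        ny, nx = self.shape
        y0, x0 = self.gy // 2 - ny // 2, self.gx // 2 - nx // 2
        return img[..., y0:y0 + ny, x0:x0 + nx]

    # -- transforms ---------------------------------------------------------

    def forward(self, img: np.ndarray) -> np.ndarray:
        """Image(s) (..., ny, nx) -> samples (..., M)."""
        img = np.asarray(img) * self._deapod
        grid = self._pad(img)
        ksp = np.fft.fftshift(np.fft.fft2(
            np.fft.ifftshift(grid, axes=(-2, -1)), norm="ortho"),
            axes=(-2, -1))
        flat = ksp.reshape(-1, self.gy * self.gx)
        out = (self._interp @ flat.T).T
        return out.reshape(img.shape[:-2] + (self.m,))

    def adjoint(self, data: np.ndarray) -> np.ndarray:
        """Samples (..., M) -> image(s) (..., ny, nx); exact adjoint of
        :meth:`forward`."""
        data = np.asarray(data)
        flat = data.reshape(-1, self.m)
        grid = (self._interp.conj().T @ flat.T).T
        grid = grid.reshape(data.shape[:-1] + (self.gy, self.gx))
        img = np.fft.fftshift(np.fft.ifft2(
            np.fft.ifftshift(grid, axes=(-2, -1)), norm="ortho"),
            axes=(-2, -1))
        return self._crop(img) * self._deapod


class DirectNdft2D:
    """Exact dense non-uniform DFT (forward/adjoint), for simulation and as
    an oracle.  Memory O(M * ny * nx); intended for desk-scale problems."""

    def __init__(self, k: np.ndarray, shape: tuple[int, int]) -> None:
        k = np.asarray(k)
        if np.iscomplexobj(k):
            kx, ky = k.real.ravel(), k.imag.ravel()
        else:
            kx, ky = k[..., 0].ravel(), k[..., 1].ravel()
        ny, nx = shape
        self.shape = (ny, nx)
        self.m = kx.size
        y = np.arange(ny) - ny // 2
        x = np.arange(nx) - nx // 2
        yy, xx = np.meshgrid(y, x, indexing="ij")
        phase = kx[:, None] * xx.ravel()[None, :] + \
            ky[:, None] * yy.ravel()[None, :]
        self._a = np.exp(-2j * np.pi * phase).astype(np.complex64)

    def forward(self, img: np.ndarray) -> np.ndarray:
        img = np.asarray(img)
        flat = img.reshape(-1, self.shape[0] * self.shape[1])
        out = flat @ self._a.T
        return out.reshape(img.shape[:-2] + (self.m,))

    def adjoint(self, data: np.ndarray) -> np.ndarray:
        data = np.asarray(data)
        flat = data.reshape(-1, self.m)
        out = flat @ self._a.conj()
        return out.reshape(data.shape[:-1] + self.shape)
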