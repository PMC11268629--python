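"""CPU image filtering and spectra: the visualisation-support math.

`convolve` reproduces, on the CPU, the weighted-average scheme a GPU
fragment shader applies when it samples an image texture in an N×M grid
around each texel and averages with kernel weights.  Texture sampling clamps
coordinates at the border, so edge handling here is nearest-border
replication.  The weighted average does not flip the kernel, i.e. this is a
correlation; an impulse image therefore reproduces the point-reflected
kernel.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "convolve",
    "gaussian_kernel_1d",
    "gaussian_kernel_2d",
    "gaussian_filter",
    "bandpass_filter",
    "power_spectrum",
    "log_display",
]


def convolve(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Centered weighted average of an image with an arbitrary 2D kernel.

    Kernel dimensions must be odd (the window is centered on each pixel);
    edges are handled by border replication.  No kernel flip is applied
    (correlation convention, matching texture-sampling semantics).
    """
    image = np.asarray(image, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if image.ndim != 2 or kernel.ndim != 2:
        raise ValueError("convolve expects a 2D image and a 2D kernel")
    if kernel.shape[0] % 2 == 0 or kernel.shape[1] % 2 == 0:
        raise ValueError(f"kernel dimensions must be odd, got {kernel.shape}")
    if not np.all(np.isfinite(kernel)):
        raise ValueError("kernel contains non-finite weights")
    ry, rx = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(image, ((ry, ry), (rx, rx)), mode="edge")
    windows = sliding_window_view(padded, kernel.shape)
    return np.einsum("ijkl,kl->ij", windows, kernel)


def gaussian_kernel_1d(sigma: float, size: int | None = None) -> np.ndarray:
    """Normalised 1D Gaussian; auto size = 2·ceil(3σ)+1."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if size is None:
        size = 2 * int(np.ceil(3 * sigma)) + 1
    if size % 2 == 0:
        raise ValueError(f"kernel size must be odd, got {size}")
    x = np.arange(size) - size // 2
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_kernel_2d(sigma: float, size: int | None = None) -> np.ndarray:
    k = gaussian_kernel_1d(sigma, size)
    return np.outer(k, k)


def gaussian_filter(
    image: np.ndarray, sigma: float, size: int | None = None
) -> np.ndarray:
    """Separable Gaussian blur with border replication (2D or 3D).

    Equivalent (to float precision) to :func:`convolve` with the dense
    Gaussian kernel, but computed one axis at a time.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim not in (2, 3):
        raise ValueError(f"expected a 2D or 3D image, got {image.ndim}D")
    k = gaussian_kernel_1d(sigma, size)
    r = len(k) // 2
    out = np.pad(image, r, mode="edge")
    for axis in range(out.ndim):
        windows = sliding_window_view(out, len(k), axis=axis)
        out = np.tensordot(windows, k, axes=([-1], [0]))
    return out


def _radial_frequency(shape: tuple[int, ...]) -> np.ndarray:
    """Frequency magnitude in cycles/image for each FFT bin."""
    grids = np.meshgrid(
        *[np.fft.fftfreq(n) * n for n in shape], indexing="ij", sparse=True
    )
    return np.sqrt(sum(g**2 for g in grids))


def _smoothstep(r: np.ndarray, edge: float, width: float) -> np.ndarray:
    """Raised-cosine ramp from 0 below edge-width/2 to 1 above edge+width/2."""
    t = np.clip((r - (edge - width / 2)) / width, 0.0, 1.0)
    return 0.5 * (1 - np.cos(np.pi * t))


def bandpass_filter(
    image: np.ndarray, low_cycles: float, high_cycles: float, edge_width: float = 2.0
) -> np.ndarray:
    """Radial FFT bandpass retaining frequencies in [low, high] cycles/image.

    The mask edges are raised-cosine ramps of ``edge_width`` frequency pixels
    to limit ringing.  ``low_cycles = 0`` keeps the DC component.
    """
    if low_cycles < 0 or low_cycles >= high_cycles:
        raise ValueError(
            f"need 0 <= low < high, got low={low_cycles}, high={high_cycles}"
        )
    image = np.asarray(image, dtype=float)
    r = _radial_frequency(image.shape)
    mask = _smoothstep(r, low_cycles, edge_width) if low_cycles > 0 else np.ones_like(r)
    mask = mask * (1.0 - _smoothstep(r, high_cycles, edge_width))
    return np.real(np.fft.ifftn(np.fft.fftn(image) * mask))


def power_spectrum(image: np.ndarray, stack_axis: int | None = None) -> np.ndarray:
    """|FFT|² with the zero-frequency component centered.

    Unnormalised forward FFT convention, so Parseval reads
    ``sum(P) = N_pixels · sum(|image|²)``.  For a stack, pass the stack axis
    and each member is transformed independently.
    """
    image = np.asarray(image, dtype=float)
    if stack_axis is not None:
        moved = np.moveaxis(image, stack_axis, 0)
        out = np.stack([power_spectrum(m) for m in moved])
        return np.moveaxis(out, 0, stack_axis)
    return np.fft.fftshift(np.abs(np.fft.fftn(image)) ** 2)


def log_display(power: np.ndarray) -> np.ndarray:
    """log(1 + P) display transform for power spectra."""
    return np.log1p(np.asarray(power, dtype=float))
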