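"""Centered, orthonormal 2D Fourier transforms.

Every k-space array in this package places DC at ``(H//2, W//2)`` and uses
orthonormal scaling, so Parseval holds exactly and zero-padding geometry is
a centered box.
"""

import numpy as np

__all__ = ["fft2c", "ifft2c"]


def fft2c(x: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D FFT over the last two axes."""
    axes = (-2, -1)
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def ifft2c(y: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D inverse FFT over the last two axes."""
    axes = (-2, -1)
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(y, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )
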