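"""The two hidden processing pipelines and k-space re-synthesis.

Public image archives rarely contain raw k-space.  What they do contain has
typically been through one of two pipelines before release:

* the *scanner export* pipeline — k-space zero padding (interpolation),
  per-coil inverse FFT, root-sum-of-squares combination, yielding a real
  nonnegative magnitude image on an enlarged grid; or
* the *storage* pipeline — 8-bit conversion and lossy JPEG compression.

Researchers then re-synthesize "raw" k-space from such images with a forward
FFT and run retrospective undersampling experiments on it.  This module
implements both pipelines, the re-synthesis, the per-image 98th-percentile
intensity normalization, and a forensic helper that looks for zero-padding
evidence in k-space.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Any, Optional, Union

import numpy as np
from PIL import Image

from retrobias.fourier import fft2c, ifft2c
from retrobias.simulate import RawKSpace, rss_combine

__all__ = [
    "Box",
    "ScannerPipelineConfig",
    "JPEGPipelineConfig",
    "ProcessedImage",
    "SynthesizedKSpace",
    "scanner_pipeline",
    "jpeg_pipeline",
    "jpeg_bytes",
    "normalize_98",
    "synthesize_kspace",
    "detect_zero_pad_box",
    "zero_pad_kspace",
]


@dataclass(frozen=True)
class Box:
    """Centered rectangle in array coordinates: top-left corner + size."""

    row0: int
    col0: int
    height: int
    width: int

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row0 + self.height),
                slice(self.col0, self.col0 + self.width))

    @staticmethod
    def centered(grid: tuple[int, int], size: tuple[int, int]) -> "Box":
        """Box of ``size`` whose DC pixel (``size//2``) sits on the grid's
        DC pixel (``grid//2``)."""
        gh, gw = grid
        bh, bw = size
        return Box(gh // 2 - bh // 2, gw // 2 - bw // 2, bh, bw)


@dataclass(frozen=True)
class ScannerPipelineConfig:
    """Zero-pad factor applied per axis before the inverse FFT (>= 1)."""

    zero_pad_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.zero_pad_factor < 1:
            raise ValueError("zero_pad_factor must be >= 1")


@dataclass(frozen=True)
class JPEGPipelineConfig:
    """JPEG quality factor in 1..100, or ``"none"`` to bypass the codec
    (the 8-bit quantization round-trip is still applied)."""

    quality_factor: Union[int, str] = 75

    def __post_init__(self) -> None:
        qf = self.quality_factor
        if qf == "none":
            return
        if not isinstance(qf, (int, np.integer)) or not 1 <= int(qf) <= 100:
            raise ValueError("quality_factor must be in 1..100 or 'none'")


@dataclass(frozen=True)
class ProcessedImage:
    """Real nonnegative magnitude image plus its processing provenance."""

    pixels: np.ndarray
    provenance: dict[str, Any]

    @property
    def original_box(self) -> Box:
        b = self.provenance["original_box"]
        return b if isinstance(b, Box) else Box(*b)


@dataclass(frozen=True)
class SynthesizedKSpace:
    """Single-"coil" k-space re-synthesized from a processed image."""

    data: np.ndarray
    original_box: Box


def zero_pad_kspace(kspace: np.ndarray, factor: float) -> tuple[np.ndarray, Box]:
    """Symmetrically zero-pad centered k-space to ``round(factor*size)``
    per axis; returns the padded array and the box holding the original
    data.  DC stays on the centered-FFT DC pixel (``n//2``)."""
    if factor < 1:
        raise ValueError("zero-pad factor must be >= 1")
    h, w = kspace.shape[-2:]
    nh, nw = int(round(factor * h)), int(round(factor * w))
    box = Box.centered((nh, nw), (h, w))
    out = np.zeros(kspace.shape[:-2] + (nh, nw), dtype=complex)
    out[..., box.row0:box.row0 + h, box.col0:box.col0 + w] = kspace
    return out, box


def scanner_pipeline(raw: RawKSpace, cfg: ScannerPipelineConfig) -> ProcessedImage:
    """Scanner export: zero-pad multicoil k-space, inverse FFT per coil,
    RSS combine.  Output grid = padded grid; provenance records where the
    true (nonpadded) data sit in the enlarged k-space."""
    padded, box = zero_pad_kspace(raw.data, cfg.zero_pad_factor)
    img = rss_combine(ifft2c(padded))
    return ProcessedImage(img, provenance={
        "pipeline": "scanner",
        "zero_pad_factor": float(cfg.zero_pad_factor),
        "original_box": (box.row0, box.col0, box.height, box.width),
    })


def jpeg_bytes(image: np.ndarray, quality: int) -> bytes:
    """Encoded byte stream of the max-scaled 8-bit grayscale image."""
    img8 = _to_uint8(image)[0]
    buf = _io.BytesIO()
    Image.fromarray(img8, mode="L").save(buf, format="JPEG", quality=int(quality))
    return buf.getvalue()


def _to_uint8(image: np.ndarray) -> tuple[np.ndarray, float]:
    scale = float(image.max())
    if scale <= 0:
        raise ValueError("image must have positive maximum for 8-bit scaling")
    return np.round(image / scale * 255.0).astype(np.uint8), scale


def jpeg_pipeline(image: np.ndarray,
                  cfg: JPEGPipelineConfig) -> ProcessedImage:
    """Storage pipeline: max-scale to 8-bit grayscale, JPEG encode/decode at
    the configured quality factor, rescale back to the original intensity
    range.  ``quality_factor="none"`` skips the codec but keeps the 8-bit
    quantization round-trip."""
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    img8, scale = _to_uint8(image)
    if cfg.quality_factor == "none":
        dec = img8
    else:
        buf = _io.BytesIO()
        Image.fromarray(img8, mode="L").save(
            buf, format="JPEG", quality=int(cfg.quality_factor))
        buf.seek(0)
        dec = np.asarray(Image.open(buf), dtype=np.uint8)
    out = dec.astype(float) / 255.0 * scale
    h, w = out.shape
    return ProcessedImage(out, provenance={
        "pipeline": "jpeg",
        "quality_factor": cfg.quality_factor,
        "scale": scale,
        "original_box": (0, 0, h, w),
    })


def normalize_98(image: np.ndarray) -> np.ndarray:
    """Divide an image by its 98th percentile (the normalization commonly
    applied to processed datasets at training time)."""
    image = np.asarray(image, dtype=float)
    if image.size == 0 or not np.any(np.isfinite(image)):
        raise ValueError("image must have finite pixels")
    p98 = float(np.percentile(image, 98))
    if p98 <= 0:
        raise ValueError("98th percentile must be positive")
    return image / p98


def synthesize_kspace(img: Union[ProcessedImage, np.ndarray],
                      original_box: Optional[Box] = None) -> SynthesizedKSpace:
    """Re-synthesize "raw" single-coil k-space from a processed magnitude
    image via the forward FFT.  For zero-padded inputs, artificial data now
    occupy the periphery outside ``original_box``."""
    if isinstance(img, ProcessedImage):
        pixels = img.pixels
        box = img.original_box
    else:
        pixels = np.asarray(img, dtype=float)
        h, w = pixels.shape
        box = original_box or Box(0, 0, h, w)
    if np.any(pixels < 0):
        raise ValueError("processed image must be nonnegative")
    return SynthesizedKSpace(fft2c(pixels), box)


#: minimum detrended log-density step (nats) accepted as a padding edge;
#: smooth spectra extrapolate to within ~e^0.8 of themselves, true
#: interpolation edges overshoot this by a wide margin
_EDGE_MIN_STEP = 0.8
_EDGE_WIN = 6


def _ring_log_profile(k: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """log median ``|k|^2`` on the 1-pixel frame of each centered candidate
    box, indexed by box height (width scales with the aspect ratio)."""
    h, w = k.shape
    bhs = np.arange(8, h + 1)
    ell = np.empty(len(bhs))
    for i, bh in enumerate(bhs):
        bw = max(8, int(round(bh / h * w)))
        box = Box.centered((h, w), (min(bh, h), min(bw, w)))
        r0, c0 = box.row0, box.col0
        r1, c1 = r0 + box.height, c0 + box.width
        m = np.zeros((h, w), dtype=bool)
        m[r0:r1, c0:c1] = True
        m[r0 + 1:r1 - 1, c0 + 1:c1 - 1] = False
        ell[i] = np.log(float(np.median(k[m])) + 1e-300)
    return bhs, ell


def detect_zero_pad_box(kspace: np.ndarray, threshold: float = 1e-2
                        ) -> Optional[Box]:
    """Look for zero-padding evidence in 2D k-space.

    Works on the log of the median ``|k|^2`` profile over centered
    box-boundary rings.  A padding edge is a *step* in that profile: the
    densities just outside a candidate boundary fall far below the linear
    extrapolation of the densities just inside (detrending separates a
    genuine step from steep smooth spectral decay, e.g. near the
    low-frequency knee).  A detected edge is confirmed only if the total
    energy outside the box is below ``threshold`` times the energy inside
    it.  Candidate boxes smaller than a quarter of the grid (padding
    factors above 4x) are not considered.  Returns ``None`` when no
    confirmed edge exists.
    """
    k = np.abs(np.asarray(kspace)) ** 2
    h, w = k.shape
    bhs, ell = _ring_log_profile(k)
    win = _EDGE_WIN
    best_bh, best_score = None, -np.inf
    for i in range(win, len(bhs) - win):
        if bhs[i] < h // 4 or bhs[i] >= h:
            continue
        xi = np.arange(i - win, i)
        slope, icpt = np.polyfit(xi, ell[i - win:i], 1)
        pred = slope * np.arange(i, i + win) + icpt
        score = float((pred - ell[i:i + win]).mean())
        if score > best_score:
            best_bh, best_score = int(bhs[i]), score
    if best_bh is None or best_score < _EDGE_MIN_STEP:
        return None
    # refine: the boundary is the single sharpest ring-to-ring drop nearby
    j = int(np.flatnonzero(bhs == best_bh)[0])
    lo = max(1, j - win)
    hi = min(len(bhs) - 1, j + win)
    drops = ell[lo - 1:hi] - ell[lo:hi + 1]
    edge_bh = int(bhs[lo + int(np.argmax(drops))])
    box = Box.centered((h, w), (edge_bh - 1,
                                max(8, int(round((edge_bh - 1) / h * w)))))
    inside = float(k[box.slices()].sum())
    outside = float(k.sum() - inside)
    if inside <= 0 or outside > threshold * inside:
        return None
    return box
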