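"""Synthetic fully sampled multicoil k-space.

Stands in for raw-data archives in which fully sampled ground truth is
available.  A slice is a piecewise-smooth complex image (ellipse composition
with small high-contrast details emulating fine anatomy and pathology) times
a smooth spatial phase, seen through smooth complex coil sensitivities, with
i.i.d. complex Gaussian noise added in k-space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.ndimage import gaussian_filter

from retrobias.fourier import fft2c, ifft2c

__all__ = [
    "PhantomSpec",
    "CoilProfile",
    "RawKSpace",
    "make_phantom",
    "make_coil_maps",
    "simulate_raw_kspace",
    "rss_combine",
    "ground_truth_image",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice.

    Parameters
    ----------
    height, width
        Grid size in pixels; at least 32.
    n_features
        Number of small high-contrast detail structures (ellipses / short
        bars) placed inside the phantom support.
    phase_smoothness
        Low-pass cutoff of the synthetic spatial phase map, as a fraction of
        the grid's Nyquist band.  ``0`` disables the phase entirely (real
        phantom).
    noise_sigma
        Std of the complex k-space noise, relative to the peak magnitude of
        the noiseless multicoil k-space.
    texture_amp
        Amplitude of the band-limited stochastic texture inside the tissue
        support (fraction of the tissue intensity scale), emulating the
        fine parenchymal/trabecular texture of real anatomy.
    seed
        RNG seed; the generator is fully deterministic given the spec.
    """

    height: int = 320
    width: int = 320
    n_features: int = 8
    phase_smoothness: float = 0.04
    noise_sigma: float = 2e-3
    texture_amp: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("phantom grid must be at least 32x32")
        if self.n_features < 0:
            raise ValueError("n_features must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class CoilProfile:
    """Smooth complex coil sensitivity maps, shape ``(n_coils, H, W)``."""

    maps: np.ndarray

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def grid(self) -> tuple[int, int]:
        return self.maps.shape[-2:]


@dataclass(frozen=True)
class RawKSpace:
    """Fully sampled multicoil k-space of one slice, ``(coil, ky, kx)``."""

    data: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def grid(self) -> tuple[int, int]:
        return self.data.shape[-2:]

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]


def _ellipse(h: int, w: int, cy: float, cx: float, ay: float, ax: float,
             theta: float) -> np.ndarray:
    """Boolean mask of a rotated ellipse (axes in pixels)."""
    yy, xx = np.mgrid[0:h, 0:w]
    y = yy - cy
    x = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * x + st * y
    v = -st * x + ct * y
    return (u / ax) ** 2 + (v / ay) ** 2 <= 1.0


def _smooth_field(h: int, w: int, cutoff: float, rng: np.random.Generator
                  ) -> np.ndarray:
    """Real smooth random field from random coefficients in a central
    k-space box of half-width ``cutoff * min(h, w) / 2``."""
    half = max(1, int(round(cutoff * min(h, w) / 2)))
    coeff = np.zeros((h, w), dtype=complex)
    box = rng.standard_normal((2 * half + 1, 2 * half + 1)) \
        + 1j * rng.standard_normal((2 * half + 1, 2 * half + 1))
    coeff[h // 2 - half: h // 2 + half + 1,
          w // 2 - half: w // 2 + half + 1] = box
    f = ifft2c(coeff).real
    return f / (np.abs(f).max() + 1e-30)


def _band_field(h: int, w: int, lo: float, hi: float,
                rng: np.random.Generator) -> np.ndarray:
    """Real random field band-limited to the annulus ``[lo, hi]`` of the
    Nyquist band, normalized to unit std."""
    yy = (np.arange(h) - h // 2) / (h / 2)
    xx = (np.arange(w) - w // 2) / (w / 2)
    r = np.sqrt(yy[:, None] ** 2 + xx[None, :] ** 2)
    band = (r >= lo) & (r <= hi)
    coeff = (rng.standard_normal((h, w)) + 1j * rng.standard_normal((h, w))) * band
    f = ifft2c(coeff).real
    return f / (f.std() + 1e-30)


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Generate one complex phantom slice.

    The magnitude is a composition of a few large soft-contrast ellipses on
    an elliptical support plus ``n_features`` small high-contrast details;
    the phase is a smooth random field scaled to ~1 rad.  Bit-identical for
    identical specs.  The base anatomy consumes the RNG before the details
    do, so two specs differing only in ``n_features`` share their
    background exactly.
    """
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)

    # support + interior anatomy
    cy, cx = h / 2 + rng.uniform(-0.02, 0.02) * h, w / 2 + rng.uniform(-0.02, 0.02) * w
    support = _ellipse(h, w, cy, cx, 0.42 * h * rng.uniform(0.95, 1.05),
                       0.42 * w * rng.uniform(0.95, 1.05),
                       rng.uniform(-0.2, 0.2))
    mag = np.where(support, 0.55, 0.0)
    for _ in range(4):
        ecy = cy + rng.uniform(-0.18, 0.18) * h
        ecx = cx + rng.uniform(-0.18, 0.18) * w
        eay = rng.uniform(0.08, 0.22) * h
        eax = rng.uniform(0.08, 0.22) * w
        mag += np.where(_ellipse(h, w, ecy, ecx, eay, eax,
                                 rng.uniform(0, np.pi)) & support,
                        rng.uniform(-0.18, 0.22), 0.0)
    # gentle shading so the interior is piecewise-smooth, not piecewise-flat
    shade = _smooth_field(h, w, 0.02, rng)
    mag = np.where(support, mag * (1.0 + 0.15 * shade), 0.0)
    mag = np.clip(mag, 0.0, None)
    # normalize on the feature-free anatomy so adding details later changes
    # only the detail pixels (keeps the background bit-identical across
    # n_features)
    mag /= mag.max() + 1e-30

    # small high-contrast details inside the inner half of the support
    feat_rng = np.random.default_rng(rng.integers(0, 2 ** 31))
    scale = min(h, w) / 320.0
    placed: list[tuple[float, float, float]] = []
    n_placed = 0
    attempts = 0
    while n_placed < spec.n_features and attempts < 200 * max(spec.n_features, 1):
        attempts += 1
        fy = cy + feat_rng.uniform(-0.25, 0.25) * h
        fx = cx + feat_rng.uniform(-0.25, 0.25) * w
        ry = feat_rng.uniform(2.0, 5.0) * scale
        rx = feat_rng.uniform(2.0, 5.0) * scale
        if feat_rng.random() < 0.3:     # short bar
            rx = feat_rng.uniform(5.0, 9.0) * scale
            ry = max(1.2 * scale, 1.2)
        rad = max(ry, rx)
        if any((fy - py) ** 2 + (fx - px) ** 2
               < (rad + pr + max(8 * scale, 5.0)) ** 2
               for py, px, pr in placed):
            continue
        contrast = feat_rng.choice([-0.35, 0.45])
        mag += np.where(_ellipse(h, w, fy, fx, max(ry, 1.0), max(rx, 1.0),
                                 feat_rng.uniform(0, np.pi)) & support,
                        contrast, 0.0)
        placed.append((fy, fx, rad))
        n_placed += 1
    mag = np.clip(mag, 0.0, None)
    # mild point-spread blur: acquired MRI slices are band-limited, and
    # hard-edged ellipses would be unrealistically broadband
    mag = gaussian_filter(mag, sigma=0.008 * min(h, w))

    # fine stochastic texture inside the tissue (drawn from its own
    # substream so the background stays identical across n_features)
    if spec.texture_amp > 0:
        tex_rng = np.random.default_rng(rng.integers(0, 2 ** 31))
        tex = _band_field(h, w, 0.1, 0.45, tex_rng)
        mag = np.clip(mag + spec.texture_amp * tex * (mag > 0.08), 0.0, None)

    if spec.phase_smoothness > 0:
        phase = 1.0 * _smooth_field(h, w, spec.phase_smoothness, rng)
        return mag * np.exp(1j * phase)
    return mag.astype(complex)


def make_coil_maps(grid: tuple[int, int], n_coils: int, seed: int = 0,
                   band: float = 0.08) -> CoilProfile:
    """Smooth complex coil sensitivity maps.

    Each map is a positive Gaussian bump (centered on the image rim, one
    per coil) over a 0.1 floor, times a smooth unit-modulus phase, then hard
    band-limited to the central ``band`` fraction of k-space.  ``n_coils=1``
    returns the identity map.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    h, w = grid
    if n_coils == 1:
        return CoilProfile(np.ones((1, h, w), dtype=complex))
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    maps = np.empty((n_coils, h, w), dtype=complex)
    sigma = 0.45 * min(h, w)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.uniform(-0.3, 0.3)
        cy = h / 2 + 0.55 * h * np.sin(ang)
        cx = w / 2 + 0.55 * w * np.cos(ang)
        bump = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))
        phase = 0.8 * _smooth_field(h, w, 0.02, rng)
        m = (0.1 + bump) * np.exp(1j * phase)
        # hard band-limit: keep the central box, kill everything outside
        half_y = max(1, int(round(band * h / 2)))
        half_x = max(1, int(round(band * w / 2)))
        k = fft2c(m)
        keep = np.zeros_like(k)
        keep[h // 2 - half_y: h // 2 + half_y + 1,
             w // 2 - half_x: w // 2 + half_x + 1] = \
            k[h // 2 - half_y: h // 2 + half_y + 1,
              w // 2 - half_x: w // 2 + half_x + 1]
        maps[c] = ifft2c(keep)
    return CoilProfile(maps)


def simulate_raw_kspace(image: np.ndarray, coils: CoilProfile,
                        noise_sigma: float = 0.0, seed: int = 0) -> RawKSpace:
    """Forward-model a fully sampled multicoil acquisition.

    Per-coil k-space is the centered orthonormal FFT of (coil map x image)
    plus complex Gaussian noise whose per-sample std is
    ``noise_sigma * max |noiseless k-space|``.  With ``noise_sigma=0`` the
    model is exactly invertible coil by coil.
    """
    if image.shape != coils.grid:
        raise ValueError(
            f"image shape {image.shape} does not match coil grid {coils.grid}")
    clean = fft2c(coils.maps * image[None])
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        sigma_abs = noise_sigma * np.abs(clean).max()
        noise = (rng.standard_normal(clean.shape)
                 + 1j * rng.standard_normal(clean.shape)) * (sigma_abs / np.sqrt(2))
        data = clean + noise
    else:
        data = clean
    return RawKSpace(data, provenance={
        "noise_sigma": float(noise_sigma), "seed": int(seed),
        "n_coils": coils.n_coils})


def rss_combine(coil_images: np.ndarray) -> np.ndarray:
    """Root-sum-of-squares coil combination.

    ``coil_images`` is complex with shape ``(n_coils, H, W)``; the result is
    the real nonnegative per-pixel sqrt of the summed squared moduli.
    """
    coil_images = np.asarray(coil_images)
    if coil_images.ndim != 3 or coil_images.shape[0] < 1:
        raise ValueError("need at least one coil image of shape (C, H, W)")
    return np.sqrt(np.sum(np.abs(coil_images) ** 2, axis=0))


def ground_truth_image(raw: RawKSpace) -> np.ndarray:
    """Reference magnitude image: RSS of the per-coil inverse FFT."""
    return rss_combine(ifft2c(raw.data))
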