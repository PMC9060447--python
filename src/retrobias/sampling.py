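"""Variable-density k-space sampling: PDFs, Monte-Carlo masks, and the
global vs. effective sampling-rate statistic.

Three schemes are provided.  ``uniform`` samples every location with equal
probability ``1/R``.  The two variable-density (VD) schemes build the
probability map from the radial profile ``f(r) = (1 - r)^p`` plus a constant
offset, clipped to ``[0, 1]``, with the offset solved so that the overall
mean equals ``1/R``:

    prob = clip((1 - r)^p + c, 0, 1),   mean(prob) = 1/R.

Under this construction a *large* power (the default weak-VD ``p = 7``)
gives a narrow central bump over a near-uniform floor — weak variable
density — while small powers (``p = 1..3``) spread substantial extra mass
over the center — strong variable density.  A small calibration region at
the k-space center is fully sampled in every mask.

The *effective* sampling rate of a mask with respect to a centered box is
the sampled fraction inside that box only.  When the box is the original
(nonpadded) data region of a zero-padded acquisition, VD masks concentrate
on it and the effective rate exceeds the advertised global rate — the
statistic that reveals the bias of retrospective experiments on processed
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from retrobias.pipelines import Box

__all__ = [
    "SamplingConfig",
    "SamplingPDF",
    "SamplingMask",
    "STRONG_VD_POWER",
    "WEAK_VD_POWER",
    "default_power",
    "default_calib",
    "build_pdf",
    "draw_mask",
    "effective_rate",
    "expected_effective_rate",
]

WEAK_VD_POWER = 7.0
#: strong-VD powers per acceleration factor; R=6 is anchor-selected
STRONG_VD_POWER = {2: 1.0, 3: 2.0, 4: 3.0, 6: 3.0}


def default_power(scheme: str, R: float) -> float:
    if scheme == "weak_vd":
        return WEAK_VD_POWER
    if scheme == "strong_vd":
        return STRONG_VD_POWER.get(int(round(R)), 3.0)
    return 0.0


def default_calib(grid: tuple[int, int]) -> tuple[int, int]:
    """Calibration-region size: 6x6 on a 320x320 grid, scaled with the
    image size (at least 2 per axis)."""
    return (max(2, int(round(6 * grid[0] / 320))),
            max(2, int(round(6 * grid[1] / 320))))


@dataclass(frozen=True)
class SamplingConfig:
    """Scheme (``uniform`` | ``weak_vd`` | ``strong_vd``), density power
    ``p``, acceleration ``R`` (target rate ``1/R``), calibration-region size
    and seed.  ``p=None`` picks the scheme's default power."""

    scheme: str = "strong_vd"
    R: float = 4.0
    p: Optional[float] = None
    calib_height: Optional[int] = None
    calib_width: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in {"uniform", "weak_vd", "strong_vd"}:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.R <= 1:
            raise ValueError("acceleration R must be > 1")
        if self.p is not None and self.p < 0:
            raise ValueError("power p must be >= 0")

    def power(self) -> float:
        return self.p if self.p is not None else default_power(self.scheme, self.R)


@dataclass(frozen=True)
class SamplingPDF:
    """Per-location sampling probability map with its construction record."""

    prob: np.ndarray
    target_rate: float
    scheme: str
    power: float
    calib_box: Optional[Box]

    @property
    def grid(self) -> tuple[int, int]:
        return self.prob.shape


@dataclass(frozen=True)
class SamplingMask:
    """One Bernoulli realization of a :class:`SamplingPDF`."""

    mask: np.ndarray
    seed: int
    pdf_ref: Optional[SamplingPDF] = field(default=None, repr=False)

    @property
    def grid(self) -> tuple[int, int]:
        return self.mask.shape


def _radius(grid: tuple[int, int]) -> np.ndarray:
    """Per-axis-normalized center distance: r = 1 at every mid-edge."""
    h, w = grid
    yy = (np.arange(h) - h // 2) / (h / 2)
    xx = (np.arange(w) - w // 2) / (w / 2)
    return np.sqrt(yy[:, None] ** 2 + xx[None, :] ** 2)


def _calib_box(grid: tuple[int, int], cfg: SamplingConfig) -> Optional[Box]:
    ch = cfg.calib_height
    cw = cfg.calib_width
    if ch is None and cw is None:
        ch, cw = default_calib(grid)
    ch = int(ch or 0)
    cw = int(cw or 0)
    if ch <= 0 or cw <= 0:
        return None
    if ch >= grid[0] or cw >= grid[1]:
        raise ValueError("calibration region must be smaller than the grid")
    return Box.centered(grid, (ch, cw))


def build_pdf(grid: tuple[int, int], cfg: SamplingConfig) -> SamplingPDF:
    """Build the sampling probability map for ``grid``.

    The calibration region is forced to probability 1 before the mean-rate
    constraint ``mean(prob) = 1/R`` is enforced (to 1e-8) by solving for
    the constant offset (VD schemes) or the constant level (uniform).
    """
    h, w = grid
    target = 1.0 / cfg.R
    calib = _calib_box(grid, cfg)
    cal_mask = np.zeros((h, w), dtype=bool)
    if calib is not None:
        cal_mask[calib.slices()] = True
    n_cal = int(cal_mask.sum())
    n = h * w
    if n_cal / n > target + 1e-12:
        raise ValueError("calibration region alone exceeds the sampling budget")

    if cfg.scheme == "uniform":
        level = (target * n - n_cal) / (n - n_cal)
        prob = np.full((h, w), level)
        prob[cal_mask] = 1.0
        return SamplingPDF(prob, target, cfg.scheme, 0.0, calib)

    p = cfg.power()
    r = _radius(grid)
    base = np.where(r <= 1, (1.0 - np.clip(r, 0, 1)) ** p, 0.0)

    def mean_for(c: float) -> float:
        prob = np.clip(base + c, 0.0, 1.0)
        prob[cal_mask] = 1.0
        return float(prob.mean())

    if mean_for(-1.0) > target:      # even the bare calibration region overshoots
        raise ValueError("target rate infeasible for this configuration")
    c = brentq(lambda c: mean_for(c) - target, -1.0, 1.0, xtol=1e-10)
    prob = np.clip(base + c, 0.0, 1.0)
    prob[cal_mask] = 1.0
    return SamplingPDF(prob, target, cfg.scheme, p, calib)


def draw_mask(pdf: SamplingPDF, seed: int = 0) -> SamplingMask:
    """One independent-Bernoulli mask realization (deterministic in seed)."""
    rng = np.random.default_rng(seed)
    mask = rng.random(pdf.prob.shape) < pdf.prob
    return SamplingMask(mask, seed=seed, pdf_ref=pdf)


def _check_box(grid: tuple[int, int], box: Box) -> None:
    if box.height <= 0 or box.width <= 0:
        raise ValueError("box must be non-empty")
    if (box.row0 < 0 or box.col0 < 0
            or box.row0 + box.height > grid[0]
            or box.col0 + box.width > grid[1]):
        raise ValueError("box must lie inside the grid")


def effective_rate(mask: SamplingMask, original_box: Box) -> float:
    """Sampled fraction inside ``original_box`` (the nonpadded area)."""
    _check_box(mask.grid, original_box)
    return float(mask.mask[original_box.slices()].mean())


def expected_effective_rate(pdf: SamplingPDF, original_box: Box) -> float:
    """Analytic counterpart of :func:`effective_rate`: the PDF mean over
    the box."""
    _check_box(pdf.grid, original_box)
    return float(pdf.prob[original_box.slices()].mean())
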