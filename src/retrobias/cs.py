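"""Compressed-sensing reconstruction: FISTA with an l1-wavelet prior.

Solves

    x_hat = argmin_x  1/2 ||E x - y||_2^2 + lambda ||Psi x||_1,

where ``E = U F`` (centered orthonormal FFT followed by binary k-space
subsampling) and ``Psi`` is an orthonormal wavelet transform.  With the
orthonormal FFT and a binary mask the data-consistency gradient has
Lipschitz constant 1, so the proximal-gradient step size is fixed at 1.
Soft-thresholding acts on complex wavelet coefficients by magnitude
(phase-preserving).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pywt

from retrobias.fourier import fft2c, ifft2c
from retrobias.metrics import nrmse
from retrobias.sampling import SamplingMask

__all__ = [
    "EncodingOperator",
    "CSConfig",
    "ReconResult",
    "fista_reconstruct",
    "objective_value",
    "calibrate_lambda",
    "default_lambda_grid",
]


@dataclass(frozen=True)
class EncodingOperator:
    """Subsampled Fourier encoding ``E = U F`` for one binary mask."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @classmethod
    def from_mask(cls, mask: SamplingMask) -> "EncodingOperator":
        return cls(mask.mask)

    @property
    def grid(self) -> tuple[int, int]:
        return self.mask.shape

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.mask * fft2c(x)

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        return ifft2c(self.mask * y)


@dataclass(frozen=True)
class CSConfig:
    """FISTA configuration: regularization weight, wavelet, iteration
    budget and relative-change stopping tolerance."""

    lam: float = 1e-3
    wavelet_name: str = "db4"
    n_levels: int = 4
    n_iters: int = 200
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.n_iters < 1:
            raise ValueError("n_iters must be >= 1")
        if not pywt.Wavelet(self.wavelet_name).orthogonal:
            raise ValueError(
                f"wavelet {self.wavelet_name!r} is not orthonormal; the "
                "objective assumes an orthonormal Psi")


@dataclass(frozen=True)
class ReconResult:
    """Reconstructed image plus solver diagnostics."""

    image: np.ndarray
    objective_trace: np.ndarray
    config: Any = field(repr=False, default=None)


def _wav_forward(x: np.ndarray, cfg: CSConfig):
    return pywt.wavedec2(x, cfg.wavelet_name, mode="periodization",
                         level=cfg.n_levels)


def _wav_inverse(coeffs, cfg: CSConfig) -> np.ndarray:
    return pywt.waverec2(coeffs, cfg.wavelet_name, mode="periodization")


def _wav_l1(coeffs) -> float:
    total = np.abs(coeffs[0]).sum()
    for detail in coeffs[1:]:
        total += sum(np.abs(d).sum() for d in detail)
    return float(total)


def _soft_by_magnitude(c: np.ndarray, thresh: float) -> np.ndarray:
    mag = np.abs(c)
    return np.where(mag > 0, c * np.maximum(1.0 - thresh / np.maximum(mag, 1e-300), 0.0), 0.0)


def _soft_coeffs(coeffs, thresh: float):
    out = [_soft_by_magnitude(coeffs[0], thresh)]
    for detail in coeffs[1:]:
        out.append(tuple(_soft_by_magnitude(d, thresh) for d in detail))
    return out


def objective_value(x: np.ndarray, y: np.ndarray, op: EncodingOperator,
                    cfg: CSConfig) -> float:
    """Evaluate 1/2 ||Ex - y||^2 + lam ||Psi x||_1."""
    resid = op.forward(x) - op.mask * y
    dc = 0.5 * float(np.sum(np.abs(resid) ** 2))
    if cfg.lam == 0:
        return dc
    return dc + cfg.lam * _wav_l1(_wav_forward(x, cfg))


def fista_reconstruct(y: np.ndarray, op: EncodingOperator,
                      cfg: CSConfig) -> ReconResult:
    """FISTA on the l1-wavelet objective, initialized at the zero-filled
    adjoint ``E^H y``; stops at ``n_iters`` or when the relative iterate
    change drops below ``tol``."""
    y = np.asarray(y)
    if np.any(np.isnan(y)):
        raise ValueError("NaN in input k-space")
    if y.shape != op.grid:
        raise ValueError("k-space shape does not match the operator grid")
    h, w = op.grid
    if h % 2 ** cfg.n_levels or w % 2 ** cfg.n_levels:
        raise ValueError("grid must be divisible by 2**n_levels for an "
                         "orthonormal periodized wavelet")
    y = op.mask * y
    x = op.adjoint(y)
    z = x
    t = 1.0
    trace = []
    for _ in range(cfg.n_iters):
        grad = op.adjoint(op.forward(z) - y)
        x_new = z - grad
        if cfg.lam > 0:
            x_new = _wav_inverse(_soft_coeffs(_wav_forward(x_new, cfg), cfg.lam), cfg)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = x_new + ((t - 1.0) / t_new) * (x_new - x)
        delta = np.linalg.norm(x_new - x) / max(np.linalg.norm(x_new), 1e-30)
        x, t = x_new, t_new
        trace.append(objective_value(x, y, op, cfg))
        if delta < cfg.tol:
            break
    return ReconResult(x, np.asarray(trace), cfg)


def default_lambda_grid(points_per_decade: int = 9,
                        lo: float = 1e-9, hi: float = 1e-1) -> np.ndarray:
    """Log-spaced calibration grid over ``[lo, hi]``."""
    n_dec = np.log10(hi / lo)
    n = int(round(points_per_decade * n_dec)) + 1
    return np.logspace(np.log10(lo), np.log10(hi), n)


def calibrate_lambda(tuning_set: Sequence[tuple[np.ndarray, np.ndarray, EncodingOperator]],
                     grid: Sequence[float],
                     cfg: CSConfig) -> float:
    """Grid-search lambda minimizing mean NRMSE over a tuning set.

    ``tuning_set`` holds ``(reference, masked_kspace, operator)`` triples.
    Ties break toward the smaller lambda.
    """
    grid = sorted(float(g) for g in grid)
    if not grid or not tuning_set:
        raise ValueError("grid and tuning set must be non-empty")
    best_lam, best_err = None, np.inf
    for lam in grid:
        cfg_l = CSConfig(lam=lam, wavelet_name=cfg.wavelet_name,
                         n_levels=cfg.n_levels, n_iters=cfg.n_iters,
                         tol=cfg.tol)
        errs = [nrmse(np.abs(fista_reconstruct(y, op, cfg_l).image), ref)
                for ref, y, op in tuning_set]
        err = float(np.mean(errs))
        if err < best_err:
            best_lam, best_err = lam, err
    return best_lam
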