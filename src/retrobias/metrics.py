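"""Image-quality metrics: NRMSE and SSIM.

NRMSE is normalized by the l2 norm of the reference (the convention of the
large public raw-data benchmarks); ``normalizer`` switches to range- or
mean-normalization.  SSIM uses the standard constants of the original
structural-similarity formulation: Gaussian window (sigma 1.5, 11x11),
K1=0.01, K2=0.03, data range = reference max.
"""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["nrmse", "ssim"]


def nrmse(recon: np.ndarray, reference: np.ndarray,
          normalizer: str = "l2") -> float:
    """Normalized RMS error between magnitude images."""
    recon = np.abs(np.asarray(recon, dtype=float))
    reference = np.abs(np.asarray(reference, dtype=float))
    if recon.shape != reference.shape:
        raise ValueError("shapes must match")
    rmse = np.linalg.norm(recon - reference)
    if normalizer == "l2":
        denom = np.linalg.norm(reference)
    elif normalizer == "range":
        denom = (reference.max() - reference.min()) * np.sqrt(reference.size)
        rmse = np.linalg.norm(recon - reference)
    elif normalizer == "mean":
        denom = reference.mean() * np.sqrt(reference.size)
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    if denom <= 0:
        raise ValueError("reference must not be identically zero")
    return float(rmse / denom)


def ssim(recon: np.ndarray, reference: np.ndarray,
         data_range: float | None = None) -> float:
    """Mean structural similarity with a Gaussian window."""
    recon = np.abs(np.asarray(recon, dtype=float))
    reference = np.abs(np.asarray(reference, dtype=float))
    if recon.shape != reference.shape:
        raise ValueError("shapes must match")
    if min(recon.shape) < 11:
        raise ValueError("image smaller than the 11x11 SSIM window")
    if data_range is None:
        data_range = float(reference.max())
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    return float(structural_similarity(
        reference, recon, win_size=11, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03, data_range=data_range))
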