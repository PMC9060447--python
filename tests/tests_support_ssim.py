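"""Shared straight-from-definition SSIM oracle used by the metric tests."""

import numpy as np
from scipy.signal import convolve2d


def ssim_oracle(x, y, data_range):
    """Mean SSIM with an 11x11 Gaussian window (sigma 1.5), K1=0.01,
    K2=0.03, weighted (not sample) covariance, averaged over the positions
    where the full window fits."""
    g = np.arange(11) - 5
    k1d = np.exp(-g ** 2 / (2 * 1.5 ** 2))
    k = np.outer(k1d, k1d)
    k /= k.sum()
    C1 = (0.01 * data_range) ** 2
    C2 = (0.03 * data_range) ** 2

    def w(f):
        return convolve2d(f, k, mode="valid")

    mx, my = w(x), w(y)
    sxx = w(x * x) - mx ** 2
    syy = w(y * y) - my ** 2
    sxy = w(x * y) - mx * my
    s = ((2 * mx * my + C1) * (2 * sxy + C2)) / \
        ((mx ** 2 + my ** 2 + C1) * (sxx + syy + C2))
    return s.mean()
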