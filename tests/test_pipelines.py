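"""Processing pipelines: scanner zero-pad/RSS, JPEG storage, intensity
normalization, k-space re-synthesis and zero-pad forensics."""

import numpy as np
import pytest
import pywt

from retrobias.fourier import fft2c, ifft2c
from retrobias.pipelines import (Box, JPEGPipelineConfig,
                                 ScannerPipelineConfig, detect_zero_pad_box,
                                 jpeg_bytes, jpeg_pipeline, normalize_98,
                                 scanner_pipeline, synthesize_kspace,
                                 zero_pad_kspace)
from retrobias.simulate import (PhantomSpec, ground_truth_image, make_phantom,
                                make_coil_maps, simulate_raw_kspace)


def _wavelet_l1(img):
    c = pywt.wavedec2(img, "db4", mode="periodization", level=3)
    return np.abs(c[0]).sum() + sum(np.abs(d).sum() for lev in c[1:] for d in lev)


class TestScannerPipeline:
    def test_factor1_is_plain_rss(self, raw96):
        out = scanner_pipeline(raw96, ScannerPipelineConfig(1.0))
        assert out.pixels.shape == raw96.grid
        assert np.allclose(out.pixels, ground_truth_image(raw96), atol=1e-12)

    def test_factor2_doubles_grid(self, raw96):
        out = scanner_pipeline(raw96, ScannerPipelineConfig(2.0))
        assert out.pixels.shape == (192, 192)
        assert out.original_box == Box(48, 48, 96, 96)

    def test_nonnegative(self, raw96):
        for f in (1.0, 1.5, 2.0):
            assert scanner_pipeline(raw96, ScannerPipelineConfig(f)).pixels.min() >= 0

    def test_rss_nonlinearity_fills_periphery(self, raw96):
        """The padded region of the re-synthesized k-space is nonzero:
        the RSS step spreads energy outside the original box."""
        out = scanner_pipeline(raw96, ScannerPipelineConfig(2.0))
        k = np.abs(fft2c(out.pixels)) ** 2
        sl = out.original_box.slices()
        outside = k.sum() - k[sl].sum()
        assert outside > 1e-10 * k.sum()

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            ScannerPipelineConfig(0.5)


class TestJPEGPipeline:
    def test_quantization_only_bound(self, raw96):
        img = ground_truth_image(raw96)
        out = jpeg_pipeline(img, JPEGPipelineConfig("none")).pixels
        assert np.max(np.abs(out - img)) <= img.max() / 255 * 0.5 + 1e-9

    def test_byte_size_ordering(self):
        img = np.abs(make_phantom(PhantomSpec(height=96, width=96, seed=3)))
        assert len(jpeg_bytes(img, 20)) < len(jpeg_bytes(img, 75)) \
            < len(jpeg_bytes(img, 100))

    def test_compression_reduces_wavelet_l1(self, raw96):
        """Stronger compression yields a sparser image (entropy proxy)."""
        img = ground_truth_image(raw96)
        l1_20 = _wavelet_l1(jpeg_pipeline(img, JPEGPipelineConfig(20)).pixels)
        l1_75 = _wavelet_l1(jpeg_pipeline(img, JPEGPipelineConfig(75)).pixels)
        assert l1_20 < l1_75

    def test_l1_monotone_over_qf_ladder(self):
        """Wavelet-l1 non-increasing along QF 100 -> 75 -> 50 -> 20 on >=10
        seeds, allowing at most one violation as codec noise."""
        violations = 0
        for seed in range(10):
            ph = make_phantom(PhantomSpec(height=96, width=96, seed=seed))
            coils = make_coil_maps((96, 96), 2, seed=seed + 50)
            img = ground_truth_image(simulate_raw_kspace(ph, coils, 2e-3,
                                                         seed=seed + 100))
            l1 = [_wavelet_l1(jpeg_pipeline(img, JPEGPipelineConfig(q)).pixels)
                  for q in (100, 75, 50, 20)]
            violations += not all(l1[i + 1] <= l1[i] for i in range(3))
        assert violations <= 1

    def test_nonnegative_output(self, raw96):
        img = ground_truth_image(raw96)
        assert jpeg_pipeline(img, JPEGPipelineConfig(20)).pixels.min() >= 0

    @pytest.mark.parametrize("qf", [0, 101, -5, 3.5])
    def test_invalid_qf(self, qf):
        with pytest.raises(ValueError):
            JPEGPipelineConfig(qf)


class TestNormalize98:
    def test_constant_image(self):
        assert np.allclose(normalize_98(np.full((8, 8), 3.7)), 1.0)

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(1, 100, size=(40, 40))
        v = np.sort(img.ravel())
        # linear-interpolation percentile, straight from the definition
        q = 0.98 * (v.size - 1)
        lo, hi = int(np.floor(q)), int(np.ceil(q))
        p98 = v[lo] + (q - lo) * (v[hi] - v[lo])
        assert np.allclose(normalize_98(img), img / p98)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 5, size=(16, 16))
        once = normalize_98(img)
        assert np.allclose(normalize_98(once), once, rtol=1e-12)

    def test_nonpositive_percentile_rejected(self):
        with pytest.raises(ValueError):
            normalize_98(np.zeros((8, 8)))


class TestSynthesizeKSpace:
    def test_roundtrip(self, processed_2x):
        ks = synthesize_kspace(processed_2x)
        back = ifft2c(ks.data)
        assert np.max(np.abs(back - processed_2x.pixels)) < 1e-10

    def test_conjugate_symmetric(self, processed_2x):
        k = synthesize_kspace(processed_2x).data
        refl = np.conj(np.roll(k[::-1, ::-1], (1, 1), axis=(0, 1)))
        assert np.max(np.abs(k - refl)) < 1e-8 * np.abs(k).max()

    def test_original_box_propagated(self, processed_2x):
        ks = synthesize_kspace(processed_2x)
        assert ks.original_box == Box(48, 48, 96, 96)
        assert ks.data.shape == (192, 192)


class TestDetectZeroPad:
    def test_unpadded_gives_none(self, raw96):
        img = normalize_98(ground_truth_image(raw96))
        assert detect_zero_pad_box(fft2c(img)) is None

    def test_hard_zeros_exact(self):
        mag = np.abs(make_phantom(PhantomSpec(height=96, width=96, seed=1)))
        padded, true_box = zero_pad_kspace(fft2c(mag), 2.0)
        assert detect_zero_pad_box(padded) == true_box

    @pytest.mark.parametrize("factor", [1.5, 2.0])
    def test_scanner_output_within_tolerance(self, raw96, factor):
        """Recovered box within +/-2 px per edge of the provenance box."""
        proc = scanner_pipeline(raw96, ScannerPipelineConfig(factor))
        ks = fft2c(normalize_98(proc.pixels))
        est = detect_zero_pad_box(ks, threshold=1e-2)
        true = proc.original_box
        assert est is not None
        assert abs(est.row0 - true.row0) <= 2
        assert abs(est.col0 - true.col0) <= 2
        assert abs(est.height - true.height) <= 4
        assert abs(est.width - true.width) <= 4


class TestZeroPadGeometry:
    def test_dc_stays_centered(self):
        k = np.zeros((10, 10), dtype=complex)
        k[5, 5] = 1.0           # DC pixel of the centered convention
        padded, box = zero_pad_kspace(k, 1.5)
        assert padded.shape == (15, 15)
        assert padded[7, 7] == 1.0
        assert box == Box(2, 2, 10, 10)
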