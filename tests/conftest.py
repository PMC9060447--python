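import numpy as np
import pytest

from retrobias.fourier import fft2c
from retrobias.pipelines import ProcessedImage, normalize_98, scanner_pipeline, \
    ScannerPipelineConfig, synthesize_kspace
from retrobias.sampling import SamplingConfig, build_pdf, draw_mask
from retrobias.cs import EncodingOperator
from retrobias.simulate import PhantomSpec, make_phantom, make_coil_maps, \
    simulate_raw_kspace


@pytest.fixture(scope="session")
def phantom96():
    """Deterministic 96x96 complex phantom with fine details."""
    return make_phantom(PhantomSpec(height=96, width=96, n_features=5, seed=7))


@pytest.fixture(scope="session")
def coils96():
    return make_coil_maps((96, 96), 4, seed=11)


@pytest.fixture(scope="session")
def raw96(phantom96, coils96):
    return simulate_raw_kspace(phantom96, coils96, noise_sigma=2e-4, seed=13)


@pytest.fixture(scope="session")
def reference96(phantom96):
    """Normalized magnitude reference on the unpadded grid."""
    return normalize_98(np.abs(phantom96))


@pytest.fixture(scope="session")
def masked_problem96(reference96):
    """(reference, masked k-space, operator) at R=4 strong VD."""
    pdf = build_pdf((96, 96), SamplingConfig(scheme="strong_vd", R=4))
    mask = draw_mask(pdf, seed=3)
    op = EncodingOperator(mask.mask)
    y = op.mask * fft2c(reference96)
    return reference96, y, op


@pytest.fixture(scope="session")
def processed_2x(raw96):
    """2x zero-padded scanner-pipeline output with normalization."""
    proc = scanner_pipeline(raw96, ScannerPipelineConfig(2.0))
    return ProcessedImage(normalize_98(proc.pixels), proc.provenance)
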