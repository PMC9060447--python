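"""Dictionary learning: patch algebra, OMP, K-SVD, and the alternating
reconstruction."""

import numpy as np
import pytest

from retrobias.cs import EncodingOperator
from retrobias.dictl import (DictLConfig, Dictionary, calibrate_dictl,
                             dictl_reconstruct, ksvd_update, omp_encode,
                             overcomplete_dct, patch_assemble, patch_extract,
                             patch_grid)
from retrobias.fourier import fft2c
from retrobias.metrics import nrmse


class TestPatches:
    @pytest.mark.parametrize("stride", [1, 2, 4, 8])
    def test_assemble_inverts_extract(self, stride):
        rng = np.random.default_rng(0)
        img = rng.standard_normal((24, 24))
        p = patch_extract(img, 8, stride)
        assert np.allclose(patch_assemble(p, img.shape, 8, stride), img)

    def test_nonoverlapping_tiling_identity(self):
        rng = np.random.default_rng(1)
        img = rng.standard_normal((16, 16))
        p = patch_extract(img, 4, 4)
        assert p.shape == (16, 16)
        assert np.allclose(patch_assemble(p, img.shape, 4, 4), img)

    def test_patch_count_closed_form(self):
        rows, cols = patch_grid((33, 41), 8, 3)
        # ceil((n - b) / stride) + 1 grid positions incl. the forced
        # trailing offset
        assert len(rows) == int(np.ceil((33 - 8) / 3)) + 1
        assert len(cols) == int(np.ceil((41 - 8) / 3)) + 1

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError):
            patch_extract(np.zeros((6, 6)), 8, 1)


class TestOMP:
    def test_single_atom_patch(self):
        D = overcomplete_dct(4, 16)
        patch = 2.5 * D.atoms[:, [7]]
        code = omp_encode(patch, D, K=1)
        nz = np.flatnonzero(np.abs(code.codes[:, 0]) > 1e-12)
        assert list(nz) == [7]
        assert np.isclose(code.codes[7, 0], 2.5)

    def test_complete_basis_exact(self):
        """K = b^2 with a full-rank square dictionary reproduces any patch."""
        D = overcomplete_dct(4, 16)
        rng = np.random.default_rng(2)
        patches = rng.standard_normal((16, 10))
        code = omp_encode(patches, D, K=16)
        assert np.linalg.norm(patches - D.atoms @ code.codes) < 1e-8

    def test_sparsity_constraint(self):
        D = overcomplete_dct(6, 24)
        rng = np.random.default_rng(3)
        patches = rng.standard_normal((36, 50))
        code = omp_encode(patches, D, K=4)
        assert np.all((np.abs(code.codes) > 0).sum(axis=0) <= 4)

    def test_residuals_bounded_by_pair_enumeration(self):
        """For K=2 on 6-dim patches, OMP's residual cannot beat the optimum
        over all atom pairs with least-squares refit (brute-force oracle)."""
        rng = np.random.default_rng(4)
        atoms = rng.standard_normal((6, 8))
        atoms /= np.linalg.norm(atoms, axis=0)
        D = Dictionary(atoms)
        patches = rng.standard_normal((6, 20))
        code = omp_encode(patches, D, K=2)
        omp_res = np.linalg.norm(patches - atoms @ code.codes, axis=0)
        for li in range(20):
            best = np.inf
            for i in range(8):
                for j in range(i + 1, 8):
                    A = atoms[:, [i, j]]
                    coef, *_ = np.linalg.lstsq(A, patches[:, li], rcond=None)
                    best = min(best, np.linalg.norm(patches[:, li] - A @ coef))
            assert omp_res[li] >= best - 1e-10

    def test_zero_dictionary_rejected(self):
        with pytest.raises(ValueError):
            omp_encode(np.ones((4, 2)), Dictionary(np.zeros((4, 4))), K=1)


class TestKSVD:
    def test_rank1_data_recovers_direction(self):
        rng = np.random.default_rng(5)
        v = rng.standard_normal(16)
        patches = np.outer(v, rng.uniform(0.5, 2.0, size=30))
        D = overcomplete_dct(4, 8)
        code = omp_encode(patches, D, K=1)
        D2, code2 = ksvd_update(patches, D, code)
        used = np.flatnonzero((np.abs(code2.codes) > 0).any(axis=1))
        align = max(abs(np.dot(D2.atoms[:, p], v / np.linalg.norm(v)))
                    for p in used)
        assert align > 0.999

    def test_representation_error_nonincreasing(self):
        rng = np.random.default_rng(6)
        patches = rng.standard_normal((16, 20))
        D = overcomplete_dct(4, 8)
        code = omp_encode(patches, D, K=2)
        before = np.linalg.norm(patches - D.atoms @ code.codes)
        D2, code2 = ksvd_update(patches, D, code)
        after = np.linalg.norm(patches - D2.atoms @ code2.codes)
        assert after <= before + 1e-10

    def test_atom_norms_unit(self):
        rng = np.random.default_rng(7)
        patches = rng.standard_normal((16, 40))
        D = overcomplete_dct(4, 12)
        D2, _ = ksvd_update(patches, D, omp_encode(patches, D, K=2))
        norms = np.linalg.norm(D2.atoms, axis=0)
        assert np.all(norms <= 1 + 1e-8)
        assert np.all(norms >= 1 - 1e-8)

    def test_all_zero_patches_rejected(self):
        D = overcomplete_dct(4, 8)
        code = omp_encode(np.ones((16, 3)), D, K=1)
        with pytest.raises(ValueError):
            ksvd_update(np.zeros((16, 3)), D, code)


class TestDictLReconstruct:
    def test_full_mask_dc_dominated_identity(self, reference96):
        """With full sampling and a data-dominated blend the reconstruction
        returns the zero-filled image regardless of dictionary state."""
        op = EncodingOperator(np.ones((96, 96), dtype=bool))
        y = fft2c(reference96)
        cfg = DictLConfig(P=32, K=2, lam_D=1e-6, b=8, N_iter=2, L=200,
                          stride=4)
        res = dictl_reconstruct(y, op, cfg)
        assert nrmse(np.abs(res.image), reference96) < 1e-3

    def test_objective_trace_monotone(self, masked_problem96):
        _, y, op = masked_problem96
        cfg = DictLConfig(P=64, K=3, lam_D=0.1, b=8, N_iter=6, L=400,
                          stride=2, seed=0)
        res = dictl_reconstruct(y, op, cfg)
        tr = res.objective_trace
        assert np.all(np.diff(tr) <= 1e-8 * tr[0])

    def test_beats_zero_filled(self, masked_problem96):
        ref, y, op = masked_problem96
        cfg = DictLConfig(P=64, K=3, lam_D=0.05, b=8, N_iter=5, L=500,
                          stride=2, seed=0)
        res = dictl_reconstruct(y, op, cfg)
        assert nrmse(np.abs(res.image), ref) < nrmse(np.abs(op.adjoint(y)), ref)

    def test_sparsity_invariant_on_emitted_codes(self):
        rng = np.random.default_rng(8)
        patches = rng.standard_normal((64, 100))
        D = overcomplete_dct(8, 64)
        for K in (1, 3, 5):
            code = omp_encode(patches, D, K)
            assert np.all((np.abs(code.codes) > 0).sum(axis=0) <= K)

    def test_l_clamped_with_warning(self, masked_problem96):
        _, y, op = masked_problem96
        cfg = DictLConfig(P=16, K=2, lam_D=0.1, b=8, N_iter=1, L=10 ** 6,
                          stride=8)
        with pytest.warns(UserWarning):
            dictl_reconstruct(y, op, cfg)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            DictLConfig(K=0)
        with pytest.raises(ValueError):
            DictLConfig(K=100, b=4)
        with pytest.raises(ValueError):
            DictLConfig(b=1)


class TestCalibrateDictL:
    def _tuning_set(self, n=2):
        from retrobias.sampling import SamplingConfig, build_pdf, draw_mask
        from retrobias.simulate import PhantomSpec, make_phantom
        out = []
        for i in range(n):
            ref = np.abs(make_phantom(PhantomSpec(height=64, width=64, seed=i)))
            pdf = build_pdf((64, 64), SamplingConfig(scheme="strong_vd", R=3))
            op = EncodingOperator(draw_mask(pdf, seed=i).mask)
            out.append((ref, op.mask * fft2c(ref), op))
        return out

    def test_single_combination(self):
        cfg = DictLConfig(P=16, K=2, lam_D=0.1, b=4, N_iter=2, L=100, stride=4)
        assert calibrate_dictl(self._tuning_set(1), [cfg]) == cfg

    def test_matches_exhaustive_oracle(self):
        ts = self._tuning_set(2)
        grid = [DictLConfig(P=16, K=K, lam_D=lam, b=4, N_iter=2, L=200, stride=4)
                for K in (2, 4) for lam in (0.05, 0.5)]
        best = calibrate_dictl(ts, grid)
        errs = {}
        for cfg in grid:
            errs[cfg] = np.mean([nrmse(np.abs(dictl_reconstruct(y, op, cfg).image),
                                       ref) for ref, y, op in ts])
        assert errs[best] == min(errs.values())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            calibrate_dictl([], [DictLConfig()])
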