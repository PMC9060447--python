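"""Dictionary-learning reconstruction: alternating minimization with
batch OMP sparse coding and K-SVD dictionary updates.

Solves, per image and directly from the subsampled k-space,

    min_{x, A, D}  1/2 ||E x - y||_2^2 + lam_D/2 ||x - R(D A)||_2^2
        s.t.  ||a_l||_0 <= K,  ||d_p||_2 <= 1,

where ``R`` assembles overlapping b-by-b patches back into an image by
overlap-averaging.  Each outer iteration: sample L training patches from
the current image, sparse-code them (OMP) and refit the dictionary (K-SVD),
code *all* stride-grid patches with the refreshed dictionary, and update
the image in closed form in k-space — at measured locations
``(Fx)_k = (y_k + lam_D (F R(DA))_k) / (1 + lam_D)``, elsewhere
``(Fx)_k = (F R(DA))_k`` — the exact minimizer in ``x`` for fixed (D, A)
under the orthonormal FFT.  No training data beyond the measurements
themselves are used.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from retrobias.cs import EncodingOperator, ReconResult
from retrobias.fourier import fft2c, ifft2c
from retrobias.metrics import nrmse

__all__ = [
    "DictLConfig",
    "Dictionary",
    "SparseCode",
    "patch_extract",
    "patch_assemble",
    "patch_grid",
    "overcomplete_dct",
    "omp_encode",
    "ksvd_update",
    "dictl_reconstruct",
    "calibrate_dictl",
    "default_dictl_grid",
]


@dataclass(frozen=True)
class DictLConfig:
    """Hyperparameters of the per-image dictionary-learning solver.

    ``P`` atoms of size ``b*b``, sparsity level ``K``, data-consistency
    weight ``lam_D``, ``N_iter`` outer iterations, ``L`` training patches
    sampled per iteration, patch ``stride``.
    """

    P: int = 64
    K: int = 3
    lam_D: float = 0.1
    b: int = 8
    N_iter: int = 5
    L: int = 2000
    stride: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.P < 1 or self.N_iter < 1 or self.L < 1:
            raise ValueError("P, N_iter and L must be >= 1")
        if self.b < 2:
            raise ValueError("block edge b must be >= 2")
        if not 1 <= self.K <= self.b ** 2:
            raise ValueError("sparsity K must be in [1, b^2]")


@dataclass(frozen=True)
class Dictionary:
    """Atoms as columns of a ``(b^2, P)`` matrix, each with l2 norm <= 1."""

    atoms: np.ndarray

    @property
    def P(self) -> int:
        return self.atoms.shape[1]


@dataclass(frozen=True)
class SparseCode:
    """Per-patch coefficient vectors as columns of a ``(P, L)`` matrix,
    each with at most K nonzeros."""

    codes: np.ndarray
    K: int


# ---------------------------------------------------------------- patches

def patch_grid(shape: tuple[int, int], b: int, stride: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-left corners of the patch grid; the trailing offset is always
    included so every pixel is covered."""
    h, w = shape
    if b > min(h, w):
        raise ValueError("patch edge exceeds image size")
    rows = list(range(0, h - b + 1, stride))
    cols = list(range(0, w - b + 1, stride))
    if rows[-1] != h - b:
        rows.append(h - b)
    if cols[-1] != w - b:
        cols.append(w - b)
    return np.asarray(rows), np.asarray(cols)


def patch_extract(image: np.ndarray, b: int, stride: int = 1) -> np.ndarray:
    """All b-by-b patches on the stride grid, vectorized as columns of a
    ``(b^2, n_patches)`` matrix (row-major over the grid)."""
    rows, cols = patch_grid(image.shape, b, stride)
    out = np.empty((b * b, len(rows) * len(cols)), dtype=image.dtype)
    i = 0
    for r in rows:
        for c in cols:
            out[:, i] = image[r:r + b, c:c + b].ravel()
            i += 1
    return out


def patch_assemble(patches: np.ndarray, shape: tuple[int, int], b: int,
                   stride: int = 1) -> np.ndarray:
    """Overlap-average inverse of :func:`patch_extract`:
    ``patch_assemble(patch_extract(x)) == x``."""
    rows, cols = patch_grid(shape, b, stride)
    acc = np.zeros(shape, dtype=patches.dtype if np.iscomplexobj(patches) else float)
    count = np.zeros(shape)
    i = 0
    for r in rows:
        for c in cols:
            acc[r:r + b, c:c + b] += patches[:, i].reshape(b, b)
            count[r:r + b, c:c + b] += 1.0
            i += 1
    return acc / count


# ---------------------------------------------------------------- dictionary

def overcomplete_dct(b: int, P: int) -> Dictionary:
    """Overcomplete 2D-DCT dictionary: kron of 1D DCT frames, the standard
    deterministic initialization for K-SVD."""
    n1 = int(np.ceil(np.sqrt(P)))
    k = np.arange(n1)
    d1 = np.cos(np.pi * np.outer(np.arange(b), k) / n1)
    d1[:, 1:] -= d1[:, 1:].mean(axis=0)
    d1 /= np.linalg.norm(d1, axis=0)
    full = np.kron(d1, d1)  # (b^2, n1^2)
    return Dictionary(full[:, :P])


def _normalize_atoms(atoms: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(atoms, axis=0)
    return atoms / np.maximum(norms, 1e-12)


# ---------------------------------------------------------------- OMP

def omp_encode(patches: np.ndarray, D: Dictionary, K: int,
               tol: float = 1e-10) -> SparseCode:
    """Batch orthogonal matching pursuit.

    Greedy selection of up to ``K`` atoms per patch with a full
    least-squares refit after every selection; a patch stops early when its
    residual norm drops below ``tol``.  Vectorized over the patch batch.
    """
    A = D.atoms
    if not np.any(np.abs(A) > 0):
        raise ValueError("dictionary is identically zero")
    d, L = patches.shape
    P = A.shape[1]
    dtype = np.result_type(patches.dtype, A.dtype, float)
    codes = np.zeros((P, L), dtype=dtype)
    resid = patches.astype(dtype).copy()
    sel = np.full((L, K), -1, dtype=int)
    active = np.linalg.norm(resid, axis=0) > tol
    for step in range(K):
        if not active.any():
            break
        corr = np.abs(A.conj().T @ resid[:, active])        # (P, n_active)
        pick = np.argmax(corr, axis=0)
        idx_active = np.flatnonzero(active)
        sel[idx_active, step] = pick
        k = step + 1
        # batched least-squares refit on the selected atoms
        sub = A[:, sel[idx_active, :k]]                     # (d, n_active, k)
        sub = np.transpose(sub, (1, 0, 2))                  # (n_active, d, k)
        gram = np.einsum("nik,nil->nkl", sub.conj(), sub)
        gram += 1e-12 * np.eye(k)[None]
        rhs = np.einsum("nik,ni->nk", sub.conj(), patches[:, idx_active].T)
        coef = np.linalg.solve(gram, rhs[..., None])[..., 0]   # (n_active, k)
        approx = np.einsum("nik,nk->ni", sub, coef)
        resid[:, idx_active] = patches[:, idx_active] - approx.T
        block = np.zeros((len(idx_active), P), dtype=dtype)
        np.put_along_axis(block, sel[idx_active, :k], coef, axis=1)
        codes[:, idx_active] = block.T
        active[idx_active] = np.linalg.norm(resid[:, idx_active], axis=0) > tol
    return SparseCode(codes, K)


# ---------------------------------------------------------------- K-SVD

def ksvd_update(patches: np.ndarray, D: Dictionary, codes: SparseCode
                ) -> tuple[Dictionary, SparseCode]:
    """Sequential rank-1 K-SVD refit of every used atom (and its
    coefficients); unused atoms are replaced by the worst-represented patch.
    The total representation error ``||patches - D A||_F`` never increases.
    """
    if not np.any(np.abs(patches) > 0):
        raise ValueError("degenerate all-zero patch set")
    A = D.atoms.copy()
    X = codes.codes.copy()
    E_full = patches - A @ X
    for p in range(A.shape[1]):
        used = np.flatnonzero(np.abs(X[p]) > 0)
        if used.size == 0:
            err = np.linalg.norm(E_full, axis=0)
            worst = int(np.argmax(err))
            atom = patches[:, worst]
            nrm = np.linalg.norm(atom)
            if nrm > 1e-12:
                A[:, p] = atom / nrm
            continue
        # restricted error without atom p's contribution
        Ep = E_full[:, used] + np.outer(A[:, p], X[p, used])
        try:
            u, s, vh = np.linalg.svd(Ep, full_matrices=False)
            new_atom = u[:, 0]
            new_coef = s[0] * vh[0].conj()
        except np.linalg.LinAlgError:      # pragma: no cover - rare
            continue
        E_full[:, used] = Ep - np.outer(new_atom, new_coef)
        A[:, p] = new_atom
        X[p, used] = new_coef
    return Dictionary(_normalize_atoms(A)), SparseCode(X, codes.K)


# ---------------------------------------------------------------- solver

def _dictl_objective(x: np.ndarray, y: np.ndarray, op: EncodingOperator,
                     recon_patches_img: np.ndarray, lam_D: float) -> float:
    dc = 0.5 * float(np.sum(np.abs(op.forward(x) - op.mask * y) ** 2))
    reg = 0.5 * lam_D * float(np.sum(np.abs(x - recon_patches_img) ** 2))
    return dc + reg


def dictl_reconstruct(y: np.ndarray, op: EncodingOperator,
                      cfg: DictLConfig) -> ReconResult:
    """Alternating-minimization dictionary-learning reconstruction."""
    y = op.mask * np.asarray(y)
    rng = np.random.default_rng(cfg.seed)
    x = op.adjoint(y)
    D = overcomplete_dct(cfg.b, cfg.P)
    if np.iscomplexobj(y):
        D = Dictionary(D.atoms.astype(complex))
    trace = []
    best_obj = np.inf
    for _ in range(cfg.N_iter):
        all_patches = patch_extract(x, cfg.b, cfg.stride)
        n_patches = all_patches.shape[1]
        L = cfg.L
        if L > n_patches:
            warnings.warn("L exceeds available patches; clamping")
            L = n_patches
        train_idx = rng.choice(n_patches, size=L, replace=False)
        train = all_patches[:, train_idx]
        codes = omp_encode(train, D, cfg.K)
        D, _ = ksvd_update(train, D, codes)
        # code all stride-grid patches with the refreshed dictionary
        all_codes = omp_encode(all_patches, D, cfg.K)
        recon = patch_assemble(D.atoms @ all_codes.codes, x.shape, cfg.b,
                               cfg.stride)
        # closed-form image update in k-space
        z = fft2c(recon)
        k = np.where(op.mask, (y + cfg.lam_D * z) / (1.0 + cfg.lam_D), z)
        x_new = ifft2c(k)
        obj = _dictl_objective(x_new, y, op, recon, cfg.lam_D)
        # monotone acceptance: the greedy coding need not improve the
        # objective every pass; a worsening image update is rejected (the
        # dictionary keeps evolving and may succeed on a later pass)
        if obj <= best_obj:
            x, best_obj = x_new, obj
        trace.append(best_obj)
    return ReconResult(x, np.asarray(trace), cfg)


# ---------------------------------------------------------------- tuning

def default_dictl_grid() -> list[DictLConfig]:
    """Desk-scale hyperparameter grid (the full-scale search ran P up to
    300, K up to 13, b up to 32 and N_iter up to 13)."""
    combos = itertools.product([64, 128], [3, 5], [0.01, 0.1], [8], [5, 9])
    return [DictLConfig(P=P, K=K, lam_D=lam, b=b, N_iter=n)
            for P, K, lam, b, n in combos]


def calibrate_dictl(tuning_set: Sequence[tuple[np.ndarray, np.ndarray, EncodingOperator]],
                    grid: Sequence[DictLConfig]) -> DictLConfig:
    """Grid search minimizing mean NRMSE over ``(reference, masked k-space,
    operator)`` triples; ties break toward smaller P, then smaller K."""
    if not grid or not tuning_set:
        raise ValueError("grid and tuning set must be non-empty")
    ordered = sorted(grid, key=lambda c: (c.P, c.K))
    best_cfg, best_err = None, np.inf
    for cfg in ordered:
        errs = [nrmse(np.abs(dictl_reconstruct(y, op, cfg).image), ref)
                for ref, y, op in tuning_set]
        err = float(np.mean(errs))
        if err < best_err:
            best_cfg, best_err = cfg, err
    return best_cfg
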