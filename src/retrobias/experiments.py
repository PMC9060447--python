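"""Experiment drivers: effective sampling rate, processing-bias sweeps,
and the generalization gap.

Each driver is deterministic in its master seed: every phantom, coil set,
noise draw and sampling mask descends from it through a seed tree.  The
train/tune/test splits are disjoint at the synthetic-subject level, and a
fresh mask is drawn for every k-space example ("on-the-fly" masking), so no
solver is tuned to a particular mask realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Optional, Sequence, Union
import zlib

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from retrobias.cs import (CSConfig, EncodingOperator, calibrate_lambda,
                          fista_reconstruct)
from retrobias.dictl import DictLConfig, calibrate_dictl, dictl_reconstruct
from retrobias.metrics import nrmse, ssim
from retrobias.pipelines import (Box, JPEGPipelineConfig, ProcessedImage,
                                 ScannerPipelineConfig, jpeg_pipeline,
                                 normalize_98, scanner_pipeline,
                                 synthesize_kspace)
from retrobias.sampling import (SamplingConfig, build_pdf, draw_mask,
                                effective_rate, expected_effective_rate)
from retrobias.simulate import (PhantomSpec, RawKSpace, make_coil_maps,
                                make_phantom, simulate_raw_kspace)

__all__ = [
    "ExperimentConfig",
    "generate_raw_slices",
    "process_slice",
    "run_effective_rate_experiment",
    "run_crime1_experiment",
    "run_crime2_experiment",
    "run_impact_experiment",
    "paired_sign_test",
    "summarize",
]

Level = Union[float, int, str]


def _stable_tag(*parts: object) -> int:
    """Process-independent tag for seed derivation (builtin hash is salted)."""
    return zlib.crc32("|".join(map(repr, parts)).encode()) % (2 ** 16)



@dataclass(frozen=True)
class ExperimentConfig:
    """Shared configuration for the experiment drivers.

    ``pad_factors`` must include the clean baseline 1.0 and
    ``quality_factors`` must include ``"none"`` so every sweep has an
    unprocessed reference arm.
    """

    solvers: tuple[str, ...] = ("cs", "dictl")
    pad_factors: tuple[float, ...] = (1.0, 1.5, 2.0)
    quality_factors: tuple[Level, ...] = ("none", 75, 50, 20)
    scheme: str = "strong_vd"
    R: float = 4.0
    grid: int = 96
    n_coils: int = 4
    n_features: int = 8
    noise_sigma: float = 2e-3
    n_test: int = 20
    n_tune_cs: int = 10
    n_tune_dictl: int = 5
    n_masks: int = 15
    seed: int = 0
    cs_cfg: CSConfig = field(default_factory=lambda: CSConfig(
        n_iters=100, tol=1e-5, n_levels=3))
    lambda_grid: tuple[float, ...] = tuple(np.logspace(-4, -1, 7))
    dictl_grid: tuple[DictLConfig, ...] = tuple(
        DictLConfig(P=64, K=K, lam_D=lam, b=8, N_iter=5, L=500, stride=2)
        for K in (3, 5) for lam in (0.01, 0.1))

    def __post_init__(self) -> None:
        if 1.0 not in self.pad_factors:
            raise ValueError("pad_factors must include the baseline 1.0")
        if "none" not in self.quality_factors:
            raise ValueError("quality_factors must include 'none'")
        if not self.solvers:
            raise ValueError("solver list must be non-empty")


# ------------------------------------------------------------- data plumbing

def _child_seeds(master: int, n: int, tag: int = 0) -> np.ndarray:
    """Deterministic child seeds below 2**31."""
    return np.random.SeedSequence([master, tag]).generate_state(n) % (2 ** 31)


def generate_raw_slices(cfg: ExperimentConfig, n: int, tag: int
                        ) -> list[RawKSpace]:
    """``n`` fully sampled multicoil slices; ``tag`` separates splits so
    tune and test subjects never overlap."""
    seeds = _child_seeds(cfg.seed, 2 * n, tag)
    coils = make_coil_maps((cfg.grid, cfg.grid), cfg.n_coils,
                           seed=int(_child_seeds(cfg.seed, 1, 999)[0]))
    out = []
    for i in range(n):
        spec = PhantomSpec(height=cfg.grid, width=cfg.grid,
                           n_features=cfg.n_features,
                           noise_sigma=cfg.noise_sigma, seed=int(seeds[2 * i]))
        img = make_phantom(spec)
        out.append(simulate_raw_kspace(img, coils, cfg.noise_sigma,
                                       seed=int(seeds[2 * i + 1])))
    return out


def process_slice(raw: RawKSpace, crime: str, level: Level) -> ProcessedImage:
    """Run one slice through a processing pipeline and the training-time
    intensity normalization; returns the per-level gold standard."""
    if crime == "zero_pad":
        proc = scanner_pipeline(raw, ScannerPipelineConfig(float(level)))
    elif crime == "jpeg":
        rss = scanner_pipeline(raw, ScannerPipelineConfig(1.0))
        proc = jpeg_pipeline(rss.pixels, JPEGPipelineConfig(level))
    else:
        raise ValueError(f"unknown crime {crime!r}")
    return ProcessedImage(normalize_98(proc.pixels), proc.provenance)


def _masked_example(ref: ProcessedImage, cfg: ExperimentConfig, seed: int
                    ) -> tuple[np.ndarray, np.ndarray, EncodingOperator]:
    """(reference, masked k-space, operator) with an on-the-fly mask."""
    ks = synthesize_kspace(ref)
    pdf = build_pdf(ks.data.shape, SamplingConfig(scheme=cfg.scheme, R=cfg.R))
    mask = draw_mask(pdf, seed=seed)
    op = EncodingOperator(mask.mask)
    return ref.pixels, op.mask * ks.data, op


def _reconstruct(solver: str, y: np.ndarray, op: EncodingOperator,
                 params: Any) -> np.ndarray:
    if solver == "cs":
        return np.abs(fista_reconstruct(y, op, params).image)
    if solver == "dictl":
        return np.abs(dictl_reconstruct(y, op, params).image)
    raise ValueError(f"unknown solver {solver!r}")


def calibrate_solvers(cfg: ExperimentConfig, crime: str, level: Level,
                      tune_cs: Sequence[RawKSpace],
                      tune_dictl: Sequence[RawKSpace]) -> dict[str, Any]:
    """Per-level ("instance-optimal") hyperparameter calibration."""
    params: dict[str, Any] = {}
    if "cs" in cfg.solvers:
        seeds = _child_seeds(cfg.seed, len(tune_cs), tag=_stable_tag("tune_cs", str(level)))
        triples = [_masked_example(process_slice(r, crime, level), cfg, int(s))
                   for r, s in zip(tune_cs, seeds)]
        lam = calibrate_lambda(triples, cfg.lambda_grid, cfg.cs_cfg)
        params["cs"] = replace(cfg.cs_cfg, lam=lam)
    if "dictl" in cfg.solvers:
        seeds = _child_seeds(cfg.seed, len(tune_dictl), tag=_stable_tag("tune_dictl", str(level)))
        triples = [_masked_example(process_slice(r, crime, level), cfg, int(s))
                   for r, s in zip(tune_dictl, seeds)]
        params["dictl"] = calibrate_dictl(triples, cfg.dictl_grid)
    return params


# ------------------------------------------------------------- experiments

def run_effective_rate_experiment(
        base_grid: int = 320,
        pad_factors: Sequence[float] = (1.0, 1.5, 2.0),
        schemes: Sequence[str] = ("uniform", "weak_vd", "strong_vd"),
        R: float = 6.0,
        n_masks: int = 15,
        seed: int = 0) -> pd.DataFrame:
    """Global vs. effective sampling rate per (scheme, zero-pad factor).

    For each cell: build the PDF at rate ``1/R`` on the padded grid, draw
    ``n_masks`` Monte-Carlo masks, and average the sampled fraction inside
    the original (nonpadded) central box; the analytic expectation (PDF
    mean over the box) is reported alongside.
    """
    rows = []
    for scheme in schemes:
        for f in pad_factors:
            g = int(round(f * base_grid))
            box = Box.centered((g, g), (base_grid, base_grid))
            pdf = build_pdf((g, g), SamplingConfig(scheme=scheme, R=R))
            seeds = _child_seeds(seed, n_masks, tag=_stable_tag(scheme, f))
            rates = [effective_rate(draw_mask(pdf, int(s)), box) for s in seeds]
            p_box = pdf.prob[box.slices()]
            rows.append({
                "scheme": scheme, "pad_factor": f, "R": R,
                "global_rate": 1.0 / R,
                "mean_effective_rate": float(np.mean(rates)),
                "sd_effective_rate": float(np.std(rates, ddof=1)),
                "expected_effective_rate": expected_effective_rate(pdf, box),
                # exact per-mask binomial sd of the effective rate
                "binomial_sd": float(np.sqrt((p_box * (1 - p_box)).sum())
                                     / p_box.size),
                "n_masks": n_masks, "seed": seed,
            })
    return pd.DataFrame(rows)


def _run_crime(cfg: ExperimentConfig, crime: str, levels: Sequence[Level],
               calibrations: Optional[dict[Level, dict[str, Any]]] = None
               ) -> dict[str, Any]:
    tune_cs = generate_raw_slices(cfg, cfg.n_tune_cs, tag=1)
    tune_dictl = generate_raw_slices(cfg, cfg.n_tune_dictl, tag=2)
    test = generate_raw_slices(cfg, cfg.n_test, tag=3)
    calib = dict(calibrations or {})
    rows = []
    for level in levels:
        if level not in calib:
            calib[level] = calibrate_solvers(cfg, crime, level, tune_cs, tune_dictl)
        mask_seeds = _child_seeds(cfg.seed, cfg.n_test,
                                  tag=_stable_tag("test", crime, str(level)))
        for i, raw in enumerate(test):
            ref_img = process_slice(raw, crime, level)
            ref, y, op = _masked_example(ref_img, cfg, int(mask_seeds[i]))
            for solver in cfg.solvers:
                recon = _reconstruct(solver, y, op, calib[level][solver])
                rows.append({
                    "solver": solver, "crime": crime, "level": level,
                    "scheme": cfg.scheme, "R": cfg.R, "slice": i,
                    "nrmse": nrmse(recon, ref), "ssim": ssim(recon, ref),
                    "seed": cfg.seed,
                })
    return {"per_slice": pd.DataFrame(rows),
            "table": summarize(pd.DataFrame(rows)),
            "calibrations": calib}


def run_crime1_experiment(cfg: ExperimentConfig) -> dict[str, Any]:
    """Zero-padding bias sweep: per pad factor, calibrate each solver on
    that level's tuning split, reconstruct the test split against that
    level's own (processed) gold standard, tabulate NRMSE/SSIM."""
    return _run_crime(cfg, "zero_pad", list(cfg.pad_factors))


def run_crime2_experiment(cfg: ExperimentConfig) -> dict[str, Any]:
    """JPEG-compression bias sweep over quality factors."""
    return _run_crime(cfg, "jpeg", list(cfg.quality_factors))


def run_impact_experiment(cfg: ExperimentConfig,
                          calibrations: Optional[dict[Level, dict[str, Any]]] = None,
                          crime: str = "zero_pad") -> dict[str, Any]:
    """Generalization gap: hyperparameters calibrated on each processed
    level are applied both to that level's processed test k-space and to
    the unprocessed test k-space; each arm is scored against its own
    matching reference."""
    levels: Sequence[Level] = (cfg.pad_factors if crime == "zero_pad"
                               else cfg.quality_factors)
    baseline: Level = 1.0 if crime == "zero_pad" else "none"
    tune_cs = generate_raw_slices(cfg, cfg.n_tune_cs, tag=1)
    tune_dictl = generate_raw_slices(cfg, cfg.n_tune_dictl, tag=2)
    test = generate_raw_slices(cfg, cfg.n_test, tag=3)
    calib = dict(calibrations or {})
    rows = []
    for level in levels:
        if level not in calib:
            calib[level] = calibrate_solvers(cfg, crime, level, tune_cs, tune_dictl)
        for arm, arm_level in (("processed", level), ("unprocessed", baseline)):
            mask_seeds = _child_seeds(
                cfg.seed, cfg.n_test,
                tag=_stable_tag("impact", crime, str(level), arm))
            for i, raw in enumerate(test):
                ref_img = process_slice(raw, crime, arm_level)
                ref, y, op = _masked_example(ref_img, cfg, int(mask_seeds[i]))
                for solver in cfg.solvers:
                    recon = _reconstruct(solver, y, op, calib[level][solver])
                    rows.append({
                        "solver": solver, "crime": crime, "level": level,
                        "arm": arm, "slice": i,
                        "nrmse": nrmse(recon, ref), "ssim": ssim(recon, ref),
                    })
    per_slice = pd.DataFrame(rows)
    gap_rows = []
    for (solver, level), grp in per_slice.groupby(["solver", "level"]):
        proc = grp[grp.arm == "processed"].sort_values("slice")["nrmse"].to_numpy()
        unproc = grp[grp.arm == "unprocessed"].sort_values("slice")["nrmse"].to_numpy()
        gap_rows.append({
            "solver": solver, "level": level,
            "nrmse_processed": float(proc.mean()),
            "nrmse_unprocessed": float(unproc.mean()),
            "relative_gap": float((unproc.mean() - proc.mean()) / proc.mean()),
            "p_sign": paired_sign_test(unproc, proc),
            "n": len(proc),
        })
    return {"per_slice": per_slice, "table": pd.DataFrame(gap_rows),
            "calibrations": calib}


# ------------------------------------------------------------- statistics

def summarize(per_slice: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD NRMSE and SSIM per (solver, level) configuration cell."""
    keys = [k for k in ("solver", "crime", "level", "scheme", "R")
            if k in per_slice.columns]
    g = per_slice.groupby(keys, sort=False)
    out = g.agg(mean_nrmse=("nrmse", "mean"), sd_nrmse=("nrmse", "std"),
                mean_ssim=("ssim", "mean"), sd_ssim=("ssim", "std"),
                n=("nrmse", "size")).reset_index()
    return out


def paired_sign_test(a: np.ndarray, b: np.ndarray) -> float:
    """One-sided paired sign test for H1: b < a (b is the improved arm).

    Ties are dropped; returns the binomial p-value for the number of pairs
    with ``b < a`` among the non-tied pairs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    wins = int(np.sum(b < a))
    n = int(np.sum(b != a))
    if n == 0:
        return 1.0
    return float(binomtest(wins, n, 0.5, alternative="greater").pvalue)
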