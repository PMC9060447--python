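"""File I/O: HDF5 slice files, PNG/NPZ export, provenance sidecars.

The HDF5 layout follows the dialect of the public raw k-space archives: a
``kspace`` dataset of complex multicoil slices, shape
``(n_slices, n_coils, H, W)``, so real data can stand in for the synthetic
generator when available.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Union

import h5py
import numpy as np
from PIL import Image

from retrobias.simulate import RawKSpace

__all__ = [
    "write_kspace_h5",
    "read_kspace_h5",
    "export_png",
    "save_mask_npz",
    "load_mask_npz",
    "write_provenance",
    "save_pdf_profile_csv",
    "export_dictionary_npz",
    "export_atom_montage_png",
]

PathLike = Union[str, Path]


def write_kspace_h5(path: PathLike, slices: list[RawKSpace]) -> None:
    """Write slices as a ``kspace`` dataset (n_slices, n_coils, H, W)."""
    data = np.stack([s.data for s in slices]).astype(np.complex64)
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=data)
        f.attrs["provenance"] = json.dumps(
            [s.provenance for s in slices], default=str)


def read_kspace_h5(path: PathLike) -> list[RawKSpace]:
    """Read a slice file; accepts any file with a ``kspace`` dataset."""
    with h5py.File(path, "r") as f:
        data = np.asarray(f["kspace"])
        prov = json.loads(f.attrs.get("provenance", "[]"))
    if data.ndim == 3:          # single slice stored without the slice axis
        data = data[None]
    return [RawKSpace(np.asarray(d, dtype=complex),
                      provenance=prov[i] if i < len(prov) else {})
            for i, d in enumerate(data)]


def export_png(path: PathLike, image: np.ndarray) -> None:
    """8-bit max-scaled grayscale PNG export of a magnitude image."""
    image = np.abs(np.asarray(image, dtype=float))
    scale = image.max()
    if scale <= 0:
        scale = 1.0
    img8 = np.round(image / scale * 255.0).astype(np.uint8)
    Image.fromarray(img8, mode="L").save(path, format="PNG")


def save_mask_npz(path: PathLike, mask: np.ndarray, **meta: Any) -> None:
    np.savez(path, mask=np.asarray(mask, dtype=bool), **meta)


def load_mask_npz(path: PathLike) -> np.ndarray:
    return np.load(path)["mask"].astype(bool)


def write_provenance(path: PathLike, provenance: dict[str, Any]) -> None:
    """JSON sidecar describing how an artifact was produced."""
    Path(path).write_text(json.dumps(provenance, indent=2, default=str))


def save_pdf_profile_csv(path: PathLike, prob: np.ndarray) -> None:
    """Radial profile of a sampling PDF (the central row and column) as
    CSV, for plotting density profiles."""
    h, w = prob.shape
    rows = ["index,row_profile,col_profile"]
    for i in range(max(h, w)):
        r = prob[i, w // 2] if i < h else ""
        c = prob[h // 2, i] if i < w else ""
        rows.append(f"{i},{r},{c}")
    Path(path).write_text("\n".join(rows) + "\n")


def export_dictionary_npz(path: PathLike, atoms: np.ndarray) -> None:
    """Dictionary atoms (columns of a (b^2, P) matrix) as NPZ."""
    np.savez(path, atoms=atoms)


def export_atom_montage_png(path: PathLike, atoms: np.ndarray) -> None:
    """Square montage of dictionary atoms for visual inspection."""
    d, P = atoms.shape
    b = int(round(np.sqrt(d)))
    n = int(np.ceil(np.sqrt(P)))
    canvas = np.zeros((n * (b + 1), n * (b + 1)))
    for p_i in range(P):
        a = np.abs(atoms[:, p_i]).reshape(b, b)
        a = a / (a.max() + 1e-30)
        r, c = divmod(p_i, n)
        canvas[r * (b + 1):r * (b + 1) + b, c * (b + 1):c * (b + 1) + b] = a
    export_png(path, canvas)
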