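"""Reading and writing the standard on-disk formats (NIfTI-1, motion text)."""

from __future__ import annotations

import numpy as np
import nibabel as nib

from cordbold.morphometry import CordMask

__all__ = [
    "save_mask",
    "save_volume",
    "save_bold",
    "load_bold",
    "save_motion",
    "load_motion",
]


def _affine(voxel_dims) -> np.ndarray:
    return np.diag([voxel_dims[0], voxel_dims[1], voxel_dims[2], 1.0])


def save_mask(mask: CordMask, path: str) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.voxel_dims))
    img.header.set_zooms(mask.voxel_dims)
    nib.save(img, path)


def save_volume(data: np.ndarray, voxel_dims, path: str) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_dims))
    img.header.set_zooms(voxel_dims)
    nib.save(img, path)


def save_bold(data: np.ndarray, voxel_dims, tr: float, path: str) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_dims))
    img.header.set_zooms((*voxel_dims, tr))
    nib.save(img, path)


def load_bold(path: str) -> tuple[np.ndarray, tuple[float, float, float], float]:
    """Return (4-D data, voxel dims mm, TR s)."""
    img = nib.load(path)
    zooms = img.header.get_zooms()
    return np.asarray(img.dataobj, dtype=float), tuple(float(z) for z in zooms[:3]), float(zooms[3])


def save_motion(motion: np.ndarray, path: str) -> None:
    """Whitespace-delimited 6 columns: translations mm, rotations rad."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be (n_volumes, 6), got {motion.shape}")
    np.savetxt(path, motion, fmt="%.8f")


def load_motion(path: str) -> np.ndarray:
    motion = np.loadtxt(path)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion file must have 6 columns, got shape {motion.shape}")
    return motion
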