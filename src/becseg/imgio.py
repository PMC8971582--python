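"""Image and mask file IO: PNG/TIFF, single NIfTI slices, provenance sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_gray", "write_mask", "read_mask", "write_provenance"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_gray(path, nifti_slice: int | None = None) -> np.ndarray:
    """Load a 2-D grayscale image.

    PNG/TIFF: RGB(A) inputs are collapsed to gray by the channel mean (alpha
    dropped).  NIfTI volumes require ``nifti_slice``, the axial (last-axis)
    slice index.  Values are returned as stored; intensity normalization
    happens later in the segmenter.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj)
        if vol.ndim != 3:
            raise ValueError(f"expected a 3-D NIfTI volume, got shape {vol.shape}")
        if nifti_slice is None:
            raise ValueError("a NIfTI input needs an axial slice index")
        if not 0 <= nifti_slice < vol.shape[2]:
            raise ValueError(
                f"slice {nifti_slice} out of range for {vol.shape[2]} axial slices"
            )
        return np.asarray(vol[:, :, nifti_slice], dtype=float)
    if path.suffix.lower() not in (".png", ".tif", ".tiff"):
        raise ValueError(f"unsupported image format: {path.suffix!r}")
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)  # luminance average; drop alpha
    if img.ndim != 2:
        raise ValueError(f"cannot interpret image of shape {img.shape} as grayscale")
    return img.astype(float)


def write_mask(mask, path) -> None:
    """Save a 0/1 mask as a single-channel 0/255 PNG."""
    m = np.asarray(mask)
    if not np.all(np.isin(np.unique(m), (0, 1))):
        raise ValueError("mask must be binary 0/1")
    iio.imwrite(Path(path), (m.astype(np.uint8) * 255))


def read_mask(path) -> np.ndarray:
    """Load a mask PNG back to 0/1 (any nonzero pixel counts as foreground)."""
    img = np.asarray(iio.imread(Path(path)))
    if img.ndim == 3:
        img = img[..., :3].max(axis=2)
    return (img > 0).astype(np.uint8)


def write_provenance(path, record: dict) -> None:
    """JSON sidecar with the parameters and seeds that produced an output."""
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
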