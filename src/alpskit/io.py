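"""Diffusion-MRI file IO: NIfTI volumes and FSL-style bval/bvec gradient tables.

Signals are always held as floating point (the fit works in log space), and
gradient directions are interpreted in the image coordinate frame of the
supplied volumes — the data are assumed preprocessed, so no gradient
re-orientation is performed.
"""
from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: b-values at or below this are treated as non-diffusion-weighted (s/mm^2).
DEFAULT_B0_THRESHOLD = 50.0

#: b-values are snapped to the nearest multiple of this when assigning shells,
#: absorbing per-volume vendor jitter.
SHELL_ROUNDING = 50.0

#: Tolerated deviation of a diffusion-weighted direction from unit norm.
BVEC_NORM_TOL = 1e-3


@dataclass(frozen=True)
class GradientTable:
    """A multi-shell acquisition scheme: b-values plus unit directions.

    Parameters
    ----------
    bvals : (M,) array
        Diffusion weightings in s/mm^2.
    bvecs : (M, 3) array
        Unit direction cosines; rows for b0 entries may be zero.
    b0_threshold : float
        b-values at or below this are labelled shell 0.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_threshold: float = DEFAULT_B0_THRESHOLD
    shell_labels: np.ndarray = field(init=False)

    def __post_init__(self):
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvals.ndim != 1 or bvals.size < 1:
            raise ValueError("bvals must be a non-empty 1D array")
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"bvecs shape {bvecs.shape} does not match {bvals.size} b-values"
            )
        norms = np.linalg.norm(bvecs, axis=1)
        dw = bvals > self.b0_threshold
        bad = dw & (np.abs(norms - 1.0) > BVEC_NORM_TOL)
        if np.any(bad):
            raise ValueError(
                f"{bad.sum()} diffusion-weighted direction(s) deviate from unit "
                f"norm by more than {BVEC_NORM_TOL}"
            )
        shells = np.where(dw, SHELL_ROUNDING * np.round(bvals / SHELL_ROUNDING), 0.0)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "shell_labels", shells.astype(int))

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.shell_labels == 0

    @property
    def shells(self) -> np.ndarray:
        """Sorted distinct nonzero shell b-values."""
        return np.unique(self.shell_labels[self.shell_labels > 0])

    @property
    def dki_capable(self) -> bool:
        """Whether the scheme can determine the 22-parameter kurtosis model."""
        return self.shells.size >= 2 and len(self) >= 22


def _parse_rows(text) -> np.ndarray:
    if isinstance(text, (str, Path)) and "\n" not in str(text) and Path(text).exists():
        text = Path(text).read_text()
    elif hasattr(text, "read"):
        text = text.read()
    rows = []
    for line in str(text).splitlines():
        line = line.strip()
        if not line:
            continue
        try:
            rows.append([float(tok) for tok in line.split()])
        except ValueError as exc:
            raise ValueError(f"non-numeric token in gradient file: {exc}") from exc
    if not rows:
        raise ValueError("empty gradient file")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("ragged rows in gradient file")
    return np.asarray(rows, dtype=float)


def load_gradients(
    bval_text,
    bvec_text,
    b0_threshold: float = DEFAULT_B0_THRESHOLD,
    strict: bool = True,
) -> GradientTable:
    """Parse FSL-dialect bval/bvec content into a validated gradient table.

    ``bval_text``/``bvec_text`` may be file paths, open streams, or raw text.
    The bvec matrix is accepted as 3xM (FSL convention) or Mx3; orientation is
    auto-detected from the shape. With ``strict=False``, off-unit directions
    are renormalized with a warning instead of raising.
    """
    bvals = _parse_rows(bval_text).ravel()
    bvecs = _parse_rows(bvec_text)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] == 3 and bvecs.shape[0] != 3:
        pass  # already Mx3
    elif bvecs.shape == (3, 3):
        # Ambiguous square case: FSL files are rows-of-M, so treat as 3xM.
        bvecs = bvecs.T
    else:
        raise ValueError(f"bvec matrix must be 3xM or Mx3, got {bvecs.shape}")
    if bvecs.shape[0] != bvals.size:
        raise ValueError(
            f"bval count {bvals.size} does not match bvec count {bvecs.shape[0]}"
        )
    if not strict:
        norms = np.linalg.norm(bvecs, axis=1)
        dw = bvals > b0_threshold
        off = dw & (np.abs(norms - 1.0) > BVEC_NORM_TOL)
        if np.any(off):
            warnings.warn(
                f"renormalizing {off.sum()} off-unit gradient direction(s)",
                stacklevel=2,
            )
            bvecs = bvecs.copy()
            bvecs[off] /= norms[off, None]
    return GradientTable(bvals, bvecs, b0_threshold=b0_threshold)


@dataclass
class DWIVolume:
    """A 4D diffusion-weighted series with its acquisition scheme.

    ``data`` is stored as float64 regardless of on-disk dtype; the 4th axis
    must match the gradient table length.
    """

    data: np.ndarray
    affine: np.ndarray
    gradients: GradientTable
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("not a 4D series")
        if self.data.shape[3] != len(self.gradients):
            raise ValueError(
                f"4th dimension ({self.data.shape[3]}) does not match gradient "
                f"table length ({len(self.gradients)})"
            )
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape does not match spatial shape")

    @property
    def shape(self):
        return self.data.shape


def load_dwi(
    image_path,
    bval_path,
    bvec_path,
    mask_path=None,
    b0_threshold: float = DEFAULT_B0_THRESHOLD,
) -> DWIVolume:
    """Load a NIfTI DWI series with its FSL gradient files (and optional mask)."""
    img = nib.load(str(image_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{image_path}: not a 4D series (got {data.ndim}D)")
    gradients = load_gradients(bval_path, bvec_path, b0_threshold=b0_threshold)
    mask = None
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mask = np.asanyarray(mimg.dataobj) > 0
    return DWIVolume(data=data, affine=img.affine, gradients=gradients, mask=mask)


def save_map(volume: np.ndarray, affine: np.ndarray, path, dtype=np.float32) -> None:
    """Write a 3D scalar map as NIfTI (float32 by default; NaNs preserved)."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D map, got {volume.ndim}D")
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    img = nib.Nifti1Image(volume.astype(dtype), affine)
    nib.save(img, str(path))


def save_dwi(dwi: DWIVolume, image_path, bval_path, bvec_path) -> None:
    """Write a DWI series as NIfTI (float64, lossless) + FSL bval/bvec files."""
    img = nib.Nifti1Image(dwi.data.astype(np.float64), dwi.affine)
    nib.save(img, str(image_path))
    g = dwi.gradients
    Path(bval_path).write_text(" ".join(f"{b:g}" for b in g.bvals) + "\n")
    lines = [" ".join(f"{v:.10f}" for v in g.bvecs[:, ax]) for ax in range(3)]
    Path(bvec_path).write_text("\n".join(lines) + "\n")
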