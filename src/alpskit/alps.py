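"""ALPS indices: four spherical ROIs and the perivascular diffusivity ratios.

At the lateral-ventricle body the perivascular space runs right-left (x),
projection fibres run inferior-superior (z) and association fibres run
anterior-posterior (y). The indices contrast x-axis diffusion — perpendicular
to both fibre systems, along the perivascular space — with the dominant-fibre
perpendicular diffusivities:

    DTI-ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)
    DKI-ALPS = mean(Kxxxx_proj, Kxxxx_assoc) / mean(Kyyyy_proj, Kzzzz_assoc)

computed per hemisphere; the whole-brain index defaults to the mean of the
left and right indices.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .tensor import AxisMetricMaps

ROI_KEYS = ("proj_left", "assoc_left", "proj_right", "assoc_right")
DEFAULT_DIAMETER_MM = 5.0

#: Editable default sphere centres (MNI mm) on the lateral-ventricle-body
#: plane of the 1 mm JHU-ICBM-FA template: projection ROIs medial, association
#: ROIs lateral, mirrored across x = 0. These are package defaults for
#: template-space maps, not study-reported coordinates; user-supplied masks or
#: a JSON config override them.
DEFAULT_MNI_CENTERS = {
    "proj_left": (-26.0, -14.0, 26.0),
    "assoc_left": (-36.0, -14.0, 26.0),
    "proj_right": (26.0, -14.0, 26.0),
    "assoc_right": (36.0, -14.0, 26.0),
}

#: An ROI keeps a subject only if at least this fraction of its voxels is valid.
MIN_VALID_FRACTION = 0.5


@dataclass
class AlpsRoiSet:
    """The four-sphere ALPS geometry (or four explicit mask volumes)."""

    centers: dict | None = None          # key -> world-mm 3-vector
    diameter: float = DEFAULT_DIAMETER_MM
    masks: dict | None = None            # key -> 3D bool array (alternative)
    source: str = "config"

    def __post_init__(self):
        ref = self.masks if self.masks is not None else self.centers
        if ref is None:
            raise ValueError("either sphere centers or mask volumes are required")
        if set(ref) != set(ROI_KEYS):
            raise ValueError(f"ROI set must have exactly the keys {ROI_KEYS}")
        if self.masks is None and not self.diameter > 0:
            raise ValueError("ROI diameter must be positive")

    @classmethod
    def from_config(cls, config) -> "AlpsRoiSet":
        """Build from a JSON file/dict: {'diameter_mm': 5, 'centers_mm': {...}}."""
        if isinstance(config, (str, Path)):
            config = json.loads(Path(config).read_text())
        centers = {k: tuple(map(float, v)) for k, v in config["centers_mm"].items()}
        return cls(centers=centers,
                   diameter=float(config.get("diameter_mm", DEFAULT_DIAMETER_MM)),
                   source="config")

    @classmethod
    def from_masks(cls, paths: dict) -> "AlpsRoiSet":
        """Build from four 0/1 NIfTI mask files keyed by ROI name."""
        masks = {k: np.asanyarray(nib.load(str(p)).dataobj) > 0
                 for k, p in paths.items()}
        return cls(masks=masks, source="mask-files")

    def mask_for(self, key: str, affine: np.ndarray, shape) -> np.ndarray:
        if self.masks is not None:
            m = self.masks[key]
            if m.shape != tuple(shape):
                raise ValueError(f"ROI mask {key!r} shape {m.shape} != map shape {shape}")
            return m
        m = sphere_mask(self.centers[key], self.diameter, affine, shape, name=key)
        return m

    def all_masks(self, affine, shape) -> dict:
        masks = {k: self.mask_for(k, affine, shape) for k in ROI_KEYS}
        for side in ("left", "right"):
            if np.any(masks[f"proj_{side}"] & masks[f"assoc_{side}"]):
                raise ValueError(f"proj and assoc ROIs overlap on the {side} side")
        return masks


def sphere_mask(center, diameter: float, affine: np.ndarray, shape,
                name: str = "ROI") -> np.ndarray:
    """Voxels whose centre lies within ``diameter/2`` mm of a world-space point."""
    center = np.asarray(center, dtype=float)
    shape = tuple(shape)
    ijk = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), -1)
    world = ijk @ affine[:3, :3].T + affine[:3, 3]
    mask = np.sum((world - center) ** 2, axis=-1) <= (diameter / 2.0) ** 2
    if not mask.any():
        raise ValueError(
            f"{name}: 5 mm-scale sphere at {tuple(center)} contains no voxel "
            "centres (outside the volume or smaller than the voxel spacing)"
        )
    return mask


@dataclass
class RoiDiffusivities:
    """ROI-mean axis metrics for one hemisphere."""

    dxx_proj: float
    dxx_assoc: float
    dyy_proj: float
    dzz_assoc: float
    kxxxx_proj: float
    kxxxx_assoc: float
    kyyyy_proj: float
    kzzzz_assoc: float
    side: str
    voxel_counts: dict = field(default_factory=dict)
    flagged: bool = False


@dataclass
class AlpsResult:
    """Left/right/global DTI- and DKI-ALPS ratios with provenance."""

    dti_left: float
    dti_right: float
    dti_global: float
    dki_left: float
    dki_right: float
    dki_global: float
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "dti_left": self.dti_left, "dti_right": self.dti_right,
            "dti_global": self.dti_global, "dki_left": self.dki_left,
            "dki_right": self.dki_right, "dki_global": self.dki_global,
        }


def _roi_mean(volume: np.ndarray, mask: np.ndarray, name: str):
    vals = volume[mask]
    valid = np.isfinite(vals)
    if not valid.any():
        raise ValueError(f"ROI {name!r} contains no valid (non-NaN) voxels")
    return float(vals[valid].mean()), int(valid.sum()), int(vals.size)


def extract_roi_means(maps: AxisMetricMaps, roiset: AlpsRoiSet,
                      side: str) -> RoiDiffusivities:
    """Mean axis metrics over the proj/assoc spheres of one hemisphere.

    NaN voxels are excluded; an ROI retaining fewer than half of its voxels
    sets the ``flagged`` bit (subject-level QC).
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    shape = maps.dxx.shape
    proj = roiset.mask_for(f"proj_{side}", maps.affine, shape)
    assoc = roiset.mask_for(f"assoc_{side}", maps.affine, shape)
    if np.any(proj & assoc):
        raise ValueError(f"proj and assoc ROIs overlap on the {side} side")

    counts = {}
    vals = {}
    for label, mask, metric_names in (
        (f"proj_{side}", proj, ("dxx_proj", "dyy_proj", "kxxxx_proj", "kyyyy_proj")),
        (f"assoc_{side}", assoc, ("dxx_assoc", "dzz_assoc", "kxxxx_assoc", "kzzzz_assoc")),
    ):
        source = {
            "dxx_proj": maps.dxx, "dyy_proj": maps.dyy,
            "kxxxx_proj": maps.kxxxx, "kyyyy_proj": maps.kyyyy,
            "dxx_assoc": maps.dxx, "dzz_assoc": maps.dzz,
            "kxxxx_assoc": maps.kxxxx, "kzzzz_assoc": maps.kzzzz,
        }
        for mname in metric_names:
            mean, n_valid, n_total = _roi_mean(source[mname], mask,
                                               f"{label}:{mname}")
            vals[mname] = mean
            prev = counts.get(label, (n_total, n_total))
            counts[label] = (min(prev[0], n_valid), n_total)
    flagged = any(nv < MIN_VALID_FRACTION * nt for nv, nt in counts.values())
    return RoiDiffusivities(side=side, voxel_counts=counts, flagged=flagged, **vals)


def alps_ratio(x_proj: float, x_assoc: float, y_proj: float,
               z_assoc: float) -> float:
    """mean(x_proj, x_assoc) / mean(y_proj, z_assoc); the ALPS construction."""
    denom = (y_proj + z_assoc) / 2.0
    if denom <= 0:
        raise ValueError("ALPS index undefined: nonpositive denominator mean")
    return ((x_proj + x_assoc) / 2.0) / denom


def check_axis_aligned(affine: np.ndarray, tol_deg: float = 5.0) -> bool:
    """Warn if voxel axes deviate from world axes by more than ``tol_deg``.

    The ALPS construction reads off x/y/z tensor components directly, so it is
    meaningless when the grid is rotated away from the right-left /
    anterior-posterior / inferior-superior axes.
    """
    R = np.asarray(affine, float)[:3, :3]
    R = R / np.linalg.norm(R, axis=0, keepdims=True)
    cosmax = np.max(np.abs(R), axis=0)
    angles = np.degrees(np.arccos(np.clip(cosmax, -1, 1)))
    if np.any(angles > tol_deg):
        warnings.warn(
            f"voxel axes deviate up to {angles.max():.1f} deg from world axes; "
            "axis-aligned ALPS metrics are unreliable on rotated grids",
            stacklevel=2,
        )
        return False
    return True


def compute_alps(maps: AxisMetricMaps, roiset: AlpsRoiSet,
                 whole_brain: str = "mean") -> AlpsResult:
    """Left, right and whole-brain DTI-/DKI-ALPS from axis-metric maps.

    ``whole_brain='mean'`` averages the two hemispheric indices;
    ``'pooled'`` averages the four ROI means before taking the ratio.
    """
    check_axis_aligned(maps.affine)
    roiset.all_masks(maps.affine, maps.dxx.shape)  # overlap validation
    left = extract_roi_means(maps, roiset, "left")
    right = extract_roi_means(maps, roiset, "right")

    dti = {s.side: alps_ratio(s.dxx_proj, s.dxx_assoc, s.dyy_proj, s.dzz_assoc)
           for s in (left, right)}
    dki = {s.side: alps_ratio(s.kxxxx_proj, s.kxxxx_assoc, s.kyyyy_proj,
                              s.kzzzz_assoc)
           for s in (left, right)}

    if whole_brain == "mean":
        dti_g = (dti["left"] + dti["right"]) / 2.0
        dki_g = (dki["left"] + dki["right"]) / 2.0
    elif whole_brain == "pooled":
        dti_g = alps_ratio((left.dxx_proj + right.dxx_proj) / 2,
                           (left.dxx_assoc + right.dxx_assoc) / 2,
                           (left.dyy_proj + right.dyy_proj) / 2,
                           (left.dzz_assoc + right.dzz_assoc) / 2)
        dki_g = alps_ratio((left.kxxxx_proj + right.kxxxx_proj) / 2,
                           (left.kxxxx_assoc + right.kxxxx_assoc) / 2,
                           (left.kyyyy_proj + right.kyyyy_proj) / 2,
                           (left.kzzzz_assoc + right.kzzzz_assoc) / 2)
    else:
        raise ValueError(f"unknown whole-brain mode {whole_brain!r}")

    prov = {
        "convention": maps.convention,
        "whole_brain": whole_brain,
        "roi_source": roiset.source,
        "voxel_counts": {**left.voxel_counts, **right.voxel_counts},
        "flagged": left.flagged or right.flagged,
    }
    return AlpsResult(dti_left=dti["left"], dti_right=dti["right"],
                      dti_global=dti_g, dki_left=dki["left"],
                      dki_right=dki["right"], dki_global=dki_g,
                      provenance=prov)
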