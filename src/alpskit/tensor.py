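"""Per-voxel diffusion- and kurtosis-tensor estimation from multi-shell dMRI.

The signal model is the standard fourth-order cumulant expansion of the
diffusion-weighted signal,

    ln S(b, n) = ln S0 - b * D_app(n) + (b^2 / 6) * MD^2 * K_app-like term,

written with linear unknowns [ln S0 | 6 diffusion-tensor components | 15
components of U = MD^2 * W], where D_app(n) = sum_ij n_i n_j D_ij and
W_app(n) = sum_ijkl n_i n_j n_k n_l W_ijkl. Fitting is ordinary or weighted
(two-pass, weights = squared predicted signals) least squares on the
log-signal; the kurtosis tensor W is recovered post hoc as U / MD^2.

Two axis-metric conventions are exposed for the diagonal kurtosis maps:
``tensor`` returns the raw W_iiii components (what kurtosis-tensor output
files contain) and ``apparent`` returns the directional excess kurtosis
K_app(e_i) = (MD^2 / D_ii^2) * W_iiii.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import prod

import numpy as np

from .io import DWIVolume, GradientTable

# Unique component orders and symmetry multiplicities. Cross terms of the
# rank-2 tensor appear twice in the double sum; rank-4 classes aaaa/aaab/
# aabb/aabc appear 1/4/6/12 times in the quadruple sum.
D_COMPONENTS = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
D_MULTIPLICITY = np.array([1, 1, 1, 2, 2, 2], dtype=float)
D_NAMES = ["dxx", "dyy", "dzz", "dxy", "dxz", "dyz"]

W_COMPONENTS = [
    (0, 0, 0, 0), (1, 1, 1, 1), (2, 2, 2, 2),
    (0, 0, 0, 1), (0, 0, 0, 2), (0, 1, 1, 1), (1, 1, 1, 2), (0, 2, 2, 2),
    (1, 2, 2, 2),
    (0, 0, 1, 1), (0, 0, 2, 2), (1, 1, 2, 2),
    (0, 0, 1, 2), (0, 1, 1, 2), (0, 1, 2, 2),
]
W_MULTIPLICITY = np.array([1, 1, 1, 4, 4, 4, 4, 4, 4, 6, 6, 6, 12, 12, 12],
                          dtype=float)
W_NAMES = [
    "wxxxx", "wyyyy", "wzzzz", "wxxxy", "wxxxz", "wxyyy", "wyyyz", "wxzzz",
    "wyzzz", "wxxyy", "wxxzz", "wyyzz", "wxxyz", "wxyyz", "wxyzz",
]

N_PARAMS = 22
#: MD^2 below this (mm^4/s^2) leaves the kurtosis tensor undefined.
MD2_FLOOR = 1e-12
#: Physical-plausibility window for directional (apparent) kurtosis.
K_QC_RANGE = (-3.0, 10.0)

# Voxel quality flags (bitmask).
FLAG_OK = 0
FLAG_NONPOS_SIGNAL = 1
FLAG_NONPOS_MD = 2
FLAG_K_OUT_OF_RANGE = 4


def build_design_matrix(gtab: GradientTable) -> np.ndarray:
    """Build the Mx22 log-linear design matrix for a kurtosis-capable scheme.

    Column order: [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, Uxxxx, Uyyyy, Uzzzz,
    Uxxxy, Uxxxz, Uxyyy, Uyyyz, Uxzzz, Uyzzz, Uxxyy, Uxxzz, Uyyzz, Uxxyz,
    Uxyyz, Uxyzz] with U = MD^2 * W.
    """
    if not gtab.dki_capable:
        raise ValueError(
            "model underdetermined: the kurtosis fit needs >= 2 nonzero shells "
            "and >= 22 measurements"
        )
    X = _design_matrix_unchecked(gtab)
    if np.linalg.matrix_rank(X) < N_PARAMS:
        raise ValueError(
            "model underdetermined: design matrix rank below 22 "
            "(directions insufficiently spread)"
        )
    return X


@dataclass
class VoxelTensors:
    """Fitted tensors for a single voxel."""

    s0: float
    D: np.ndarray  # 6 unique components, mm^2/s
    W: np.ndarray  # 15 unique components, dimensionless
    flags: int = FLAG_OK

    @property
    def md(self) -> float:
        """Mean diffusivity, trace(D)/3."""
        return float(np.mean(self.D[:3]))

    @property
    def valid(self) -> bool:
        return self.flags == FLAG_OK


@dataclass
class TensorFields:
    """Voxel-wise tensor fits over a volume (NaN outside the mask/invalid)."""

    s0: np.ndarray          # (X, Y, Z)
    D: np.ndarray           # (X, Y, Z, 6)
    W: np.ndarray           # (X, Y, Z, 15)
    flags: np.ndarray       # (X, Y, Z) int bitmask
    affine: np.ndarray
    mask: np.ndarray
    method: str = "wls"

    @property
    def md(self) -> np.ndarray:
        return np.mean(self.D[..., :3], axis=-1)

    def qc_counts(self) -> dict:
        m = self.mask
        return {
            "n_voxels": int(m.sum()),
            "n_nonpositive_signal": int(((self.flags & FLAG_NONPOS_SIGNAL) > 0)[m].sum()),
            "n_nonpositive_md": int(((self.flags & FLAG_NONPOS_MD) > 0)[m].sum()),
            "n_kurtosis_out_of_range": int(((self.flags & FLAG_K_OUT_OF_RANGE) > 0)[m].sum()),
        }


@dataclass
class AxisMetricMaps:
    """Axis-aligned diffusivity and kurtosis maps, the raw material of ALPS."""

    dxx: np.ndarray
    dyy: np.ndarray
    dzz: np.ndarray
    kxxxx: np.ndarray
    kyyyy: np.ndarray
    kzzzz: np.ndarray
    convention: str
    affine: np.ndarray

    def __post_init__(self):
        if self.convention not in ("tensor", "apparent"):
            raise ValueError(f"unknown kurtosis convention {self.convention!r}")
        shapes = {m.shape for m in (self.dxx, self.dyy, self.dzz,
                                    self.kxxxx, self.kyyyy, self.kzzzz)}
        if len(shapes) != 1:
            raise ValueError("axis metric maps must share one shape")

    def as_dict(self) -> dict:
        return {
            "dxx": self.dxx, "dyy": self.dyy, "dzz": self.dzz,
            "kxxxx": self.kxxxx, "kyyyy": self.kyyyy, "kzzzz": self.kzzzz,
        }


def _qc_flags(D: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Quality flags from fitted parameters; D is (..., 6), W (..., 15)."""
    md = np.mean(D[..., :3], axis=-1)
    flags = np.zeros(md.shape, dtype=np.uint8)
    flags[~(md > 0) | (md * md < MD2_FLOOR)] |= FLAG_NONPOS_MD
    with np.errstate(divide="ignore", invalid="ignore"):
        kax = (md[..., None] ** 2 / D[..., :3] ** 2) * W[..., :3]
    lo, hi = K_QC_RANGE
    bad_k = np.any((kax < lo) | (kax > hi) | ~np.isfinite(kax), axis=-1)
    flags[bad_k & (flags == 0)] |= FLAG_K_OUT_OF_RANGE
    return flags


def _fit_params(signals: np.ndarray, X: np.ndarray, method: str) -> np.ndarray:
    """Solve the log-linear system for (V, M) signals; returns (V, 22) betas.

    Columns of X span ~7 orders of magnitude (1 vs b^2/6), so the matrix is
    equilibrated to unit column norm before solving; the WLS normal equations
    would otherwise square an ~5e6 condition number.
    """
    y = np.log(signals)
    scale = np.linalg.norm(X, axis=0)
    Xn = X / scale
    beta = np.linalg.lstsq(Xn, y.T, rcond=None)[0].T
    if method == "wls":
        # Two-pass WLS: weights are the squared OLS-predicted signals, the
        # first-order variance of log-transformed Gaussian-noise data.
        # Solved by batched QR on the row-weighted system — forming normal
        # equations would square the (weight-inflated) condition number.
        w = np.exp(np.clip(Xn @ beta.T, -300.0, 300.0)).T  # (V, M) sqrt-weights
        A = Xn[None, :, :] * w[:, :, None]                 # (V, M, 22)
        q, r = np.linalg.qr(A)
        rhs = np.einsum("vmi,vm->vi", q, w * y)
        beta = np.linalg.solve(r, rhs[..., None])[..., 0]
    elif method != "ols":
        raise ValueError(f"unknown fit method {method!r}")
    return beta / scale


def _params_to_tensors(beta: np.ndarray):
    """Split (V, 22) betas into s0, D, W; W = U / MD^2."""
    s0 = np.exp(beta[..., 0])
    D = beta[..., 1:7]
    U = beta[..., 7:22]
    md = np.mean(D[..., :3], axis=-1)
    md2 = md * md
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(md2[..., None] >= MD2_FLOOR, U / md2[..., None], np.nan)
    return s0, D, W


def fit_voxel(signal: np.ndarray, gtab: GradientTable, method: str = "wls") -> VoxelTensors:
    """Fit the 22-parameter model to one voxel's signals.

    Voxels containing nonpositive signal are flagged invalid rather than
    clamped (flooring the log biases the kurtosis estimates).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape != (len(gtab),):
        raise ValueError("signal length does not match gradient table")
    if np.any(signal <= 0):
        return VoxelTensors(np.nan, np.full(6, np.nan), np.full(15, np.nan),
                            flags=FLAG_NONPOS_SIGNAL)
    X = build_design_matrix(gtab)
    beta = _fit_params(signal[None, :], X, method)
    s0, D, W = _params_to_tensors(beta)
    flags = int(_qc_flags(D, W)[0])
    return VoxelTensors(float(s0[0]), D[0], W[0], flags=flags)


def fit_volume(dwi: DWIVolume, method: str = "wls") -> TensorFields:
    """Fit every in-mask voxel; results match per-voxel fits exactly."""
    mask = dwi.mask if dwi.mask is not None else np.ones(dwi.data.shape[:3], bool)
    if not mask.any():
        raise ValueError("empty mask: no voxels to fit")
    X = build_design_matrix(dwi.gradients)
    sig = dwi.data[mask]                                   # (V, M)
    ok = np.all(sig > 0, axis=1)

    shape = dwi.data.shape[:3]
    s0 = np.full(shape, np.nan)
    D = np.full(shape + (6,), np.nan)
    W = np.full(shape + (15,), np.nan)
    flags = np.zeros(shape, dtype=np.uint8)
    flags[mask & ~_scatter(mask, ok)] = FLAG_NONPOS_SIGNAL

    if ok.any():
        beta = _fit_params(sig[ok], X, method)
        s0_v, D_v, W_v = _params_to_tensors(beta)
        f_v = _qc_flags(D_v, W_v)
        idx = np.argwhere(mask)[ok]
        s0[tuple(idx.T)] = s0_v
        D[tuple(idx.T)] = D_v
        W[tuple(idx.T)] = W_v
        flags[tuple(idx.T)] = f_v
    return TensorFields(s0=s0, D=D, W=W, flags=flags, affine=dwi.affine,
                        mask=mask, method=method)


def _scatter(mask: np.ndarray, values: np.ndarray) -> np.ndarray:
    out = np.zeros(mask.shape, dtype=values.dtype)
    out[mask] = values
    return out


def axis_metrics(fields: TensorFields, convention: str = "tensor") -> AxisMetricMaps:
    """Extract Dxx/Dyy/Dzz and the three diagonal kurtosis maps.

    Flagged voxels become NaN so downstream ROI means can exclude them.
    """
    bad = fields.flags != FLAG_OK
    D = fields.D.copy()
    W = fields.W.copy()
    D[bad] = np.nan
    W[bad] = np.nan
    md = np.mean(D[..., :3], axis=-1)
    if convention == "tensor":
        k = W[..., :3]
    elif convention == "apparent":
        with np.errstate(divide="ignore", invalid="ignore"):
            k = (md[..., None] ** 2 / D[..., :3] ** 2) * W[..., :3]
    else:
        raise ValueError(f"unknown kurtosis convention {convention!r}")
    return AxisMetricMaps(
        dxx=D[..., 0], dyy=D[..., 1], dzz=D[..., 2],
        kxxxx=k[..., 0], kyyyy=k[..., 1], kzzzz=k[..., 2],
        convention=convention, affine=fields.affine,
    )


def predict_signal(tensors: VoxelTensors, gtab: GradientTable) -> np.ndarray:
    """Forward model: S(b, n) = S0 exp(-b D_app + (b^2/6) MD^2 W_app)."""
    X = _design_matrix_unchecked(gtab)
    md2 = tensors.md ** 2
    beta = np.concatenate(([np.log(tensors.s0)], tensors.D, md2 * tensors.W))
    return np.exp(X @ beta)


def _design_matrix_unchecked(gtab: GradientTable) -> np.ndarray:
    """Design matrix without the rank/capability gate (forward model use)."""
    b = gtab.bvals
    n = gtab.bvecs
    M = len(gtab)
    X = np.empty((M, N_PARAMS))
    X[:, 0] = 1.0
    for c, (i, j) in enumerate(D_COMPONENTS):
        X[:, 1 + c] = -b * D_MULTIPLICITY[c] * n[:, i] * n[:, j]
    for c, idx in enumerate(W_COMPONENTS):
        X[:, 7 + c] = (b ** 2 / 6.0) * W_MULTIPLICITY[c] * prod(
            [n[:, k] for k in idx], start=np.ones(M)
        )
    return X


def tensors_from_arrays(D6: np.ndarray, W15: np.ndarray, s0: float = 1.0) -> VoxelTensors:
    """Convenience constructor from the 6/15 unique-component vectors."""
    return VoxelTensors(float(s0), np.asarray(D6, float), np.asarray(W15, float))


class DiffusionKurtosisModel:
    """Kurtosis-tensor model bound to an acquisition scheme.

    Mirrors the Model/Results idiom: construct from a gradient table, call
    :meth:`fit` on a volume (or raw 4D array) to obtain a
    :class:`DiffusionKurtosisResults`.
    """

    def __init__(self, gtab: GradientTable, method: str = "wls"):
        if method not in ("ols", "wls"):
            raise ValueError(f"unknown fit method {method!r}")
        self.gtab = gtab
        self.method = method
        self.design_matrix = build_design_matrix(gtab)

    def fit(self, data, mask=None, affine=None) -> "DiffusionKurtosisResults":
        if isinstance(data, DWIVolume):
            dwi = data if mask is None else DWIVolume(
                data.data, data.affine, data.gradients, mask)
        else:
            dwi = DWIVolume(
                np.asarray(data, float),
                np.eye(4) if affine is None else affine,
                self.gtab, mask)
        fields = fit_volume(dwi, method=self.method)
        return DiffusionKurtosisResults(self, fields)

    def predict(self, tensors: VoxelTensors) -> np.ndarray:
        return predict_signal(tensors, self.gtab)


class DiffusionKurtosisResults:
    """Fitted tensor fields with QC, axis metrics and a summary table."""

    def __init__(self, model: DiffusionKurtosisModel, fields: TensorFields):
        self.model = model
        self.fields = fields

    @property
    def md(self) -> np.ndarray:
        return self.fields.md

    def axis_metrics(self, convention: str = "tensor") -> AxisMetricMaps:
        return axis_metrics(self.fields, convention=convention)

    def qc_counts(self) -> dict:
        return self.fields.qc_counts()

    def summary(self) -> str:
        qc = self.qc_counts()
        m = self.fields.mask & (self.fields.flags == FLAG_OK)
        md = self.fields.md[m]
        lines = [
            "Diffusion kurtosis fit",
            "=" * 40,
            f"method:            {self.fields.method}",
            f"voxels fitted:     {qc['n_voxels']}",
            f"flagged (signal):  {qc['n_nonpositive_signal']}",
            f"flagged (MD<=0):   {qc['n_nonpositive_md']}",
            f"flagged (K range): {qc['n_kurtosis_out_of_range']}",
        ]
        if md.size:
            lines.append(f"MD median (mm^2/s): {np.median(md):.6g}")
        return "\n".join(lines)
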