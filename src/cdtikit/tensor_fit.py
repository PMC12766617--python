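"""Linear least-squares diffusion tensor estimation and tensor normalization.

The log-linearized signal model ln S = ln S0 - b g^T D g is fit per voxel by
ordinary (unweighted) least squares on the averaged images.  Negative
eigenvalues are permitted: no positivity projection is applied at any stage.
Two normalization schemes condition tensors for the de-noising network:
a global scale factor (default 1500 s/mm^2, mapping typical diffusivities
~1e-3 mm^2/s into roughly [-1, 1]) and channel-wise z-scoring with
statistics fitted on a training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dwi_sim import AcquisitionProtocol, ImageMeta
from .phantom import TensorField

__all__ = [
    "DesignMatrix",
    "NormalizationSpec",
    "LLSFit",
    "build_design_matrix",
    "fit_lls",
    "normalize_tensor",
    "denormalize_tensor",
    "fit_zscore_spec",
]


@dataclass
class DesignMatrix:
    """Rows: one per averaged image; columns: [ln S0 | 6 tensor elements].

    Column layout: [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz,
    -2b gy gz] so that the solution vector is (ln S0, Dxx, Dyy, Dzz, Dxy,
    Dxz, Dyz) in the package's fixed channel order.
    """

    matrix: np.ndarray
    keys: list[tuple[float, int]] = field(default_factory=list)

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))


@dataclass
class NormalizationSpec:
    """Tensor conditioning: global ``scale`` or channel-wise ``zscore``."""

    mode: str = "scale"
    scale_factor: float = 1500.0
    channel_mean: np.ndarray | None = None
    channel_std: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("scale", "zscore"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")
        if self.mode == "scale" and self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")


@dataclass
class LLSFit:
    """Result of a linear least-squares tensor fit."""

    tensor_field: TensorField
    s0_map: np.ndarray
    excluded_mask: np.ndarray      # masked voxels dropped (nonpositive signal)
    n_excluded: int
    condition_number: float


def build_design_matrix(
    protocol_or_meta: AcquisitionProtocol | list[ImageMeta],
) -> DesignMatrix:
    """Assemble the log-linear design matrix for a protocol or averaged stack.

    One row per distinct (b, direction) key for a protocol, or per meta entry
    for an averaged stack.  Raises if the resulting system is rank-deficient
    (fewer than 7 independent rows).
    """
    if isinstance(protocol_or_meta, AcquisitionProtocol):
        proto = protocol_or_meta
        metas = [ImageMeta(b, d, 0) for (b, d) in proto.unique_keys]
        dirset = proto.direction_set
    else:
        from .dwi_sim import DIRECTIONS_6
        metas = list(protocol_or_meta)
        dirset = DIRECTIONS_6
    rows = []
    keys = []
    for m in metas:
        if m.b_value == 0:
            rows.append([1.0, 0, 0, 0, 0, 0, 0])
        else:
            gx, gy, gz = dirset[m.direction_index]
            b = m.b_value
            rows.append([1.0, -b * gx * gx, -b * gy * gy, -b * gz * gz,
                         -2 * b * gx * gy, -2 * b * gx * gz, -2 * b * gy * gz])
        keys.append(m.key)
    matrix = np.asarray(rows, dtype=float)
    if np.linalg.matrix_rank(matrix) < 7:
        raise ValueError(
            f"protocol is rank-deficient for tensor fitting "
            f"(rank {np.linalg.matrix_rank(matrix)} < 7)"
        )
    return DesignMatrix(matrix=matrix, keys=keys)


def fit_lls(
    averaged_stack: np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray,
) -> LLSFit:
    """Per-voxel ordinary least squares on the log signal.

    Masked voxels with any nonpositive signal are flagged and excluded
    (zero-filled in the output, counted in the report); voxels outside the
    mask are zero-filled.  Raises if every masked voxel is excluded.
    """
    a = design.matrix
    n_img = a.shape[0]
    if averaged_stack.shape[0] != n_img:
        raise ValueError(
            f"stack has {averaged_stack.shape[0]} images, design expects {n_img}"
        )
    mask = np.asarray(mask, dtype=bool)
    sig = averaged_stack[:, mask]                       # (n_img, n_vox)
    good = np.all(sig > 0, axis=0)
    if not good.any():
        raise ValueError("all masked voxels have nonpositive signal")
    coef = np.zeros((7, sig.shape[1]))
    coef[:, good] = np.linalg.lstsq(a, np.log(sig[:, good]), rcond=None)[0]

    shape = mask.shape
    d = np.zeros(shape + (6,))
    d[mask] = coef[1:].T
    fitted = mask.copy()
    fitted[mask] = good
    d[~fitted] = 0.0
    s0 = np.zeros(shape)
    s0[fitted] = np.exp(coef[0, good])
    excluded = mask & ~fitted
    return LLSFit(
        tensor_field=TensorField(d=d, mask=fitted),
        s0_map=s0,
        excluded_mask=excluded,
        n_excluded=int(excluded.sum()),
        condition_number=design.condition_number,
    )


def fit_zscore_spec(tensor_fields: list[TensorField]) -> NormalizationSpec:
    """Channel statistics over the masked voxels of a training set."""
    vox = np.concatenate([tf.d[tf.mask] for tf in tensor_fields], axis=0)
    std = vox.std(axis=0)
    if np.any(std <= 0):
        raise ValueError("degenerate channel standard deviation")
    return NormalizationSpec(
        mode="zscore", channel_mean=vox.mean(axis=0), channel_std=std
    )


def normalize_tensor(tensor_field: TensorField, spec: NormalizationSpec) -> np.ndarray:
    """6-channel normalized grid (same spatial shape, channels last)."""
    d = tensor_field.d
    if spec.mode == "scale":
        return d * spec.scale_factor
    if spec.channel_mean is None or spec.channel_std is None:
        raise ValueError("zscore normalization requires fitted channel statistics")
    out = (d - spec.channel_mean) / spec.channel_std
    out[~tensor_field.mask] = 0.0
    return out


def denormalize_tensor(normalized: np.ndarray, spec: NormalizationSpec,
                       mask: np.ndarray) -> TensorField:
    """Inverse of :func:`normalize_tensor` (exact round-trip on the mask)."""
    if spec.mode == "scale":
        d = normalized / spec.scale_factor
    else:
        if spec.channel_mean is None or spec.channel_std is None:
            raise ValueError("zscore normalization requires fitted channel statistics")
        d = normalized * spec.channel_std + spec.channel_mean
    d = d.copy()
    d[~np.asarray(mask, dtype=bool)] = 0.0
    return TensorField(d=d, mask=np.asarray(mask, dtype=bool))
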