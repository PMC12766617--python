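"""Eigen-analysis and the four cDTI maps: MD, FA, HA, E2A.

Conventions (self-consistent with the phantom construction, which is the
testable contract):

* HA — the primary eigenvector is sign-flipped so its circumferential
  component is non-negative, then HA = atan2(e1.l, e1.c) in degrees,
  range (-90, 90].
* E2A — the cross-myocyte axis is the radial direction made orthogonal to
  e1, m = normalize(r - (r.e1) e1); the in-wall axis is k = e1 x m;
  E2A = |atan2(e2.m, e2.k)| folded into [0, 90] (absolute-angle convention).

Indefinite tensors (negative eigenvalues) are processed without projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import TensorField

__all__ = [
    "EigenField",
    "CDTIMaps",
    "eigendecompose",
    "compute_md_fa",
    "compute_ha",
    "compute_e2a",
    "compute_cdti_maps",
]


@dataclass
class EigenField:
    """Sorted eigen-decomposition per masked voxel.

    ``eigenvalues`` (rows, cols, 3) descending; ``eigenvectors``
    (rows, cols, 3, 3) with ``eigenvectors[..., i, :]`` the unit vector for
    eigenvalue i.  Zero off-mask.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    mask: np.ndarray


@dataclass
class CDTIMaps:
    """MD (mm^2/s), FA, HA (degrees, (-90, 90]), E2A (degrees, [0, 90]).

    Defined exactly on ``mask`` (NaN elsewhere).  ``flagged`` marks voxels
    where an angle was undefined (radial e1 or degenerate e2) and, for FA,
    all-zero eigenvalues.
    """

    md: np.ndarray
    fa: np.ndarray
    ha: np.ndarray
    e2a: np.ndarray
    mask: np.ndarray
    flagged: np.ndarray


def _fix_sign(vecs: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Deterministic eigenvector sign: first nonzero component positive."""
    v = vecs.reshape(-1, 3)
    sign = np.ones(v.shape[0])
    decided = np.zeros(v.shape[0], dtype=bool)
    for comp in range(3):
        pick = ~decided & (np.abs(v[:, comp]) > tol)
        sign[pick] = np.sign(v[pick, comp])
        decided |= pick
    return (v * sign[:, None]).reshape(vecs.shape)


def eigendecompose(tensor_field: TensorField) -> EigenField:
    """Batched symmetric eigen-decomposition, eigenvalues descending."""
    if not np.all(np.isfinite(tensor_field.d)):
        raise ValueError("tensor field contains non-finite elements")
    mask = tensor_field.mask
    mats = tensor_field.as_matrices()[mask]
    w, v = np.linalg.eigh(mats)                # ascending; v[:, :, i] = vector i
    w = w[:, ::-1]
    v = np.ascontiguousarray(v[:, :, ::-1]).transpose(0, 2, 1)  # (n, i, xyz)
    v = _fix_sign(v)
    shape = mask.shape
    eigenvalues = np.zeros(shape + (3,))
    eigenvectors = np.zeros(shape + (3, 3))
    eigenvalues[mask] = w
    eigenvectors[mask] = v
    return EigenField(eigenvalues=eigenvalues, eigenvectors=eigenvectors,
                      mask=mask.copy())


def compute_md_fa(eigen_field: EigenField) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MD = mean eigenvalue; FA from the standard closed form.

    Returns ``(md, fa, flagged)``; FA at all-zero eigenvalues is defined as 0
    and flagged.  NaN off-mask.
    """
    mask = eigen_field.mask
    lam = eigen_field.eigenvalues[mask]
    md_v = lam.mean(axis=1)
    num = np.sum((lam - md_v[:, None]) ** 2, axis=1)
    den = np.sum(lam ** 2, axis=1)
    zero = den == 0
    fa_v = np.zeros(lam.shape[0])
    fa_v[~zero] = np.sqrt(1.5 * num[~zero] / den[~zero])
    shape = mask.shape
    md = np.full(shape, np.nan)
    fa = np.full(shape, np.nan)
    flagged = np.zeros(shape, dtype=bool)
    md[mask] = md_v
    fa[mask] = fa_v
    flagged[mask] = zero
    return md, fa, flagged


def _frame_axes(frame: np.ndarray, mask: np.ndarray):
    r = frame[mask][:, 0, :]
    c = frame[mask][:, 1, :]
    l = frame[mask][:, 2, :]
    return r, c, l


def compute_ha(eigen_field: EigenField, frame: np.ndarray,
               tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Helix angle map in degrees, range (-90, 90].

    e1 is flipped so e1.c >= 0 (HA is antipodally invariant); voxels where e1
    has no tangential projection (exactly radial) are flagged NaN.
    Returns ``(ha, flagged)``.
    """
    mask = eigen_field.mask
    _, c, l = _frame_axes(frame, mask)
    e1 = eigen_field.eigenvectors[mask][:, 0, :]
    ec = np.einsum("ij,ij->i", e1, c)
    el = np.einsum("ij,ij->i", e1, l)
    flip = ec < 0
    ec = np.where(flip, -ec, ec)
    el = np.where(flip, -el, el)
    tang = np.hypot(ec, el)
    bad = tang < tol
    ha_v = np.degrees(np.arctan2(el, ec))
    # atan2 with ec >= 0 yields [-90, 90]; map -90 (ec=0, el<0 pre-flip
    # impossible after flip) — keep the half-open convention at +90
    ha_v[bad] = np.nan
    shape = mask.shape
    ha = np.full(shape, np.nan)
    flagged = np.zeros(shape, dtype=bool)
    ha[mask] = ha_v
    flagged[mask] = bad
    return ha, flagged


def compute_e2a(eigen_field: EigenField, frame: np.ndarray,
                tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Absolute sheetlet angle (E2A) in degrees, folded into [0, 90].

    Cross-myocyte axis m = normalize(r - (r.e1) e1), in-wall axis k = e1 x m,
    E2A = |atan2(e2.m, e2.k)| folded.  Voxels with e1 parallel to the radial
    direction, or with degenerate lambda2 = lambda3, are flagged NaN.
    Returns ``(e2a, flagged)``.
    """
    mask = eigen_field.mask
    r, _, _ = _frame_axes(frame, mask)
    vecs = eigen_field.eigenvectors[mask]
    lam = eigen_field.eigenvalues[mask]
    e1, e2 = vecs[:, 0, :], vecs[:, 1, :]
    m = r - np.einsum("ij,ij->i", r, e1)[:, None] * e1
    mnorm = np.linalg.norm(m, axis=1)
    bad = mnorm < tol
    bad |= np.isclose(lam[:, 1], lam[:, 2], rtol=0, atol=tol * np.abs(lam).max(initial=1.0))
    m = m / np.where(mnorm[:, None] > 0, mnorm[:, None], 1.0)
    k = np.cross(e1, m)
    em = np.einsum("ij,ij->i", e2, m)
    ek = np.einsum("ij,ij->i", e2, k)
    ang = np.abs(np.degrees(np.arctan2(em, ek)))
    ang = np.where(ang > 90.0, 180.0 - ang, ang)
    ang[bad] = np.nan
    shape = mask.shape
    e2a = np.full(shape, np.nan)
    flagged = np.zeros(shape, dtype=bool)
    e2a[mask] = ang
    flagged[mask] = bad
    return e2a, flagged


def compute_cdti_maps(tensor_field: TensorField, frame: np.ndarray) -> CDTIMaps:
    """All four maps from a tensor field and a local-frame grid."""
    ef = eigendecompose(tensor_field)
    md, fa, f1 = compute_md_fa(ef)
    ha, f2 = compute_ha(ef, frame)
    e2a, f3 = compute_e2a(ef, frame)
    return CDTIMaps(md=md, fa=fa, ha=ha, e2a=e2a, mask=ef.mask,
                    flagged=f1 | f2 | f3)
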