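"""Analytic short-axis left-ventricle phantoms with known ground-truth tensors.

The phantom is a 2-D annulus (one short-axis slice): blood pool inside the
endocardial radius, myocardium between the endocardial and epicardial radii.
Every myocardial voxel carries a local cardiac frame (radial, circumferential,
longitudinal), a prescribed helix angle that varies linearly across the wall,
a constant sheetlet (E2A) angle, and a diffusion tensor constructed so that
eigen-analysis recovers the prescribed MD/FA/HA/E2A exactly.

Coordinate convention: row-major image grid, voxel centers at integer
coordinates, 0-based.  In 3-D, x = +column, y = +row, z = slice normal (out of
plane).  The local frame at a voxel is r (in-plane unit vector from the LV
center to the voxel), l = z, and c = z x r (circumferential).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "LVGeometry",
    "OrientationField",
    "TensorField",
    "LesionSpec",
    "make_lv_geometry",
    "prescribe_orientation",
    "build_tensor_field",
    "add_infarct",
    "solve_eigenvalues",
    "TENSOR_CHANNELS",
]

#: Channel order of the 6 unique tensor elements, fixed across the package.
TENSOR_CHANNELS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class LVGeometry:
    """Annular left-ventricle geometry on a 2-D voxel grid.

    ``depth`` is the normalized transmural position: 0 at the endocardium,
    1 at the epicardium, defined exactly on ``myo_mask``; NaN elsewhere.
    """

    grid_shape: tuple[int, int]
    center: tuple[float, float]          # (row, col), continuous
    r_endo: float
    r_epi: float
    myo_mask: np.ndarray                 # bool (rows, cols)
    blood_mask: np.ndarray               # bool (rows, cols)
    depth: np.ndarray                    # float (rows, cols), NaN off-myocardium
    rho: np.ndarray = field(repr=False, default=None)  # distance from center

    def frame(self) -> np.ndarray:
        """Per-voxel orthonormal triad, shape (rows, cols, 3, 3).

        ``frame[..., 0, :]`` = radial, ``[..., 1, :]`` = circumferential,
        ``[..., 2, :]`` = longitudinal, each a unit 3-vector in (x, y, z).
        Defined on every voxel except the exact center (where it is NaN).
        """
        rows, cols = self.grid_shape
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        dx = cc - self.center[1]         # x = +column
        dy = rr - self.center[0]         # y = +row
        rho = np.hypot(dx, dy)
        with np.errstate(invalid="ignore", divide="ignore"):
            rx = np.where(rho > 0, dx / rho, np.nan)
            ry = np.where(rho > 0, dy / rho, np.nan)
        frame = np.zeros((rows, cols, 3, 3))
        frame[..., 0, 0] = rx
        frame[..., 0, 1] = ry
        # circumferential = z x r = (-ry, rx, 0)
        frame[..., 1, 0] = -ry
        frame[..., 1, 1] = rx
        frame[..., 2, 2] = 1.0
        return frame


@dataclass
class OrientationField:
    """Prescribed myocyte/sheetlet orientations on the myocardium.

    ``ha_true``/``e2a_true`` are in degrees, NaN off-myocardium.  ``frame``
    is the per-voxel (radial, circumferential, longitudinal) triad.
    """

    ha_true: np.ndarray
    e2a_true: np.ndarray
    frame: np.ndarray
    geometry: LVGeometry


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor stored as its 6 unique elements.

    ``d`` has shape (rows, cols, 6), channel order ``TENSOR_CHANNELS``
    (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz), units mm^2/s.  Positive semi-definiteness
    is not enforced anywhere in the pipeline.
    """

    d: np.ndarray
    mask: np.ndarray

    def as_matrices(self) -> np.ndarray:
        """Full symmetric 3x3 matrices, shape (rows, cols, 3, 3)."""
        dxx, dyy, dzz, dxy, dxz, dyz = np.moveaxis(self.d, -1, 0)
        m = np.empty(self.d.shape[:-1] + (3, 3))
        m[..., 0, 0] = dxx
        m[..., 1, 1] = dyy
        m[..., 2, 2] = dzz
        m[..., 0, 1] = m[..., 1, 0] = dxy
        m[..., 0, 2] = m[..., 2, 0] = dxz
        m[..., 1, 2] = m[..., 2, 1] = dyz
        return m

    @staticmethod
    def from_matrices(m: np.ndarray, mask: np.ndarray) -> "TensorField":
        d = np.stack(
            [m[..., 0, 0], m[..., 1, 1], m[..., 2, 2],
             m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]],
            axis=-1,
        )
        return TensorField(d=d, mask=mask)


@dataclass
class LesionSpec:
    """An angular sector of the annulus with altered MD/FA (infarct analogue).

    ``angular_range`` is (start, stop) in degrees, measured from the +x axis
    counter-clockwise, each within [0, 360).  A wrap-around sector
    (start > stop) is allowed.
    """

    angular_range: tuple[float, float]
    md_lesion: float
    fa_lesion: float

    def __post_init__(self) -> None:
        lo, hi = self.angular_range
        if not (0 <= lo < 360 and 0 <= hi < 360):
            raise ValueError("angular_range bounds must lie in [0, 360)")
        if lo == hi:
            raise ValueError("lesion sector has zero angular width")
        if self.md_lesion <= 0:
            raise ValueError("md_lesion must be positive")
        if not (0 <= self.fa_lesion < 1):
            raise ValueError("fa_lesion must be in [0, 1)")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def make_lv_geometry(
    grid_shape: tuple[int, int],
    center: tuple[float, float],
    r_endo: float,
    r_epi: float,
) -> LVGeometry:
    """Build the annular LV geometry.

    Myocardium: voxels whose center lies at distance rho in
    [r_endo, r_epi] from the LV center; blood pool: rho < r_endo;
    transmural depth = (rho - r_endo) / (r_epi - r_endo) on the myocardium.

    Raises ``ValueError`` if the radii are out of order or the annulus does
    not fit inside the grid.
    """
    if not (r_epi > r_endo > 0):
        raise ValueError(
            f"need r_epi > r_endo > 0, got r_endo={r_endo}, r_epi={r_epi}"
        )
    rows, cols = grid_shape
    cr, cc = center
    if (cr - r_epi < -0.5 or cr + r_epi > rows - 0.5
            or cc - r_epi < -0.5 or cc + r_epi > cols - 0.5):
        raise ValueError(
            f"annulus of radius {r_epi} at center {center} exceeds "
            f"grid {grid_shape}"
        )
    rr, ccg = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    rho = np.hypot(rr - cr, ccg - cc)
    myo = (rho >= r_endo) & (rho <= r_epi)
    blood = rho < r_endo
    depth = np.full(grid_shape, np.nan)
    depth[myo] = (rho[myo] - r_endo) / (r_epi - r_endo)
    return LVGeometry(
        grid_shape=tuple(grid_shape), center=(float(cr), float(cc)),
        r_endo=float(r_endo), r_epi=float(r_epi),
        myo_mask=myo, blood_mask=blood, depth=depth, rho=rho,
    )


# ---------------------------------------------------------------------------
# Orientation prescription
# ---------------------------------------------------------------------------

def prescribe_orientation(
    geometry: LVGeometry,
    ha_endo_deg: float = 60.0,
    ha_epi_deg: float = -60.0,
    e2a_deg: float = 20.0,
    sit_flag: bool = False,
) -> OrientationField:
    """Prescribe helix and sheetlet angles across the wall.

    The helix angle varies linearly with transmural depth between the endo-
    and epicardial values; E2A is constant.  ``sit_flag`` mirrors the helical
    chirality (situs inversus): HA is negated everywhere, E2A unchanged.
    """
    for name, val in (("ha_endo_deg", ha_endo_deg), ("ha_epi_deg", ha_epi_deg),
                      ("e2a_deg", e2a_deg)):
        if not -90 <= val <= 90:
            raise ValueError(f"{name}={val} outside [-90, 90]")
    if not geometry.myo_mask.any():
        raise ValueError("geometry has no myocardial voxels")
    ha = ha_endo_deg + geometry.depth * (ha_epi_deg - ha_endo_deg)
    if sit_flag:
        ha = -ha
    e2a = np.where(geometry.myo_mask, float(abs(e2a_deg)), np.nan)
    return OrientationField(
        ha_true=ha, e2a_true=e2a, frame=geometry.frame(), geometry=geometry
    )


# ---------------------------------------------------------------------------
# Eigenvalue solve and tensor construction
# ---------------------------------------------------------------------------

def _fa_of_eigs(l1: float, l2: float, l3: float) -> float:
    lam = np.array([l1, l2, l3])
    md = lam.mean()
    return float(np.sqrt(1.5 * np.sum((lam - md) ** 2) / np.sum(lam ** 2)))


def solve_eigenvalues(
    md: float, fa: float, shape_ratio: float = 1.5
) -> tuple[float, float, float]:
    """Eigenvalues (l1 >= l2 >= l3 > 0) matching a prescribed MD and FA.

    The secondary anisotropy is pinned by ``shape_ratio`` = l2/l3 > 1 so that
    the second eigenvector is non-degenerate and E2A well defined.  FA = 0 is
    the isotropic special case (all eigenvalues equal to MD; the shape ratio
    is moot).  The remaining 1-D problem — l3 given the trace constraint —
    is monotone and solved by bisection (Brent).

    Raises ``ValueError`` when no positive, ordered eigenvalue triple exists
    for the requested combination.
    """
    if md <= 0:
        raise ValueError("MD must be positive")
    if not (0 <= fa < 1):
        raise ValueError("FA must be in [0, 1)")
    if fa == 0:
        return (md, md, md)
    if shape_ratio <= 1:
        raise ValueError("shape_ratio must exceed 1")
    s = shape_ratio
    trace = 3.0 * md
    # l2 = s*l3, l1 = trace - (1+s)*l3; ordering l1 >= l2 requires
    # l3 <= trace/(1+2s).  FA is strictly decreasing in l3 on that interval.
    hi = trace / (1.0 + 2.0 * s)
    fa_min = _fa_of_eigs(trace - (1 + s) * hi, s * hi, hi)

    def gap(l3: float) -> float:
        return _fa_of_eigs(trace - (1 + s) * l3, s * l3, l3) - fa

    if fa <= fa_min:
        raise ValueError(
            f"FA={fa} infeasible with shape_ratio={s} "
            f"(minimum attainable FA is {fa_min:.4f})"
        )
    lo = hi * 1e-9
    l3 = brentq(gap, lo, hi, xtol=1e-18, rtol=1e-15)
    l1 = trace - (1 + s) * l3
    l2 = s * l3
    if not (l1 >= l2 >= l3 > 0):
        raise ValueError(f"no ordered positive solution for MD={md}, FA={fa}")
    return (float(l1), float(l2), float(l3))


def _eigvecs_from_angles(
    frame: np.ndarray, ha_deg: np.ndarray, e2a_deg: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigenvector triads realizing the prescribed HA/E2A in a local frame."""
    r = frame[..., 0, :]
    c = frame[..., 1, :]
    l = frame[..., 2, :]
    ha = np.deg2rad(ha_deg)[..., None]
    e2a = np.deg2rad(e2a_deg)[..., None]
    # e1 lies in the tangential (c, l) plane at the helix angle.
    e1 = np.cos(ha) * c + np.sin(ha) * l
    # The cross-myocyte axis reduces to r (e1 is tangential); in-wall axis
    # completes the right-handed triad.
    m = r
    k = np.cross(e1, m)
    e2 = np.cos(e2a) * k + np.sin(e2a) * m
    e3 = np.cross(e1, e2)
    return e1, e2, e3


def build_tensor_field(
    orientation: OrientationField,
    md_map: np.ndarray | float,
    fa_map: np.ndarray | float,
    shape_ratio: float = 1.5,
) -> TensorField:
    """Construct D = sum_i lambda_i v_i v_i^T realizing prescribed maps.

    ``md_map``/``fa_map`` may be scalars or full grids (values read on the
    myocardial mask).  Eigenvalues come from :func:`solve_eigenvalues`
    (solved once per distinct (MD, FA) pair — the solve is scale-invariant
    in MD, so it is cached per distinct FA and rescaled); eigenvectors from
    the local frame and the prescribed angles.  Off-mask voxels are zero.
    """
    geom = orientation.geometry
    mask = geom.myo_mask
    shape = geom.grid_shape
    md = np.broadcast_to(np.asarray(md_map, dtype=float), shape)
    fa = np.broadcast_to(np.asarray(fa_map, dtype=float), shape)
    if np.any(md[mask] <= 0):
        raise ValueError("md_map must be positive on the myocardium")
    if np.any((fa[mask] < 0) | (fa[mask] >= 1)):
        raise ValueError("fa_map must be in [0, 1) on the myocardium")

    # unit-MD eigenvalues per distinct FA value, then scaled by MD
    fa_vals = fa[mask]
    md_vals = md[mask]
    lam = np.empty((fa_vals.size, 3))
    for fa_u in np.unique(fa_vals):
        triple = np.array(solve_eigenvalues(1.0, float(fa_u), shape_ratio))
        lam[fa_vals == fa_u] = triple
    lam *= md_vals[:, None]

    e1, e2, e3 = _eigvecs_from_angles(
        orientation.frame[mask], orientation.ha_true[mask],
        orientation.e2a_true[mask],
    )
    dmat = (
        lam[:, 0, None, None] * e1[:, :, None] * e1[:, None, :]
        + lam[:, 1, None, None] * e2[:, :, None] * e2[:, None, :]
        + lam[:, 2, None, None] * e3[:, :, None] * e3[:, None, :]
    )
    full = np.zeros(shape + (3, 3))
    full[mask] = dmat
    return TensorField.from_matrices(full, mask.copy())


# ---------------------------------------------------------------------------
# Infarct variant
# ---------------------------------------------------------------------------

def sector_mask(geometry: LVGeometry, angular_range: tuple[float, float]) -> np.ndarray:
    """Boolean mask of myocardial voxels inside an angular sector.

    Angles are measured from the +x (column) axis, counter-clockwise in the
    (x, y) frame, in degrees within [0, 360).
    """
    rows, cols = geometry.grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    theta = np.rad2deg(
        np.arctan2(rr - geometry.center[0], cc - geometry.center[1])
    ) % 360.0
    lo, hi = angular_range
    if lo < hi:
        in_sector = (theta >= lo) & (theta < hi)
    else:  # wrap-around
        in_sector = (theta >= lo) | (theta < hi)
    return geometry.myo_mask & in_sector


def add_infarct(
    tensor_field: TensorField,
    orientation: OrientationField,
    lesion: LesionSpec,
    shape_ratio: float = 1.5,
) -> tuple[TensorField, np.ndarray, np.ndarray]:
    """Rebuild a sector of the annulus with lesion MD/FA.

    Returns ``(field, lesion_mask, remote_mask)``.  Voxels outside the sector
    are bit-identical to the input; the remote mask is the myocardium minus
    the lesion sector.  Orientation (HA/E2A) is unchanged inside the lesion:
    only the eigenvalue magnitudes differ.
    """
    geom = orientation.geometry
    lesion_mask = sector_mask(geom, lesion.angular_range)
    if not lesion_mask.any():
        raise ValueError("lesion sector does not intersect the myocardium")
    remote_mask = geom.myo_mask & ~lesion_mask

    lesion_field = build_tensor_field(
        orientation, lesion.md_lesion, lesion.fa_lesion, shape_ratio
    )
    d = tensor_field.d.copy()
    d[lesion_mask] = lesion_field.d[lesion_mask]
    return TensorField(d=d, mask=tensor_field.mask.copy()), lesion_mask, remote_mask
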