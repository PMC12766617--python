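"""Map-quality metrics and clinical-validation analyses.

Per-subject errors are voxel means over the LV myocardium: MAAE for the
helix angle (absolute angular difference with 180-degree wraparound), MAE
for E2A (on absolute angles), MD and FA.  Cohort results are summarized as
median [interquartile range] across subjects — never by pooling voxels.
Also provided: transmural HA profiles along center-to-epicardium rays,
three-zone FA statistics, the infarct-remote MD contrast, and a patch-level
error comparison between two models.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .maps import CDTIMaps
from .phantom import LVGeometry

__all__ = [
    "ErrorEntry",
    "CohortSummary",
    "TransmuralProfile",
    "maae",
    "map_errors",
    "cohort_summary",
    "transmural_profiles",
    "fa_zones",
    "delta_md",
    "patchwise_comparison",
]


@dataclass
class ErrorEntry:
    """Voxel-mean map errors for one subject.

    Units follow the reporting convention: HA/E2A in degrees, MD in
    1e-3 mm^2/s, FA dimensionless.
    """

    ha_maae: float
    e2a_mae: float
    md_mae: float
    fa_mae: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class CohortSummary:
    """median and IQR (Q3 - Q1, linear-interpolation quantiles) per metric."""

    median: dict[str, float]
    iqr: dict[str, float]
    n_subjects: int


@dataclass
class TransmuralProfile:
    """Median HA versus normalized wall position (0 = endo, 1 = epi).

    ``band_sd``/``band_iqr`` are per-position dispersion measures across
    rays (standard deviation and interquartile range respectively).
    """

    positions: np.ndarray
    median_ha: np.ndarray
    band_sd: np.ndarray
    band_iqr: np.ndarray
    n_rays: int


def maae(x_deg, y_deg):
    """Absolute angular error with 180-degree wraparound, elementwise.

    For helix angles in [-90, 90]: |x - y| when below 90 degrees, otherwise
    180 - |x - y| (angles 180 degrees apart describe the same axis; 90
    degrees is the maximum possible directional difference).
    """
    x = np.asarray(x_deg, dtype=float)
    y = np.asarray(y_deg, dtype=float)
    finite_x, finite_y = x[np.isfinite(x)], y[np.isfinite(y)]
    if np.any(np.abs(finite_x) > 90) or np.any(np.abs(finite_y) > 90):
        raise ValueError("inputs must lie within [-90, 90] degrees")
    d = np.abs(x - y)
    return np.where(d < 90.0, d, 180.0 - d)


def map_errors(pred: CDTIMaps, ref: CDTIMaps, mask: np.ndarray) -> ErrorEntry:
    """Voxel-mean errors over a shared myocardial mask.

    HA via MAAE; E2A via MAE after absolute-value folding; MD and FA via
    plain MAE.  Voxels where either map is undefined (NaN) are skipped.
    MD error is reported in 1e-3 mm^2/s.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty evaluation mask")

    def masked_mean(err: np.ndarray) -> float:
        vals = err[mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("no finite values inside the mask")
        return float(vals.mean())

    ha_err = np.full(mask.shape, np.nan)
    ok = mask & np.isfinite(pred.ha) & np.isfinite(ref.ha)
    ha_err[ok] = maae(pred.ha[ok], ref.ha[ok])
    return ErrorEntry(
        ha_maae=masked_mean(ha_err),
        e2a_mae=masked_mean(np.abs(np.abs(pred.e2a) - np.abs(ref.e2a))),
        md_mae=masked_mean(np.abs(pred.md - ref.md)) * 1e3,
        fa_mae=masked_mean(np.abs(pred.fa - ref.fa)),
    )


def cohort_summary(entries: list[ErrorEntry]) -> CohortSummary:
    """Median [IQR] across subjects for each metric."""
    if not entries:
        raise ValueError("no subjects to summarize")
    med, iqr = {}, {}
    for metric in ("ha_maae", "e2a_mae", "md_mae", "fa_mae"):
        vals = np.array([getattr(e, metric) for e in entries])
        med[metric] = float(np.median(vals))
        q1, q3 = np.percentile(vals, [25, 75])
        iqr[metric] = float(q3 - q1)
    return CohortSummary(median=med, iqr=iqr, n_subjects=len(entries))


def _epicardial_border(geometry: LVGeometry) -> np.ndarray:
    """Myocardial voxels adjacent (4-connectivity) to the outside background."""
    outside = ~geometry.myo_mask & ~geometry.blood_mask
    touch = ndimage.binary_dilation(
        outside, structure=ndimage.generate_binary_structure(2, 1)
    )
    return geometry.myo_mask & touch


def transmural_profiles(
    ha_map: np.ndarray,
    geometry: LVGeometry,
    n_positions: int = 20,
    step: float = 0.25,
) -> TransmuralProfile:
    """Median transmural HA profile from center-to-epicardium rays.

    One ray is cast from the LV center to each epicardial border pixel,
    sampled bilinearly every ``step`` voxels.  Samples outside the
    myocardium (blood pool, background) are discarded; the surviving
    segment is length-normalized to [0, 1], linearly resampled at
    ``n_positions`` evenly spaced positions, and the median across rays is
    reported together with dispersion bands.
    """
    border = _epicardial_border(geometry)
    targets = np.argwhere(border)
    if targets.size == 0:
        raise ValueError("geometry has no epicardial border pixels")
    cr, cc = geometry.center
    positions = np.linspace(0.0, 1.0, n_positions)
    # fill non-myocardial voxels with the nearest myocardial value so that
    # bilinear samples near the wall boundaries do not bleed in zeros
    filled = np.array(ha_map, dtype=float)
    missing = ~geometry.myo_mask | ~np.isfinite(filled)
    if missing.any():
        _, (ir, ic) = ndimage.distance_transform_edt(missing,
                                                     return_indices=True)
        filled = filled[ir, ic]
    profiles = []
    for tr, tc in targets:
        length = np.hypot(tr - cr, tc - cc)
        n_steps = max(int(np.ceil(length / step)), 2)
        t = np.linspace(0.0, 1.0, n_steps)
        rr = cr + t * (tr - cr)
        cc_s = cc + t * (tc - cc)
        # discard blood-pool and beyond-wall samples: the annulus bounds
        # are continuous, so clip by radius rather than the voxelized mask.
        # Restrict to the voxel-center-supported band (half a voxel inside
        # each boundary) so bilinear samples are unbiased, but normalize
        # positions by the full wall extent.
        radius = t * length
        wall = geometry.r_epi - geometry.r_endo
        margin = min(0.5, 0.25 * wall)
        in_band = ((radius >= geometry.r_endo + margin)
                   & (radius <= geometry.r_epi - margin))
        if in_band.sum() < 2:
            continue
        vals = ndimage.map_coordinates(
            filled, [rr[in_band], cc_s[in_band]], order=1
        )
        s = (radius[in_band] - geometry.r_endo) / wall
        profiles.append(np.interp(positions, s, vals))
    if not profiles:
        raise ValueError("no usable rays")
    prof = np.array(profiles)
    q1, q3 = np.percentile(prof, [25, 75], axis=0)
    return TransmuralProfile(
        positions=positions,
        median_ha=np.median(prof, axis=0),
        band_sd=prof.std(axis=0),
        band_iqr=q3 - q1,
        n_rays=prof.shape[0],
    )


def fa_zones(fa_map: np.ndarray, geometry: LVGeometry) -> tuple[float, float, float]:
    """Median FA in three equal-width transmural zones (endo, meso, epi).

    Zones partition the myocardium by depth thirds [0, 1/3), [1/3, 2/3),
    [2/3, 1].  Raises if any zone is empty.
    """
    depth = geometry.depth
    zones = (
        geometry.myo_mask & (depth < 1 / 3),
        geometry.myo_mask & (depth >= 1 / 3) & (depth < 2 / 3),
        geometry.myo_mask & (depth >= 2 / 3),
    )
    out = []
    for name, z in zip(("endo", "meso", "epi"), zones):
        vals = fa_map[z]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"empty {name} zone")
        out.append(float(np.median(vals)))
    return tuple(out)


def delta_md(md_map: np.ndarray, lesion_mask: np.ndarray,
             remote_mask: np.ndarray) -> float:
    """Mean MD over the lesion minus mean MD over the remote region (mm^2/s)."""
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    remote_mask = np.asarray(remote_mask, dtype=bool)
    if not lesion_mask.any() or not remote_mask.any():
        raise ValueError("lesion and remote masks must be nonempty")
    if (lesion_mask & remote_mask).any():
        raise ValueError("lesion and remote masks overlap")
    return float(np.nanmean(md_map[lesion_mask]) - np.nanmean(md_map[remote_mask]))


def patchwise_comparison(
    err_map_a: np.ndarray,
    err_map_b: np.ndarray,
    mask: np.ndarray,
    patch_size: int = 5,
) -> float:
    """Fraction of patches where model a's mean error is strictly below b's.

    The grid of non-overlapping ``patch_size`` tiles is anchored at the mask
    bounding-box origin; a tile qualifies if it contains at least one masked
    voxel, and its error is the mean over those voxels.  Ties count in the
    denominator but not the numerator.
    """
    if patch_size < 1:
        raise ValueError("patch_size must be at least 1")
    mask = np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty mask")
    n_lower = n_tiles = 0
    for r0 in range(rows[0], rows[-1] + 1, patch_size):
        for c0 in range(cols[0], cols[-1] + 1, patch_size):
            tile = (slice(r0, r0 + patch_size), slice(c0, c0 + patch_size))
            m = mask[tile]
            if not m.any():
                continue
            a = np.nanmean(err_map_a[tile][m])
            b = np.nanmean(err_map_b[tile][m])
            n_tiles += 1
            if a < b:
                n_lower += 1
    if n_tiles == 0:
        raise ValueError("no qualifying patches")
    return n_lower / n_tiles
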