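"""Forward simulation of STEAM diffusion-weighted magnitude images.

Implements the monoexponential diffusion signal model
S = S0 * exp(-b g^T D g) with Rician magnitude noise, the acquisition
repetition structure (b = 0, 150, 600 s/mm^2 in 6 diffusion directions),
reduced breath-hold subset regimes, and repetition averaging.

Noise streams: one master seed expands to one independent substream per
image via ``numpy.random.SeedSequence(master, image_index)``, so a series is
bit-reproducible and subsetting never perturbs the noise of retained images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import TensorField

__all__ = [
    "DIRECTIONS_6",
    "BREATH_HOLD_REGIMES",
    "AcquisitionProtocol",
    "DWISeries",
    "make_protocol",
    "simulate_dwi",
    "select_repetition_subset",
    "select_regime_subset",
    "average_repetitions",
]

#: Fixed 6-direction diffusion-encoding scheme (dual-gradient / icosahedral
#: style); together with a b=0 image it spans the 7-parameter tensor model.
DIRECTIONS_6 = np.array(
    [
        [1.0, 0.0, 1.0],
        [-1.0, 0.0, 1.0],
        [0.0, 1.0, 1.0],
        [0.0, 1.0, -1.0],
        [1.0, 1.0, 0.0],
        [-1.0, 1.0, 0.0],
    ]
) / np.sqrt(2.0)

#: Repetition counts (n_b0, n_b600, n_b150) per breath-hold regime.
BREATH_HOLD_REGIMES: dict[str, tuple[int, int, int]] = {
    "full": (12, 10, 2),
    "5BH": (4, 4, 1),
    "3BH": (2, 2, 1),
    "1BH": (1, 1, 0),
}

B_LOW = 150.0
B_HIGH = 600.0


@dataclass(frozen=True)
class ImageMeta:
    """Acquisition tags of one magnitude image."""

    b_value: float
    direction_index: int      # -1 for b=0
    repetition_index: int

    @property
    def direction(self) -> np.ndarray | None:
        if self.direction_index < 0:
            return None
        return DIRECTIONS_6[self.direction_index]

    @property
    def key(self) -> tuple[float, int]:
        """(b, direction index) — the averaging group this image belongs to."""
        return (self.b_value, self.direction_index)


@dataclass
class AcquisitionProtocol:
    """List of images to acquire: (b, direction index, repetition index)."""

    entries: list[ImageMeta]
    direction_set: np.ndarray = None

    def __post_init__(self) -> None:
        if self.direction_set is None:
            self.direction_set = DIRECTIONS_6
        norms = np.linalg.norm(self.direction_set, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("diffusion directions must be unit-norm")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def unique_keys(self) -> list[tuple[float, int]]:
        """Distinct (b, direction) groups, b ascending then direction index."""
        return sorted({m.key for m in self.entries})


@dataclass
class DWISeries:
    """Stack of magnitude DWIs with per-image acquisition metadata."""

    images: np.ndarray            # (n_images, rows, cols), >= 0
    meta: list[ImageMeta]
    noise_sigma: float
    seed: int | None

    def __post_init__(self) -> None:
        if len(self.meta) != self.images.shape[0]:
            raise ValueError("meta length must equal image count")
        if np.any(self.images < 0):
            raise ValueError("magnitude images must be non-negative")


def make_protocol(regime: str) -> AcquisitionProtocol:
    """Protocol for a breath-hold regime (``full``, ``5BH``, ``3BH``, ``1BH``).

    Image count is n_b0 + 6*n_b600 + 6*n_b150 (e.g. 7 for 1BH, 84 for full).
    """
    try:
        n_b0, n_b600, n_b150 = BREATH_HOLD_REGIMES[regime]
    except KeyError:
        raise ValueError(
            f"unknown regime {regime!r}; choose from {sorted(BREATH_HOLD_REGIMES)}"
        ) from None
    entries = []
    for rep in range(n_b0):
        entries.append(ImageMeta(0.0, -1, rep))
    for b, n in ((B_LOW, n_b150), (B_HIGH, n_b600)):
        for d in range(6):
            for rep in range(n):
                entries.append(ImageMeta(b, d, rep))
    return AcquisitionProtocol(entries=entries)


def simulate_dwi(
    tensor_field: TensorField,
    s0_map: np.ndarray,
    protocol: AcquisitionProtocol,
    noise_sigma: float,
    seed: int | None = None,
) -> DWISeries:
    """Simulate a magnitude DWI series for the protocol.

    Noiseless signal per image: S = S0 * exp(-b g^T D g).  Rician noise:
    S_noisy = sqrt((S + n1)^2 + n2^2) with n1, n2 ~ N(0, sigma^2) drawn from
    an independent per-image substream of ``seed``.  Deterministic for a
    fixed seed.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    s0 = np.asarray(s0_map, dtype=float)
    if np.any(s0 < 0):
        raise ValueError("s0_map must be non-negative")
    dmat = tensor_field.as_matrices()
    images = np.empty((len(protocol),) + s0.shape)
    for i, m in enumerate(protocol.entries):
        if m.b_value > 0:
            if m.direction_index < 0:
                raise ValueError(f"image {i}: b>0 requires a direction")
            g = protocol.direction_set[m.direction_index]
            adc = np.einsum("i,rcij,j->rc", g, dmat, g)
            s = s0 * np.exp(-m.b_value * adc)
        else:
            s = s0.copy()
        if noise_sigma > 0:
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), i]))
            n1 = rng.normal(0.0, noise_sigma, s.shape)
            n2 = rng.normal(0.0, noise_sigma, s.shape)
            s = np.hypot(s + n1, n2)
        images[i] = s
    return DWISeries(images=images, meta=list(protocol.entries),
                     noise_sigma=float(noise_sigma), seed=seed)


def select_repetition_subset(
    series: DWISeries, n: int | dict[float, int], position: str
) -> DWISeries:
    """Keep ``n`` repetitions per (b, direction) group.

    ``n`` is a single count or a per-b-value mapping (a count of 0 drops the
    b-value entirely).  ``position``: ``first`` keeps repetitions 0..n-1,
    ``last`` the final n, ``central`` the n starting at floor((R - n)/2),
    independently per group.  Raises if any group holds fewer than the
    requested repetitions, naming it.
    """
    if position not in ("first", "central", "last"):
        raise ValueError(f"position must be first/central/last, got {position!r}")
    groups: dict[tuple[float, int], list[int]] = {}
    for i, m in enumerate(series.meta):
        groups.setdefault(m.key, []).append(i)
    keep: list[int] = []
    for key, idxs in groups.items():
        n_key = n[key[0]] if isinstance(n, dict) else n
        idxs = sorted(idxs, key=lambda i: series.meta[i].repetition_index)
        big_r = len(idxs)
        if n_key > big_r:
            raise ValueError(
                f"group (b={key[0]}, dir={key[1]}) has {big_r} repetitions, "
                f"cannot select {n_key}"
            )
        if position == "first":
            start = 0
        elif position == "last":
            start = big_r - n_key
        else:
            start = (big_r - n_key) // 2
        keep.extend(idxs[start:start + n_key])
    keep.sort()
    return DWISeries(
        images=series.images[keep],
        meta=[series.meta[i] for i in keep],
        noise_sigma=series.noise_sigma,
        seed=series.seed,
    )


def select_regime_subset(series: DWISeries, regime: str,
                         position: str = "first") -> DWISeries:
    """Reduce a full-protocol series to a breath-hold regime's repetitions."""
    if regime not in BREATH_HOLD_REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    n_b0, n_b600, n_b150 = BREATH_HOLD_REGIMES[regime]
    return select_repetition_subset(
        series, {0.0: n_b0, B_LOW: n_b150, B_HIGH: n_b600}, position
    )


def average_repetitions(series: DWISeries) -> tuple[np.ndarray, list[ImageMeta]]:
    """Arithmetic mean per (b, direction) group.

    Returns ``(stack, meta)`` where the stack holds one averaged image per
    group, ordered by b ascending then direction index, and each meta entry
    carries the group's (b, direction) with repetition_index 0.
    """
    if len(series.meta) == 0:
        raise ValueError("cannot average an empty series")
    groups: dict[tuple[float, int], list[int]] = {}
    for i, m in enumerate(series.meta):
        groups.setdefault(m.key, []).append(i)
    keys = sorted(groups)
    stack = np.stack([series.images[groups[k]].mean(axis=0) for k in keys])
    meta = [ImageMeta(b_value=k[0], direction_index=k[1], repetition_index=0)
            for k in keys]
    return stack, meta
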