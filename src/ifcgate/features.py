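"""Per-event image features: focus, shape, Haralick texture, intensity.

Features mirror the families an imaging cytometer's analysis software
computes for event images:

* ``gradient_rms`` — image sharpness (RMS of the central-difference
  gradient magnitude over the mask, normalized by mean masked
  intensity); low values indicate out-of-focus events.
* ``area_um2``, ``aspect_ratio``, ``major_axis_um`` — size and shape
  from the second-order central moments of the mask (axis length =
  4 * sqrt(eigenvalue); aspect ratio = minor/major, so 1 = round).
* ``h_entropy_* / h_homogeneity_*`` — Haralick gray-level co-occurrence
  statistics at a given pixel offset ("granularity"), summarized as
  mean and standard deviation over the four directions 0/45/90/135 deg.
* ``major_axis_intensity_um`` — major axis of the intensity-weighted
  second-moment ellipse.
* ``channel_intensity`` — background-subtracted integrated signal (RFU).

Undefined features (empty mask, offset larger than the object) return
the sentinel ``NaN``; downstream gating routes such events to
``unclassified`` instead of failing the batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

SENTINEL = float("nan")


@dataclass
class EventImage:
    """Multi-channel pixel data for one acquired object.

    ``channels`` maps channel names (``bf``, ``rsg``, ``pi``) to 2-D
    float arrays of identical shape; ``pixel_size_um`` is the physical
    pixel pitch.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 0.05

    def __post_init__(self) -> None:
        shapes = {ch: img.shape for ch, img in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"no channel {name!r}; have {sorted(self.channels)}")
        return np.asarray(self.channels[name], dtype=float)


@dataclass
class Mask:
    """Binary mask aligned to an event image channel."""

    pixels: np.ndarray
    method: str = "otsu_threshold"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())


def compute_mask(
    image: EventImage,
    channel: str = "bf",
    method: str = "otsu_threshold",
    dark_foreground: bool | None = None,
) -> Mask:
    """Segment the object by Otsu thresholding, optionally regularized.

    ``morphology_combined`` dilates the threshold mask and fills holes,
    approximating a morphology mask that covers the whole cell body.
    Foreground polarity is auto-detected as the minority side (cells in
    brightfield are dark on a bright background) unless given.
    A uniform image yields an empty mask.
    """
    if method not in ("otsu_threshold", "morphology_combined"):
        raise ValueError(f"unknown mask method {method!r}")
    img = image.channel(channel)
    if np.ptp(img) == 0:
        return Mask(np.zeros(img.shape, dtype=bool), method)
    t = threshold_otsu(img)
    below = img < t
    if dark_foreground is None:
        dark_foreground = below.sum() <= below.size / 2
    mask = below if dark_foreground else ~below
    if method == "morphology_combined":
        mask = ndimage.binary_dilation(mask, iterations=1)
        mask = ndimage.binary_fill_holes(mask)
    return Mask(mask, method)


def gradient_rms(image: EventImage, channel: str, mask: Mask) -> float:
    """Sharpness: normalized RMS gradient magnitude over mask pixels."""
    if mask.n_pixels == 0:
        return SENTINEL
    img = image.channel(channel)
    gy, gx = np.gradient(img)
    mag2 = gy**2 + gx**2
    mean_int = float(img[mask.pixels].mean())
    if mean_int == 0:
        return SENTINEL
    return float(np.sqrt(mag2[mask.pixels].mean()) / mean_int)


def _moment_axes(rows: np.ndarray, cols: np.ndarray, weights: np.ndarray):
    """Axis lengths (major, minor, px) of the weighted second-moment ellipse."""
    w = weights / weights.sum()
    cy = float((w * rows).sum())
    cx = float((w * cols).sum())
    dy, dx = rows - cy, cols - cx
    cov = np.array(
        [
            [(w * dy * dy).sum(), (w * dy * dx).sum()],
            [(w * dy * dx).sum(), (w * dx * dx).sum()],
        ]
    )
    eig = np.linalg.eigvalsh(cov)
    eig = np.clip(eig, 0.0, None)
    minor, major = 4.0 * np.sqrt(eig)
    return major, minor


def shape_features(mask: Mask, pixel_size_um: float) -> tuple[float, float, float]:
    """Return ``(area_um2, aspect_ratio, major_axis_um)`` of the mask."""
    if mask.n_pixels == 0:
        return SENTINEL, SENTINEL, SENTINEL
    area = mask.n_pixels * pixel_size_um**2
    rows, cols = np.nonzero(mask.pixels)
    major, minor = _moment_axes(
        rows.astype(float), cols.astype(float), np.ones(rows.size)
    )
    if major == 0:  # single pixel: define as round
        return area, 1.0, pixel_size_um
    return area, float(minor / major), float(major * pixel_size_um)


def major_axis_intensity(
    image: EventImage, channel: str, mask: Mask, pixel_size_um: float | None = None
) -> float:
    """Major axis (um) of the intensity-weighted second-moment ellipse."""
    if mask.n_pixels == 0:
        return SENTINEL
    px = pixel_size_um if pixel_size_um is not None else image.pixel_size_um
    img = image.channel(channel)
    rows, cols = np.nonzero(mask.pixels)
    weights = img[mask.pixels].astype(float)
    weights = np.clip(weights, 0.0, None)
    if weights.sum() <= 0:
        return SENTINEL
    major, _ = _moment_axes(rows.astype(float), cols.astype(float), weights)
    return float(major * px)


def channel_intensity(image: EventImage, channel: str, mask: Mask) -> float:
    """Background-subtracted integrated masked signal (RFU).

    Background is the median of the unmasked pixels, so an additive
    offset applied to the whole image cancels out.
    """
    img = image.channel(channel)
    if mask.n_pixels == 0:
        return 0.0
    outside = img[~mask.pixels]
    background = float(np.median(outside)) if outside.size else 0.0
    return float((img[mask.pixels] - background).sum())


def _cooccurrence(
    q: np.ndarray, mask: np.ndarray, dr: int, dc: int, levels: int
) -> np.ndarray:
    """Symmetric gray-level pair counts at offset (dr, dc), in-mask only."""
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        return np.zeros((levels, levels), dtype=float)
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    pairs = np.bincount(
        a[valid].ravel() * levels + b[valid].ravel(), minlength=levels * levels
    ).reshape(levels, levels)
    return (pairs + pairs.T).astype(float)


def haralick_stats(
    image: EventImage,
    channel: str,
    mask: Mask,
    granularity: int = 1,
    levels: int = 32,
) -> tuple[float, float, float, float]:
    """GLCM entropy/homogeneity at a pixel offset, over four directions.

    The masked intensities are quantized to ``levels`` equal-width gray
    levels; symmetric normalized co-occurrence matrices are built at
    offset ``granularity`` for 0/45/90/135 deg counting only pixel
    pairs that both lie inside the mask.  Per direction, entropy =
    ``-sum p log2 p`` and homogeneity = ``sum p / (1 + |i - j|)``;
    returned as ``(entropy_mean, entropy_std, homogeneity_mean,
    homogeneity_std)`` across the four directions.  If any direction
    has no in-mask pair the feature is undefined (all-NaN).
    """
    if granularity < 1:
        raise ValueError("granularity must be >= 1")
    if mask.n_pixels < 2:
        return (SENTINEL,) * 4
    img = image.channel(channel)
    vals = img[mask.pixels]
    lo, hi = float(vals.min()), float(vals.max())
    if hi > lo:
        q = np.floor((img - lo) / (hi - lo) * levels).astype(int)
        q = np.clip(q, 0, levels - 1)
    else:
        q = np.zeros(img.shape, dtype=int)

    g = granularity
    # per-direction pixel offsets (row, col); symmetric counting makes
    # the opposite offsets redundant
    offsets = ((0, g), (g, g), (g, 0), (g, -g))
    i_idx, j_idx = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    inv_dist = 1.0 / (1.0 + np.abs(i_idx - j_idx))
    entropies, homogeneities = [], []
    for dr, dc in offsets:
        counts = _cooccurrence(q, mask.pixels, dr, dc, levels)
        total = counts.sum()
        if total == 0:
            return (SENTINEL,) * 4
        p = counts / total
        nz = p[p > 0]
        entropies.append(float(-(nz * np.log2(nz)).sum()))
        homogeneities.append(float((p * inv_dist).sum()))
    ent = np.array(entropies)
    hom = np.array(homogeneities)
    return (
        float(ent.mean()),
        float(ent.std()),
        float(hom.mean()),
        float(hom.std()),
    )


# ---------------------------------------------------------------------------
# Whole-event extraction

#: channel/mask plan for the canonical feature columns: brightfield
#: features use the default-threshold brightfield mask; stain-channel
#: features use the morphology-combined mask of that channel (covering
#: the full cell body).
DEFAULT_GRANULARITIES = (9, 11)


@dataclass
class FeatureVector:
    """Scalar features for one event, in canonical column order."""

    gradient_rms: float = SENTINEL
    area_um2: float = SENTINEL
    aspect_ratio: float = SENTINEL
    major_axis_um: float = SENTINEL
    major_axis_intensity_um: float = SENTINEL
    rsg_intensity: float = 0.0
    pi_intensity: float = 0.0
    texture: dict = field(default_factory=dict)

    def as_row(self) -> dict[str, float]:
        row = {
            "gradient_rms": self.gradient_rms,
            "area_um2": self.area_um2,
            "aspect_ratio": self.aspect_ratio,
            "major_axis_um": self.major_axis_um,
            "major_axis_intensity_um": self.major_axis_intensity_um,
            "rsg_intensity": self.rsg_intensity,
            "pi_intensity": self.pi_intensity,
        }
        row.update(self.texture)
        return row


def extract_features(
    image: EventImage,
    stain_channels: tuple[str, ...] = ("rsg", "pi"),
    granularities: tuple[int, ...] = DEFAULT_GRANULARITIES,
    levels: int = 32,
) -> FeatureVector:
    """Compute the full canonical feature vector for one event image."""
    px = image.pixel_size_um
    bf_mask = compute_mask(image, "bf", "otsu_threshold")
    body_mask = compute_mask(image, "bf", "morphology_combined")

    fv = FeatureVector()
    fv.gradient_rms = gradient_rms(image, "bf", bf_mask)
    fv.area_um2, fv.aspect_ratio, fv.major_axis_um = shape_features(bf_mask, px)

    texture: dict[str, float] = {}
    for g in granularities:
        e_mean, e_std, h_mean, h_std = haralick_stats(image, "bf", bf_mask, g, levels)
        texture[f"h_entropy_mean_bf_{g}"] = e_mean
        texture[f"h_entropy_std_bf_{g}"] = e_std
        texture[f"h_homogeneity_mean_bf_{g}"] = h_mean
        texture[f"h_homogeneity_std_bf_{g}"] = h_std

    for ch in stain_channels:
        ch_mask = compute_mask(image, ch, "morphology_combined", dark_foreground=False)
        use_mask = ch_mask if ch_mask.n_pixels else body_mask
        setattr(
            fv, f"{ch}_intensity", max(channel_intensity(image, ch, body_mask), 0.0)
        )
        if ch == stain_channels[0]:
            g0 = granularities[0]
            e_mean, e_std, _, _ = haralick_stats(image, ch, use_mask, g0, levels)
            texture[f"h_entropy_mean_{ch}_{g0}"] = e_mean
            texture[f"h_entropy_std_{ch}_{g0}"] = e_std
            fv.major_axis_intensity_um = major_axis_intensity(image, ch, use_mask, px)
    fv.texture = texture
    return fv
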