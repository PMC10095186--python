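"""Synthetic IFC event generator, plate-count and sorting simulators.

The generator emulates the statistical structure that the gating
analysis assumes in a dual-stained (RSG / PI) bacterial sample:

* four physiological subpopulations (``active``, ``mid_active_1``,
  ``mid_active_2``, ``dead``) with distinct bivariate log-normal
  RSG x PI fluorescence distributions — active cells are RSG-high /
  PI-low, dead cells the mirror image, and the two mid-active groups
  are double-positive with mid-active II at higher metabolic activity
  (RSG) than mid-active I;
* non-cellular debris (low, weakly correlated intensities, irregular
  small shapes, distinct brightfield/stain texture);
* cell aggregates (summed member-cell intensities, large area, low
  aspect ratio);
* out-of-focus events (low brightfield Gradient RMS).

Every event carries a ground-truth ``true_label`` so that gate and
classifier performance can be scored exactly.  All generators are
bit-reproducible given their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .features import EventImage
from .iodata import CELL_LABELS

# ---------------------------------------------------------------------------
# Specifications


@dataclass(frozen=True)
class FluorescenceProfile:
    """Bivariate log-normal RSG/PI intensity distribution (log10 RFU)."""

    mu_log_rsg: float
    mu_log_pi: float
    sd_log_rsg: float
    sd_log_pi: float
    rho: float = 0.2

    def __post_init__(self) -> None:
        if self.sd_log_rsg <= 0 or self.sd_log_pi <= 0:
            raise ValueError("log-SDs must be > 0")
        if not abs(self.rho) < 1:
            raise ValueError("|correlation| must be < 1")


#: Default fluorescence geometry (log10 RFU).  Centers reproduce the
#: qualitative four-quadrant layout of RSG x PI dot plots: active
#: RSG-high/PI-low, dead RSG-low/PI-high, mid-active I and II
#: double-positive with the I/II split on RSG.  The stains print no
#: numeric gate positions, so these are documented calibration choices.
DEFAULT_PROFILES: dict[str, FluorescenceProfile] = {
    "active": FluorescenceProfile(3.2, 0.7, 0.20, 0.18),
    "mid_active_1": FluorescenceProfile(1.9, 2.4, 0.18, 0.20),
    "mid_active_2": FluorescenceProfile(3.2, 2.4, 0.20, 0.20),
    "dead": FluorescenceProfile(0.7, 3.2, 0.18, 0.25),
    "debris": FluorescenceProfile(0.35, 0.35, 0.30, 0.30, rho=0.05),
}


@dataclass(frozen=True)
class ShapeSpec:
    """Morphology distributions for rendered and tabulated events.

    Lengths in micrometres.  ``aggregate_extra_mean`` parameterizes the
    Poisson tail of the aggregate size (cells per aggregate =
    2 + Poisson(aggregate_extra_mean)).
    """

    morphology: str = "coccus"
    length_um: tuple[float, float] = (1.25, 0.10)  # mean, sd
    width_um: tuple[float, float] = (1.10, 0.08)
    area_um2: tuple[float, float] = (1.10, 0.15)
    aggregate_extra_mean: float = 0.8
    aggregate_packing: float = 0.9  # area shrinkage from member overlap
    defocus_sigma_um: tuple[float, float] = (0.45, 0.10)

    def __post_init__(self) -> None:
        if self.morphology not in ("coccus", "rod"):
            raise ValueError("morphology must be 'coccus' or 'rod'")
        if not self.length_um[0] >= self.width_um[0] > 0:
            raise ValueError("length >= width > 0 required")


@dataclass(frozen=True)
class MixtureSpec:
    """Ground-truth mixture of subpopulations and nuisance events.

    Fractions are of all acquired events and must sum to <= 1; the
    remainder is generated as debris-like events with ground-truth label
    ``unclassified``.  ``profiles`` maps labels to fluorescence
    distributions (defaults: :data:`DEFAULT_PROFILES`).
    """

    f_active: float = 0.25
    f_mid_active_1: float = 0.25
    f_mid_active_2: float = 0.25
    f_dead: float = 0.25
    f_debris: float = 0.0
    f_aggregate: float = 0.0
    f_defocus: float = 0.0
    profiles: Mapping[str, FluorescenceProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    concentration_obj_per_ml: float = 3e8
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {name} = {f} outside [0, 1]")
        if sum(self.fractions.values()) > 1.0 + 1e-9:
            raise ValueError("fractions sum to more than 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def fractions(self) -> dict[str, float]:
        return {
            "active": self.f_active,
            "mid_active_1": self.f_mid_active_1,
            "mid_active_2": self.f_mid_active_2,
            "dead": self.f_dead,
            "debris": self.f_debris,
            "aggregate": self.f_aggregate,
            "out_of_focus": self.f_defocus,
        }


def mixture_from_percentages(
    active: float,
    mid_active_1: float,
    mid_active_2: float,
    dead: float,
    remainder_split: tuple[float, float, float] = (0.70, 0.15, 0.15),
    **kwargs,
) -> MixtureSpec:
    """Build a :class:`MixtureSpec` from measured subpopulation percentages.

    The published composition tables report the four subpopulations as
    percentages of all events that never sum to 100; the remainder is
    what the gating chain removed.  It is allocated here to debris,
    aggregates and out-of-focus events in the given proportions
    (default 70/15/15).
    """
    total = active + mid_active_1 + mid_active_2 + dead
    if total > 100.0 + 1e-9:
        raise ValueError("percentages sum to more than 100")
    remainder = max(0.0, 100.0 - total) / 100.0
    w = np.asarray(remainder_split, dtype=float)
    w = w / w.sum()
    return MixtureSpec(
        f_active=active / 100.0,
        f_mid_active_1=mid_active_1 / 100.0,
        f_mid_active_2=mid_active_2 / 100.0,
        f_dead=dead / 100.0,
        f_debris=remainder * w[0],
        f_aggregate=remainder * w[1],
        f_defocus=remainder * w[2],
        **kwargs,
    )


def reference_mixture(spec: MixtureSpec) -> MixtureSpec:
    """Balanced calibration mixture sharing ``spec``'s distributions.

    Equal fractions of the four stained subpopulations plus moderate
    debris/aggregate/defocus load; used to calibrate gate thresholds the
    way gates are positioned on stained control samples, independently
    of the composition of the sample under analysis.
    """
    return replace(
        spec,
        f_active=0.20,
        f_mid_active_1=0.20,
        f_mid_active_2=0.20,
        f_dead=0.20,
        f_debris=0.12,
        f_aggregate=0.04,
        f_defocus=0.04,
    )


# ---------------------------------------------------------------------------
# Event-table generation

#: per-class (mean, sd) for texture / intensity-geometry features.
#: Cells carry structured cytoplasmic texture (higher GLCM entropy);
#: debris is flatter and smaller.  Feature names follow the canonical
#: schema: ``h_<stat>_<channel>_<granularity>``.
_CELL_TEXTURE = {
    "h_entropy_mean_rsg_9": (3.20, 0.25),
    "h_entropy_std_rsg_9": (1.30, 0.12),
    "h_entropy_std_bf_9": (1.10, 0.12),
    "h_entropy_std_bf_11": (1.05, 0.12),
    "h_homogeneity_std_bf_11": (0.12, 0.02),
    "major_axis_intensity_um": (1.25, 0.12),
}
_DEBRIS_TEXTURE = {
    "h_entropy_mean_rsg_9": (2.30, 0.25),
    "h_entropy_std_rsg_9": (0.90, 0.12),
    "h_entropy_std_bf_9": (0.75, 0.12),
    "h_entropy_std_bf_11": (0.72, 0.12),
    "h_homogeneity_std_bf_11": (0.19, 0.02),
    "major_axis_intensity_um": (0.70, 0.15),
}

#: feature columns offered to the cells-vs-debris classifier; mirrors
#: the published seven-feature structure (stain-channel and brightfield
#: GLCM statistics at granularities 9 and 11, area, major axis
#: intensity).
CLASSIFIER_CANDIDATE_FEATURES = (
    "h_entropy_std_rsg_9",
    "h_entropy_std_bf_9",
    "h_homogeneity_std_bf_11",
    "area_um2",
    "h_entropy_std_bf_11",
    "h_entropy_mean_rsg_9",
    "major_axis_intensity_um",
)

_GRADIENT_RMS_IN_FOCUS = (55.0, 7.0)
_GRADIENT_RMS_DEFOCUS = (12.0, 4.0)

_GENERATOR_LABELS = (
    "active",
    "mid_active_1",
    "mid_active_2",
    "dead",
    "debris",
    "aggregate",
    "out_of_focus",
    "unclassified",
)


def _bivariate_lognormal(
    rng: np.random.Generator, prof: FluorescenceProfile, n: int
) -> tuple[np.ndarray, np.ndarray]:
    cov = np.array(
        [
            [prof.sd_log_rsg**2, prof.rho * prof.sd_log_rsg * prof.sd_log_pi],
            [prof.rho * prof.sd_log_rsg * prof.sd_log_pi, prof.sd_log_pi**2],
        ]
    )
    z = rng.multivariate_normal([prof.mu_log_rsg, prof.mu_log_pi], cov, size=n)
    return 10.0 ** z[:, 0], 10.0 ** z[:, 1]


def _cell_weights(spec: MixtureSpec) -> np.ndarray:
    w = np.array([spec.fractions[c] for c in CELL_LABELS], dtype=float)
    if w.sum() <= 0:
        w = np.ones(4)
    return w / w.sum()


def sample_events(
    spec: MixtureSpec,
    shape: ShapeSpec | None = None,
    n: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw ``n`` ground-truth-labelled events from the mixture.

    Returns an event table with intensities, all feature columns the
    gating chain consumes and a ``true_label`` column.  ``label`` starts
    as ``unclassified`` for every event.  Identical ``(spec, shape, n,
    seed)`` give identical tables.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    shape = shape or ShapeSpec()
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    fr = spec.fractions
    probs = np.array([fr[c] for c in _GENERATOR_LABELS[:-1]], dtype=float)
    probs = np.append(probs, max(0.0, 1.0 - probs.sum()))
    labels = rng.choice(len(_GENERATOR_LABELS), size=n, p=probs / probs.sum())
    true_label = np.array(_GENERATOR_LABELS, dtype=object)[labels]

    rsg = np.zeros(n)
    pi = np.zeros(n)
    area = np.zeros(n)
    aspect = np.zeros(n)
    grad = np.zeros(n)
    texture = {name: np.zeros(n) for name in _CELL_TEXTURE}

    def _fill_texture(idx: np.ndarray, table: dict) -> None:
        for name, (mu, sd) in table.items():
            texture[name][idx] = np.clip(rng.normal(mu, sd, idx.size), 0.0, None)

    # stained single cells
    for cls in CELL_LABELS:
        idx = np.flatnonzero(true_label == cls)
        if idx.size == 0:
            continue
        r, p = _bivariate_lognormal(rng, spec.profiles[cls], idx.size)
        rsg[idx], pi[idx] = r, p
        area[idx] = np.clip(rng.normal(*shape.area_um2, idx.size), 0.2, None)
        aspect[idx] = np.clip(1.0 - np.abs(rng.normal(0.0, 0.04, idx.size)), 1e-3, 1.0)
        grad[idx] = np.clip(rng.normal(*_GRADIENT_RMS_IN_FOCUS, idx.size), 0.0, None)
        _fill_texture(idx, _CELL_TEXTURE)

    # debris and unclassifiable remainder: low, weakly correlated signal
    for cls in ("debris", "unclassified"):
        idx = np.flatnonzero(true_label == cls)
        if idx.size == 0:
            continue
        r, p = _bivariate_lognormal(rng, spec.profiles["debris"], idx.size)
        rsg[idx], pi[idx] = r, p
        area[idx] = 10.0 ** rng.normal(np.log10(0.4), 0.35, idx.size)
        aspect[idx] = rng.uniform(0.2, 1.0, idx.size)
        grad[idx] = np.clip(rng.normal(*_GRADIENT_RMS_IN_FOCUS, idx.size), 0.0, None)
        _fill_texture(idx, _DEBRIS_TEXTURE)

    # aggregates: summed intensities/areas of >= 2 member cells
    idx = np.flatnonzero(true_label == "aggregate")
    if idx.size:
        k = 2 + rng.poisson(shape.aggregate_extra_mean, idx.size)
        weights = _cell_weights(spec)
        members = rng.choice(4, size=int(k.sum()), p=weights)
        m_rsg = np.zeros(members.size)
        m_pi = np.zeros(members.size)
        for ci, cls in enumerate(CELL_LABELS):
            sel = np.flatnonzero(members == ci)
            if sel.size:
                m_rsg[sel], m_pi[sel] = _bivariate_lognormal(
                    rng, spec.profiles[cls], sel.size
                )
        bounds = np.concatenate([[0], np.cumsum(k)])[:-1]
        rsg[idx] = np.add.reduceat(m_rsg, bounds)
        pi[idx] = np.add.reduceat(m_pi, bounds)
        m_area = np.clip(rng.normal(*shape.area_um2, members.size), 0.2, None)
        area[idx] = shape.aggregate_packing * np.add.reduceat(m_area, bounds)
        aspect[idx] = rng.uniform(0.25, 0.70, idx.size)
        grad[idx] = np.clip(rng.normal(*_GRADIENT_RMS_IN_FOCUS, idx.size), 0.0, None)
        _fill_texture(idx, _CELL_TEXTURE)

    # out-of-focus cells: intensities of an underlying cell class, low
    # brightfield sharpness, blur-inflated apparent area
    idx = np.flatnonzero(true_label == "out_of_focus")
    if idx.size:
        weights = _cell_weights(spec)
        under = rng.choice(4, size=idx.size, p=weights)
        for ci, cls in enumerate(CELL_LABELS):
            sel = idx[under == ci]
            if sel.size:
                rsg[sel], pi[sel] = _bivariate_lognormal(
                    rng, spec.profiles[cls], sel.size
                )
        area[idx] = 1.3 * np.clip(rng.normal(*shape.area_um2, idx.size), 0.2, None)
        aspect[idx] = np.clip(1.0 - np.abs(rng.normal(0.0, 0.06, idx.size)), 1e-3, 1.0)
        grad[idx] = np.clip(rng.normal(*_GRADIENT_RMS_DEFOCUS, idx.size), 0.0, None)
        _fill_texture(idx, _CELL_TEXTURE)

    major_axis = 2.0 * np.sqrt(area / (np.pi * aspect))
    rep = np.repeat(
        np.arange(spec.n_replicates), int(np.ceil(n / spec.n_replicates))
    )[:n]

    table = pd.DataFrame(
        {
            "event_id": np.arange(n, dtype=int),
            "replicate_id": rep,
            "true_label": true_label,
            "label": "unclassified",
            "rsg_intensity": rsg,
            "pi_intensity": pi,
            "gradient_rms": grad,
            "area_um2": area,
            "aspect_ratio": aspect,
            "major_axis_um": major_axis,
        }
    )
    for name in _CELL_TEXTURE:
        table[name] = texture[name]
    return table


# ---------------------------------------------------------------------------
# Event-image rendering


def _ellipse_mask(
    shape_px: tuple[int, int],
    center: tuple[float, float],
    semi_major: float,
    semi_minor: float,
    theta: float,
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape_px[0], 0 : shape_px[1]]
    dy = rr - center[0]
    dx = cc - center[1]
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0


def render_event_image(
    record: Mapping[str, object],
    shape: ShapeSpec | None = None,
    image_size: int = 96,
    pixel_size_um: float = 0.05,
    seed: int = 0,
) -> EventImage:
    """Render a three-channel (BF, RSG, PI) image for one event.

    Brightfield shows the cell silhouette dark on a bright background;
    the stain channels deposit the record's integrated intensity inside
    the cell mask with multiplicative granular texture.  Out-of-focus
    events are Gaussian-blurred; debris is rendered as an irregular
    low-contrast blob; aggregates as a chain of touching cells.
    """
    shape = shape or ShapeSpec()
    rng = np.random.default_rng(seed)
    label = str(record["true_label"])
    area_um2 = float(record.get("area_um2", shape.area_um2[0]))
    aspect = float(record.get("aspect_ratio", 0.95))
    aspect = min(max(aspect, 0.05), 1.0)

    area_px = area_um2 / pixel_size_um**2
    semi_major = np.sqrt(area_px / (np.pi * aspect))
    semi_minor = aspect * semi_major
    if 2 * semi_major + 8 > image_size:
        raise ValueError(
            f"image size {image_size} px too small for object of major axis "
            f"{2 * semi_major:.1f} px"
        )
    shape_px = (image_size, image_size)
    c0 = image_size / 2.0

    theta = rng.uniform(0, np.pi)
    if label == "aggregate":
        # chain of 2-4 touching cells
        k = int(min(4, 2 + rng.poisson(0.5)))
        r = np.sqrt(area_px / k / np.pi)
        mask = np.zeros(shape_px, dtype=bool)
        step = 1.8 * r
        start = c0 - step * (k - 1) / 2.0
        for i in range(k):
            cy = start + i * step + rng.normal(0, r * 0.15)
            cx = c0 + rng.normal(0, r * 0.3)
            mask |= _ellipse_mask(shape_px, (cy, cx), r, r, 0.0)
    elif label in ("debris", "unclassified"):
        # irregular blob: union of a few random small ellipses
        mask = np.zeros(shape_px, dtype=bool)
        for _ in range(rng.integers(2, 5)):
            cy = c0 + rng.normal(0, semi_major * 0.6)
            cx = c0 + rng.normal(0, semi_major * 0.6)
            mask |= _ellipse_mask(
                shape_px,
                (cy, cx),
                semi_major * rng.uniform(0.4, 0.9),
                semi_minor * rng.uniform(0.3, 0.8),
                rng.uniform(0, np.pi),
            )
    else:
        mask = _ellipse_mask(shape_px, (c0, c0), semi_major, semi_minor, theta)
    n_px = max(int(mask.sum()), 1)

    bf = rng.normal(220.0, 3.0, shape_px)
    bf[mask] = rng.normal(140.0, 12.0, n_px)

    channels = {"bf": bf}
    for ch, key in (("rsg", "rsg_intensity"), ("pi", "pi_intensity")):
        total = float(record[key])
        img = np.abs(rng.normal(0.0, 0.5, shape_px))
        if total > 0:
            weights = rng.gamma(4.0, 1.0, n_px)
            img[mask] += total * weights / weights.sum()
        channels[ch] = img

    if label == "out_of_focus":
        sigma_um = max(rng.normal(*shape.defocus_sigma_um), 0.1)
        sigma_px = sigma_um / pixel_size_um
        channels = {
            ch: ndimage.gaussian_filter(img, sigma_px) for ch, img in channels.items()
        }
    return EventImage(channels=channels, pixel_size_um=pixel_size_um)


# ---------------------------------------------------------------------------
# Plate-count simulator


@dataclass(frozen=True)
class PlateSeries:
    """One decimal-dilution pour-plate series."""

    dilution_exponents: tuple[int, ...]
    counts: tuple[int, ...]
    plated_volume_mL: float = 1.0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.dilution_exponents):
            raise ValueError("one colony count per dilution required")
        if any(c < 0 for c in self.counts):
            raise ValueError("colony counts must be nonnegative")
        if self.plated_volume_mL <= 0:
            raise ValueError("plated volume must be > 0")


def simulate_plating(
    viable_concentration: float,
    dilution_exponents: Sequence[int] = tuple(range(-1, -10, -1)),
    plated_volume_mL: float = 1.0,
    seed: int = 0,
    plating_efficiency: float = 1.0,
) -> PlateSeries:
    """Simulate a decimal dilution series plated on pour plates.

    Colonies per plate are Poisson with mean ``concentration *
    efficiency * 10**exponent * volume``.  ``plating_efficiency < 1``
    emulates the systematic undercounting of plate methods (non-growing
    but viable cells); the default is ideal plating.
    """
    if viable_concentration < 0:
        raise ValueError("concentration must be >= 0")
    if not 0.0 <= plating_efficiency <= 1.0:
        raise ValueError("plating efficiency must be in [0, 1]")
    rng = np.random.default_rng(seed)
    exps = tuple(int(e) for e in dilution_exponents)
    lam = (
        viable_concentration
        * plating_efficiency
        * np.power(10.0, np.array(exps, dtype=float))
        * plated_volume_mL
    )
    counts = tuple(int(c) for c in rng.poisson(lam))
    return PlateSeries(exps, counts, plated_volume_mL)


# ---------------------------------------------------------------------------
# Single-cell sorting simulator


@dataclass(frozen=True)
class ODGrowthModel:
    """Lag + logistic OD600 trajectory for wells seeded with one cell.

    ``OD(t) = od_max / (1 + exp(-rate * (t - t_mid)))`` with the
    midpoint ``t_mid`` drawn per well from a truncated normal
    distribution (``lag_mean_h``/``lag_sd_h``).  A well crosses an OD
    threshold ``c`` at ``t_mid - ln(od_max/c - 1)/rate``; with the
    defaults, most wells cross 0.1 before the 48 h read and slow wells
    only between 48 h and 72 h.
    """

    lag_mean_h: float = 48.0
    lag_sd_h: float = 10.0
    rate_per_h: float = 0.3
    od_max: float = 1.0
    noise_sd: float = 0.004

    def od_at(self, t_h: float, t_mid: np.ndarray) -> np.ndarray:
        return self.od_max / (1.0 + np.exp(-self.rate_per_h * (t_h - t_mid)))


@dataclass
class SortingOutcome:
    """Growth outcomes for single cells sorted per subpopulation x medium.

    ``colonies_*`` count visible colonies on MRS-Agar; ``wells_*`` count
    MRS-broth wells whose blank-subtracted OD600 exceeds the growth
    threshold.  ``od600_48h`` / ``od600_72h`` hold the blank-subtracted
    per-well readings.
    """

    n_sorted: int
    colonies_48h: dict[str, int]
    colonies_72h: dict[str, int]
    wells_48h: dict[str, int]
    wells_72h: dict[str, int]
    od600_48h: dict[str, np.ndarray]
    od600_72h: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for grp in self.colonies_48h:
            for d in (self.colonies_48h, self.colonies_72h, self.wells_48h, self.wells_72h):
                if not 0 <= d[grp] <= self.n_sorted:
                    raise ValueError("growth counts must lie in [0, n_sorted]")
            if self.colonies_72h[grp] < self.colonies_48h[grp]:
                raise ValueError("colony counts must be non-decreasing in time")
            if self.wells_72h[grp] < self.wells_48h[grp]:
                raise ValueError("well counts must be non-decreasing in time")


def simulate_sorting(
    growth_prob: Mapping[str, float],
    n_cells: int = 24,
    od_model: ODGrowthModel | None = None,
    seed: int = 0,
    od_threshold: float = 0.1,
) -> SortingOutcome:
    """Simulate sorting ``n_cells`` single cells per subpopulation.

    Each sorted cell grows with its subpopulation's probability, on both
    media independently; growing wells/colonies follow the lag +
    logistic model, so growth counts are non-decreasing from 48 h to
    72 h by construction.
    """
    if any(not 0.0 <= p <= 1.0 for p in growth_prob.values()):
        raise ValueError("growth probabilities must be in [0, 1]")
    od_model = od_model or ODGrowthModel()
    rng = np.random.default_rng(seed)

    colonies_48: dict[str, int] = {}
    colonies_72: dict[str, int] = {}
    wells_48: dict[str, int] = {}
    wells_72: dict[str, int] = {}
    od48: dict[str, np.ndarray] = {}
    od72: dict[str, np.ndarray] = {}

    def _timecourse(p: float) -> tuple[np.ndarray, np.ndarray]:
        grows = rng.random(n_cells) < p
        t_mid = np.clip(
            rng.normal(od_model.lag_mean_h, od_model.lag_sd_h, n_cells), 8.0, None
        )
        od_48 = np.where(grows, od_model.od_at(48.0, t_mid), 0.0)
        od_72 = np.where(grows, od_model.od_at(72.0, t_mid), 0.0)
        od_48 = np.abs(od_48 + rng.normal(0.0, od_model.noise_sd, n_cells))
        od_72 = np.maximum(od_72 + rng.normal(0.0, od_model.noise_sd, n_cells), od_48)
        return od_48, od_72

    for grp, p in growth_prob.items():
        # broth wells
        w48, w72 = _timecourse(p)
        od48[grp], od72[grp] = w48, w72
        wells_48[grp] = int((w48 > od_threshold).sum())
        wells_72[grp] = int((w72 > od_threshold).sum())
        # agar spots: independent cells, same lag structure; a colony is
        # countable once its trajectory passes the detection threshold
        a48, a72 = _timecourse(p)
        colonies_48[grp] = int((a48 > od_threshold).sum())
        colonies_72[grp] = int((a72 > od_threshold).sum())

    return SortingOutcome(
        n_sorted=n_cells,
        colonies_48h=colonies_48,
        colonies_72h=colonies_72,
        wells_48h=wells_48,
        wells_72h=wells_72,
        od600_48h=od48,
        od600_72h=od72,
    )
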