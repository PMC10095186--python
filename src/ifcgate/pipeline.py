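"""End-to-end orchestration: calibration, gate chain, recovery runs.

Thresholds are calibrated on a *balanced reference mixture* (equal
fractions of the four stained subpopulations plus debris/aggregate/
defocus load), the way quadrant gates are positioned on stained control
samples before analysing experimental tubes:

* focus threshold — Otsu on the reference ``gradient_rms`` histogram;
* singles gates — extreme percentiles of the reference single-cell
  area and aspect-ratio distributions;
* quadrant thresholds — valleys of smoothed log10-intensity histograms
  of reference events that survive the focus/singles/classifier gates
  (``t_pi`` between the PI-negative and PI-positive modes; ``t_rsg``
  and ``t_mid`` between the three RSG modes of PI-positive events).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu

from .classify import ClassifierModel, TruthSet, train_classifier
from .gating import (
    GateConfig,
    SubpopulationSummary,
    assign_subpopulations,
    gate_cells,
    gate_focus,
    gate_singles,
    summarize,
)
from .iodata import CELL_LABELS
from .synthetic_data import (
    CLASSIFIER_CANDIDATE_FEATURES,
    MixtureSpec,
    ShapeSpec,
    mixture_from_percentages,
    reference_mixture,
    sample_events,
)


def run_gate_chain(
    table: pd.DataFrame, config: GateConfig, model: ClassifierModel | None = None
) -> pd.DataFrame:
    """Apply focus, singles, classifier and quadrant gates in order."""
    out = gate_focus(table, config)
    out = gate_singles(out, config)
    if model is not None:
        out = gate_cells(out, model)
    return assign_subpopulations(out, config)


# ---------------------------------------------------------------------------
# Histogram calibration


def _histogram_valleys(
    values: np.ndarray, n_modes: int, bins: int = 100, smooth_bins: float = 2.5
) -> list[float]:
    """Valley positions between the ``n_modes`` lowest-position modes.

    The histogram is Gaussian-smoothed; modes are peaks with prominence
    above 2% of the maximum, taken in order of position.  Returns the
    ``n_modes - 1`` minima between consecutive modes.
    """
    values = values[np.isfinite(values)]
    if values.size < 10:
        raise ValueError("too few events to calibrate a threshold")
    hist, edges = np.histogram(values, bins=bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    smooth = gaussian_filter1d(hist.astype(float), smooth_bins)
    peaks, _ = find_peaks(smooth, prominence=0.02 * smooth.max())
    if len(peaks) < n_modes:
        raise ValueError(
            f"found {len(peaks)} modes, need {n_modes}; "
            "is the calibration sample balanced?"
        )
    peaks = np.sort(peaks)[:n_modes]
    valleys = []
    for left, right in zip(peaks[:-1], peaks[1:]):
        j = left + int(np.argmin(smooth[left : right + 1]))
        valleys.append(float(centers[j]))
    return valleys


def train_debris_classifier(
    spec: MixtureSpec,
    shape: ShapeSpec | None = None,
    n_truth: int = 32,
    k: int = 7,
    seed: int = 0,
) -> ClassifierModel:
    """Train the cells-vs-debris classifier from generated truth sets.

    Emulates the manual tagging of two exemplar populations: ``n_truth``
    unambiguous single cells (balanced across the four subpopulations)
    and ``n_truth`` debris events, then trains the k-feature linear
    discriminant on the canonical candidate features.
    """
    shape = shape or ShapeSpec()
    cells_spec = replace(
        spec,
        f_active=0.25,
        f_mid_active_1=0.25,
        f_mid_active_2=0.25,
        f_dead=0.25,
        f_debris=0.0,
        f_aggregate=0.0,
        f_defocus=0.0,
    )
    debris_spec = replace(
        spec,
        f_active=0.0,
        f_mid_active_1=0.0,
        f_mid_active_2=0.0,
        f_dead=0.0,
        f_debris=1.0,
        f_aggregate=0.0,
        f_defocus=0.0,
    )
    cells = sample_events(cells_spec, shape, n=n_truth, seed=seed + 1)
    debris = sample_events(debris_spec, shape, n=n_truth, seed=seed + 2)
    truth = TruthSet(class_a=cells, class_b=debris)
    return train_classifier(truth, CLASSIFIER_CANDIDATE_FEATURES, k=k)


def calibrate_gates(
    reference: pd.DataFrame,
    model: ClassifierModel | None = None,
    singles_percentiles: tuple[float, float] = (0.1, 99.9),
    log_pseudocount: float = 1e-3,
) -> GateConfig:
    """Calibrate all gate thresholds from a balanced reference table.

    ``reference`` must carry ``true_label`` (a control/reference sample
    of known composition); single-cell percentiles for the shape gate
    are taken over its labelled single cells, intensity valleys over
    the events that survive the upstream gates.
    """
    if "true_label" not in reference.columns:
        raise ValueError("calibration requires a labelled reference table")

    grad = reference["gradient_rms"].to_numpy(dtype=float)
    gradient_rms_min = float(threshold_otsu(grad[np.isfinite(grad)]))

    singles = reference[reference["true_label"].isin(CELL_LABELS)]
    lo, hi = singles_percentiles
    area_min = float(np.percentile(singles["area_um2"], lo))
    area_max = float(np.percentile(singles["area_um2"], hi))
    aspect_min = float(np.percentile(singles["aspect_ratio"], lo))

    config = GateConfig(
        gradient_rms_min=gradient_rms_min,
        area_min_um2=area_min,
        area_max_um2=area_max,
        aspect_ratio_min=aspect_min,
        log_pseudocount=log_pseudocount,
    )

    gated = gate_focus(reference, config)
    gated = gate_singles(gated, config)
    if model is not None:
        gated = gate_cells(gated, model)
    open_ = gated[gated["label"] == "unclassified"]

    eps = log_pseudocount
    log_pi = np.log10(np.maximum(open_["pi_intensity"].to_numpy(dtype=float), eps))
    (v_pi,) = _histogram_valleys(log_pi, n_modes=2)
    t_pi = 10.0**v_pi

    pi_pos = open_[open_["pi_intensity"] > t_pi]
    log_rsg = np.log10(np.maximum(pi_pos["rsg_intensity"].to_numpy(dtype=float), eps))
    v_rsg, v_mid = _histogram_valleys(log_rsg, n_modes=3)
    config.t_pi = t_pi
    config.t_rsg = 10.0**v_rsg
    config.t_mid = 10.0**v_mid
    return config


# ---------------------------------------------------------------------------
# Recovery runs (simulate -> calibrate -> gate -> summarize)


def recover_composition(
    composition: dict[str, float],
    n_events: int = 20000,
    seed: int = 0,
    n_reference: int = 20000,
    shape: ShapeSpec | None = None,
    denominator: str = "all_events",
) -> tuple[SubpopulationSummary, pd.DataFrame, GateConfig]:
    """Full pipeline on a synthetic sample of known composition.

    ``composition`` gives the four subpopulation percentages of all
    events (remainder modelled as debris/aggregates/defocus).  Returns
    the percentage summary, the labelled table and the calibrated gate
    configuration.  Deterministic given all arguments.
    """
    shape = shape or ShapeSpec()
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=3)]

    spec = mixture_from_percentages(**composition)
    model = train_debris_classifier(spec, shape, seed=sub[0])
    reference = sample_events(reference_mixture(spec), shape, n=n_reference, seed=sub[1])
    config = calibrate_gates(reference, model)

    table = sample_events(spec, shape, n=n_events, seed=sub[2])
    labelled = run_gate_chain(table, config, model)
    summary = summarize(labelled, denominator=denominator)
    return summary, labelled, config


def recovered_percentage(summary: SubpopulationSummary, category: str) -> float:
    """Pooled percentage of one category from a summary."""
    row = summary.pooled.loc[summary.pooled["category"] == category, "percentage"]
    if row.empty:
        raise KeyError(f"category {category!r} not in summary")
    return float(row.iloc[0])
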