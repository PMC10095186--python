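"""Three-step gating and RSG/PI subpopulation assignment.

Gates are applied in a fixed order, each writing a terminal label into
the ``label`` column of the event table (events already labelled by an
earlier gate are not revisited):

1. focus — events with brightfield ``gradient_rms`` below threshold are
   ``out_of_focus``;
2. singles — shape gate on ``area_um2`` and ``aspect_ratio``: too large
   or too elongated means ``aggregate``, too small means ``debris``;
3. cells vs debris — events scoring <= 0 under the trained linear
   classifier are ``debris``;
4. quadrants — surviving single cells are assigned by their RSG/PI
   intensities: PI-negative and RSG-positive is ``active``; PI-positive
   events split on RSG into ``dead`` (RSG <= t_rsg), ``mid_active_1``
   (t_rsg < RSG < t_mid) and ``mid_active_2`` (RSG >= t_mid);
   double-negative events stay ``unclassified``.

Each event ends with exactly one label (partition property).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .classify import ClassifierModel, score_events
from .iodata import CELL_LABELS, LABELS, SchemaError


@dataclass
class GateConfig:
    """Thresholds for the gate chain.

    Intensity thresholds are in RFU on the raw scale; calibration works
    on log10 intensities (zeros floored at ``log_pseudocount``) and
    stores back raw-scale values.  ``t_mid`` (the mid-active I/II split
    on RSG among PI-positive events) is independent of ``t_rsg``.
    """

    gradient_rms_min: float = 30.0
    area_min_um2: float = 0.6
    area_max_um2: float = 1.6
    aspect_ratio_min: float = 0.85
    t_rsg: float = 20.0
    t_pi: float = 32.0
    t_mid: float = 340.0
    log_pseudocount: float = 1e-3
    classifier_path: str | None = None

    def __post_init__(self) -> None:
        if not self.area_min_um2 < self.area_max_um2:
            raise ValueError("area_min must be < area_max")
        for name in ("t_rsg", "t_pi", "t_mid"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        values = [
            self.gradient_rms_min,
            self.area_min_um2,
            self.area_max_um2,
            self.aspect_ratio_min,
            self.t_rsg,
            self.t_pi,
            self.t_mid,
        ]
        if not np.all(np.isfinite(values)):
            raise ValueError("gate thresholds must be finite")

    def as_dict(self) -> dict[str, float]:
        return {
            "gradient_rms_min": self.gradient_rms_min,
            "area_min_um2": self.area_min_um2,
            "area_max_um2": self.area_max_um2,
            "aspect_ratio_min": self.aspect_ratio_min,
            "t_rsg": self.t_rsg,
            "t_pi": self.t_pi,
            "t_mid": self.t_mid,
        }


def _require(table: pd.DataFrame, columns: Iterable[str]) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(f"event table lacks columns: {missing}")


def _unlabelled(table: pd.DataFrame) -> pd.Series:
    if "label" not in table.columns:
        table["label"] = "unclassified"
    return table["label"] == "unclassified"


def gate_focus(table: pd.DataFrame, config: GateConfig) -> pd.DataFrame:
    """Flag events with low brightfield sharpness as ``out_of_focus``."""
    _require(table, ["gradient_rms"])
    out = table.copy()
    open_ = _unlabelled(out)
    grad = out["gradient_rms"].to_numpy(dtype=float)
    flag = open_ & ((grad < config.gradient_rms_min) | ~np.isfinite(grad))
    out.loc[flag, "label"] = "out_of_focus"
    return out


def gate_singles(table: pd.DataFrame, config: GateConfig) -> pd.DataFrame:
    """Shape gate: flag aggregates (large/elongated) and small debris."""
    _require(table, ["area_um2", "aspect_ratio"])
    out = table.copy()
    open_ = _unlabelled(out)
    area = out["area_um2"].to_numpy(dtype=float)
    aspect = out["aspect_ratio"].to_numpy(dtype=float)
    undefined = ~(np.isfinite(area) & np.isfinite(aspect))
    is_aggregate = (area > config.area_max_um2) | (aspect < config.aspect_ratio_min)
    is_small = area < config.area_min_um2
    out.loc[open_ & ~undefined & is_aggregate, "label"] = "aggregate"
    out.loc[open_ & ~undefined & ~is_aggregate & is_small, "label"] = "debris"
    # undefined shape features cannot be gated; leave unclassified
    return out


def gate_cells(table: pd.DataFrame, model: ClassifierModel) -> pd.DataFrame:
    """Flag events the linear classifier scores as debris (score <= 0)."""
    out = score_events(model, table)
    open_ = _unlabelled(out)
    score = out["classifier_score"].to_numpy(dtype=float)
    out.loc[open_ & (score <= 0) & np.isfinite(score), "label"] = "debris"
    return out


def assign_subpopulations(table: pd.DataFrame, config: GateConfig) -> pd.DataFrame:
    """Assign surviving events to the four RSG/PI subpopulations."""
    _require(table, ["rsg_intensity", "pi_intensity"])
    out = table.copy()
    open_ = _unlabelled(out).to_numpy()
    rsg = out["rsg_intensity"].to_numpy(dtype=float)
    pi = out["pi_intensity"].to_numpy(dtype=float)

    pi_pos = pi > config.t_pi
    label = np.full(len(out), "unclassified", dtype=object)
    label[~pi_pos & (rsg > config.t_rsg)] = "active"
    label[pi_pos & (rsg <= config.t_rsg)] = "dead"
    label[pi_pos & (rsg > config.t_rsg) & (rsg < config.t_mid)] = "mid_active_1"
    label[pi_pos & (rsg >= config.t_mid) & (rsg > config.t_rsg)] = "mid_active_2"
    out.loc[open_, "label"] = label[open_]
    return out


@dataclass
class SubpopulationSummary:
    """Per-replicate and pooled subpopulation percentages.

    ``per_replicate`` has one row per (replicate, category) with counts
    and percentages; ``pooled`` aggregates all events; ``mean_sd`` holds
    the across-replicate mean and sample SD of each category's
    percentage (SD is NaN with fewer than two replicates).
    """

    denominator: str
    per_replicate: pd.DataFrame
    pooled: pd.DataFrame
    mean_sd: pd.DataFrame
    categories: tuple[str, ...] = field(default=LABELS)


def summarize(
    table: pd.DataFrame,
    denominator: str = "all_events",
    replicate_column: str = "replicate_id",
) -> SubpopulationSummary:
    """Summarize assigned labels as percentages per replicate and pooled.

    ``denominator="all_events"`` uses every acquired event, so the eight
    categories sum to 100%; ``"gated_cells"`` restricts both numerator
    and denominator to the four stained-cell subpopulations.
    """
    if denominator not in ("all_events", "gated_cells"):
        raise ValueError("denominator must be 'all_events' or 'gated_cells'")
    _require(table, ["label"])
    categories = LABELS if denominator == "all_events" else CELL_LABELS

    work = table.copy()
    if replicate_column not in work.columns:
        work[replicate_column] = 0

    def _tally(df: pd.DataFrame) -> pd.DataFrame:
        if denominator == "gated_cells":
            df = df[df["label"].isin(CELL_LABELS)]
        denom = len(df)
        rows = []
        for cat in categories:
            count = int((df["label"] == cat).sum())
            pct = 100.0 * count / denom if denom else float("nan")
            rows.append(dict(category=cat, count=count, percentage=pct))
        return pd.DataFrame(rows)

    per_rep = []
    for rep, df in work.groupby(replicate_column, sort=True):
        t = _tally(df)
        t.insert(0, replicate_column, rep)
        per_rep.append(t)
    per_replicate = pd.concat(per_rep, ignore_index=True)
    pooled = _tally(work)

    stats = (
        per_replicate.groupby("category", sort=False)["percentage"]
        .agg(["mean", "std", "count"])
        .reindex(categories)
        .reset_index()
        .rename(columns={"mean": "mean_pct", "std": "sd_pct", "count": "n_replicates"})
    )
    stats.loc[stats["n_replicates"] < 2, "sd_pct"] = np.nan
    return SubpopulationSummary(
        denominator=denominator,
        per_replicate=per_replicate,
        pooled=pooled,
        mean_sd=stats,
        categories=tuple(categories),
    )


def plot_gates(
    table: pd.DataFrame, config: GateConfig, path: str | None = None, ax=None
):
    """RSG x PI scatter (log10) with quadrant gate overlays."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    eps = config.log_pseudocount
    x = np.log10(np.maximum(table["rsg_intensity"], eps))
    y = np.log10(np.maximum(table["pi_intensity"], eps))
    palette = {
        "active": "tab:green",
        "mid_active_1": "tab:orange",
        "mid_active_2": "tab:olive",
        "dead": "tab:red",
    }
    labels = table.get("label", pd.Series("unclassified", index=table.index))
    for cat, color in palette.items():
        sel = labels == cat
        ax.scatter(x[sel], y[sel], s=4, alpha=0.4, color=color, label=cat)
    rest = ~labels.isin(palette)
    ax.scatter(x[rest], y[rest], s=4, alpha=0.2, color="lightgray", label="other")
    ax.axhline(np.log10(config.t_pi), color="k", lw=0.8)
    ax.axvline(np.log10(config.t_rsg), color="k", lw=0.8)
    ax.axvline(np.log10(config.t_mid), color="k", lw=0.8, ls="--")
    ax.set_xlabel("log10 RSG intensity [RFU]")
    ax.set_ylabel("log10 PI intensity [RFU]")
    ax.legend(markerscale=3, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
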