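"""Enumeration and reporting: obj/mL, plate-count estimates, growth tables.

Three comparison surfaces:

* cytometric concentrations (obj/mL) per subpopulation from gated event
  counts and the acquired volume;
* the classical plate-count estimate (cfu/mL) from a decimal dilution
  series under the 30-300 colonies-per-plate acceptance rule;
* post-sort growth percentage tables (percent of sorted single cells
  growing per subpopulation, medium and timepoint, 1-decimal rounding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gating import SubpopulationSummary
from .iodata import CELL_LABELS
from .presets import COLONY_COUNT_RANGE, OD600_GROWTH_THRESHOLD
from .synthetic_data import PlateSeries, SortingOutcome


@dataclass
class EnumerationResult:
    """Flow-cytometric enumeration of one sample (obj/mL)."""

    total_obj_per_ml: float
    per_subpopulation: dict[str, float]
    unclassified_obj_per_ml: float
    acquisition_volume_mL: float
    plate_cfu_per_ml: float | None = None
    plate_over_flow_total: float | None = None
    plate_over_flow_active: float | None = None
    note: str = ""


def flow_concentrations(
    summary: SubpopulationSummary, acquisition_volume_mL: float
) -> EnumerationResult:
    """Convert pooled gated event counts to concentrations (obj/mL)."""
    if not acquisition_volume_mL > 0:
        raise ValueError("acquisition volume must be > 0")
    pooled = summary.pooled.set_index("category")["count"]
    per_sub = {
        cat: float(pooled.get(cat, 0)) / acquisition_volume_mL for cat in CELL_LABELS
    }
    total = float(pooled.sum()) / acquisition_volume_mL
    unclassified = total - sum(per_sub.values())
    return EnumerationResult(
        total_obj_per_ml=total,
        per_subpopulation=per_sub,
        unclassified_obj_per_ml=unclassified,
        acquisition_volume_mL=acquisition_volume_mL,
        note="aggregates and debris excluded from subpopulation counts",
    )


def plate_count_estimate(
    series: PlateSeries,
    counting_range: tuple[int, int] = COLONY_COUNT_RANGE,
    weighting: str = "mean",
) -> float | None:
    """Estimate cfu/mL from qualifying plates of a dilution series.

    Only plates whose colony count lies within ``counting_range``
    (inclusive, default 30-300) qualify.  With several qualifying
    dilutions the per-plate estimates ``count / (10**exponent *
    volume)`` are averaged (``weighting="mean"``) or combined as a
    pooled count-weighted ratio (``weighting="count_weighted"``, the
    maximum-likelihood combination for Poisson counts).  Returns
    ``None`` when no plate qualifies.
    """
    lo, hi = counting_range
    counts = np.asarray(series.counts, dtype=float)
    exps = np.asarray(series.dilution_exponents, dtype=float)
    qualify = (counts >= lo) & (counts <= hi)
    if not qualify.any():
        return None
    factors = 10.0**exps * series.plated_volume_mL
    if weighting == "mean":
        return float(np.mean(counts[qualify] / factors[qualify]))
    if weighting == "count_weighted":
        return float(counts[qualify].sum() / factors[qualify].sum())
    raise ValueError("weighting must be 'mean' or 'count_weighted'")


def compare_counts(
    flow: EnumerationResult, plate_cfu_per_ml: float
) -> EnumerationResult:
    """Append plate/flow ratios to an enumeration result."""
    flow.plate_cfu_per_ml = plate_cfu_per_ml
    flow.plate_over_flow_total = (
        plate_cfu_per_ml / flow.total_obj_per_ml if flow.total_obj_per_ml else None
    )
    active = flow.per_subpopulation.get("active", 0.0)
    flow.plate_over_flow_active = plate_cfu_per_ml / active if active else None
    return flow


def comparison_table(results: dict[str, EnumerationResult]) -> pd.DataFrame:
    """Tabulate enumeration results, one row per sample."""
    rows = []
    for name, r in results.items():
        row = dict(
            sample=name,
            plate_cfu_per_ml=r.plate_cfu_per_ml,
            flow_total_obj_per_ml=r.total_obj_per_ml,
        )
        for cat in CELL_LABELS:
            row[f"flow_{cat}_obj_per_ml"] = r.per_subpopulation.get(cat)
        row["plate_over_flow_total"] = r.plate_over_flow_total
        rows.append(row)
    return pd.DataFrame(rows)


def growth_percentages(
    outcome: SortingOutcome, od_threshold: float = OD600_GROWTH_THRESHOLD
) -> pd.DataFrame:
    """Post-sort growth table: percent of sorted cells growing.

    One row per subpopulation x medium with 48 h and 72 h percentages
    rounded to one decimal (so every value is ``round(100 * k /
    n_sorted, 1)`` for an integer ``k``).  Broth growth is recomputed
    from the stored blank-subtracted OD600 readings against the
    threshold; agar growth uses the colony counts.
    """
    if outcome.n_sorted == 0:
        raise ValueError("n_sorted is zero; growth percentage undefined")
    n = outcome.n_sorted
    rows = []
    for grp in outcome.colonies_48h:
        rows.append(
            dict(
                subpopulation=grp,
                medium="agar",
                growth_pct_48h=round(100.0 * outcome.colonies_48h[grp] / n, 1),
                growth_pct_72h=round(100.0 * outcome.colonies_72h[grp] / n, 1),
            )
        )
        w48 = int((np.asarray(outcome.od600_48h[grp]) > od_threshold).sum())
        w72 = int((np.asarray(outcome.od600_72h[grp]) > od_threshold).sum())
        rows.append(
            dict(
                subpopulation=grp,
                medium="broth",
                growth_pct_48h=round(100.0 * w48 / n, 1),
                growth_pct_72h=round(100.0 * w72 / n, 1),
            )
        )
    return pd.DataFrame(rows)


def growth_table_from_counts(
    counts: dict[str, dict[str, tuple[int, int]]], n_sorted: int
) -> pd.DataFrame:
    """Growth table directly from ``{medium: {subpop: (k48, k72)}}`` counts."""
    if n_sorted == 0:
        raise ValueError("n_sorted is zero; growth percentage undefined")
    rows = []
    for medium, by_group in counts.items():
        for grp, (k48, k72) in by_group.items():
            rows.append(
                dict(
                    subpopulation=grp,
                    medium=medium,
                    growth_pct_48h=round(100.0 * k48 / n_sorted, 1),
                    growth_pct_72h=round(100.0 * k72 / n_sorted, 1),
                )
            )
    return pd.DataFrame(rows)
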