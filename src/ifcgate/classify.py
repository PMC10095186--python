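"""Linear cells-vs-debris event classifier trained from truth populations.

A small pair of manually tagged "truth" populations (about 31-32 events
per class) trains a Fisher linear discriminant on z-scored features.
The ``k`` features with the largest standardized absolute weight are
retained (default 7, mirroring the published seven-feature classifier)
and the discriminant refit on them.  The score offset is set so the
midpoint between the standardized class means scores exactly 0: events
scoring above zero belong to the classifier's positive class, ties are
left unclassified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .iodata import SchemaError


@dataclass
class TruthSet:
    """Two labelled event collections with identical feature columns."""

    class_a: pd.DataFrame  # e.g. cells
    class_b: pd.DataFrame  # e.g. debris
    name_a: str = "cells"
    name_b: str = "debris"

    def __post_init__(self) -> None:
        if len(self.class_a) < 2 or len(self.class_b) < 2:
            raise ValueError("each truth class needs at least 2 events")


@dataclass
class ClassifierModel:
    """Weighted linear score over standardized features.

    ``score = sum_i weight_i * (x_i - mean_i) / sd_i + offset``;
    events with score > 0 are assigned ``positive_class``.
    """

    feature_names: list[str]
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    offset: float
    positive_class: str = "cells"
    negative_class: str = "debris"
    threshold: float = 0.0  # decision threshold is fixed at zero

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        n = len(self.feature_names)
        if not (self.weights.size == self.means.size == self.sds.size == n):
            raise ValueError("weights/means/sds must match feature_names")
        if np.any(self.sds <= 0):
            raise ValueError("standardization SDs must be > 0")

    def save(self, path: str | Path) -> None:
        payload = dict(
            feature_names=list(self.feature_names),
            weights=[float(w) for w in self.weights],
            means=[float(m) for m in self.means],
            sds=[float(s) for s in self.sds],
            offset=float(self.offset),
            positive_class=self.positive_class,
            negative_class=self.negative_class,
        )
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            feature_names=list(payload["feature_names"]),
            weights=np.asarray(payload["weights"], dtype=float),
            means=np.asarray(payload["means"], dtype=float),
            sds=np.asarray(payload["sds"], dtype=float),
            offset=float(payload["offset"]),
            positive_class=payload.get("positive_class", "cells"),
            negative_class=payload.get("negative_class", "debris"),
        )


def _fisher_direction(
    za: np.ndarray, zb: np.ndarray, ridge: float = 1e-8
) -> np.ndarray:
    """Fisher discriminant direction on standardized data, ridge fallback."""
    ca = np.cov(za, rowvar=False, ddof=1)
    cb = np.cov(zb, rowvar=False, ddof=1)
    sw = np.atleast_2d((ca + cb) / 2.0)
    diff = za.mean(axis=0) - zb.mean(axis=0)
    reg = ridge * np.trace(sw) / sw.shape[0]
    try:
        w = np.linalg.solve(sw + reg * np.eye(sw.shape[0]), diff)
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular within-class scatter; increasing ridge regularization",
            stacklevel=2,
        )
        reg = 1e-2 * max(np.trace(sw) / sw.shape[0], 1.0)
        w = np.linalg.solve(sw + reg * np.eye(sw.shape[0]), diff)
    return np.atleast_1d(w)


def train_classifier(
    truth: TruthSet,
    candidate_features: Sequence[str],
    k: int = 7,
) -> ClassifierModel:
    """Train the linear classifier, keeping the ``k`` strongest features.

    Features are z-scored by the pooled training mean/SD; a Fisher
    discriminant is fit on all candidates, the ``k`` features with the
    largest ``|weight|`` retained, and the discriminant refit on them.
    The offset centers the score so the midpoint of the standardized
    class means scores zero; orientation is chosen so the first truth
    class (``truth.name_a``) scores positive.
    """
    candidates = list(candidate_features)
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds {len(candidates)} candidate features")
    missing = [
        c
        for c in candidates
        if c not in truth.class_a.columns or c not in truth.class_b.columns
    ]
    if missing:
        raise SchemaError(f"truth sets lack feature columns: {missing}")

    xa = truth.class_a[candidates].to_numpy(dtype=float)
    xb = truth.class_b[candidates].to_numpy(dtype=float)
    pooled = np.vstack([xa, xb])
    means = pooled.mean(axis=0)
    sds = pooled.std(axis=0, ddof=1)
    sds = np.where(sds > 0, sds, 1.0)
    za = (xa - means) / sds
    zb = (xb - means) / sds

    w_all = _fisher_direction(za, zb)
    order = np.argsort(-np.abs(w_all), kind="stable")[:k]
    order = np.sort(order)  # keep original feature order
    names = [candidates[i] for i in order]
    w = _fisher_direction(za[:, order], zb[:, order])

    mid = (za[:, order].mean(axis=0) + zb[:, order].mean(axis=0)) / 2.0
    offset = -float(w @ mid)
    # orient so class A scores positive
    if float(w @ za[:, order].mean(axis=0) + offset) < 0:
        w = -w
        offset = -offset
    return ClassifierModel(
        feature_names=names,
        weights=w,
        means=means[order],
        sds=sds[order],
        offset=offset,
        positive_class=truth.name_a,
        negative_class=truth.name_b,
    )


def score_events(
    model: ClassifierModel, table: pd.DataFrame, score_column: str = "classifier_score"
) -> pd.DataFrame:
    """Append the classifier score and class call to an event table.

    Events with any sentinel (NaN) model feature receive a NaN score and
    the call ``unclassified``; a score of exactly zero is likewise left
    unclassified.
    """
    missing = [c for c in model.feature_names if c not in table.columns]
    if missing:
        raise SchemaError(f"event table lacks model features: {missing}")
    x = table[model.feature_names].to_numpy(dtype=float)
    z = (x - model.means) / model.sds
    score = z @ model.weights + model.offset
    undefined = ~np.isfinite(x).all(axis=1)
    score[undefined] = np.nan

    out = table.copy()
    out[score_column] = score
    call = np.where(score > 0, model.positive_class, model.negative_class)
    call = np.where(np.isnan(score) | (score == 0), "unclassified", call)
    out[f"{score_column}_class"] = call
    return out
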