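"""Frozen-panel application to the independent validation cohort.

A fitted :class:`~capomics.panel.PanelModel` is applied to the validation
cohort with no refitting of any kind: samples route through the frozen tree,
per-marker AUCs use the score orientation fixed at training time (so an
anti-correlated marker can legitimately score below 0.5), and the combined
panel's ROC score is the tree's terminal-node class proportion for the
contrast's positive class. Bootstrap percentile intervals accompany the
combined AUC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .io import IntensityTable, align
from .panel import PAIRWISE_CONTRASTS, PanelModel, sensitivity_specificity

logger = logging.getLogger(__name__)


@dataclass
class PanelApplication:
    """Per-sample routing of a frozen panel over one cohort."""

    sample_ids: list[str]
    actual: np.ndarray
    predicted: np.ndarray
    class_scores: pd.DataFrame  # samples x classes terminal-node proportions
    marker_values: pd.DataFrame  # samples x markers (raw intensities)
    excluded: list[str]  # samples dropped for missing marker values


def apply_panel(
    panel: PanelModel,
    tables: Mapping[str, IntensityTable],
    metadata: pd.DataFrame,
    cohort: str | None = "validation",
) -> PanelApplication:
    """Route cohort samples through the frozen combined tree.

    Every panel marker must be present in its validation table (rejected by
    name otherwise); a sample missing any marker value is flagged, excluded
    from metrics, and logged.
    """
    markers = panel.selected_markers
    cols = []
    sample_ids: list[str] | None = None
    for layer, fid in markers:
        if layer not in tables:
            raise KeyError(f"panel layer {layer!r} missing from validation tables")
        table = tables[layer]
        if fid not in table.values.index:
            raise KeyError(f"panel marker {fid!r} missing from layer {layer!r}")
        sub = align(table, metadata, cohort=cohort)
        if sample_ids is None:
            sample_ids = sub.sample_ids
        cols.append(sub.values.loc[fid, sample_ids].to_numpy(dtype=float))
    X_all = np.column_stack(cols)
    complete = ~np.isnan(X_all).any(axis=1)
    excluded = [s for s, ok in zip(sample_ids, complete) if not ok]
    if excluded:
        logger.info(
            "excluding %d validation sample(s) with missing marker values: %s",
            len(excluded), excluded[:10],
        )
    kept = [s for s, ok in zip(sample_ids, complete) if ok]
    X = X_all[complete]
    meta = metadata.set_index("sample_id")
    actual = meta.loc[kept, "group"].to_numpy()

    # the combined tree consumes only its own split variables, in the
    # selected-marker order it was fitted with
    predicted = panel.tree.predict(X)
    proba = panel.tree.predict_proba(X)
    class_scores = pd.DataFrame(proba, index=kept, columns=list(panel.tree.classes_))
    marker_values = pd.DataFrame(X, index=kept, columns=[f for _, f in markers])
    return PanelApplication(
        sample_ids=kept,
        actual=actual,
        predicted=predicted,
        class_scores=class_scores,
        marker_values=marker_values,
        excluded=excluded,
    )


def _fixed_orientation_auc(scores: np.ndarray, y01: np.ndarray, orientation: str) -> float:
    s = scores if orientation != "lower_is_positive" else -scores
    return float(skm.roc_auc_score(y01, s))


@dataclass
class BootstrapCI:
    level: float
    lower: float
    upper: float
    replicates: int
    seed: int


def bootstrap_auc_ci(
    scores,
    labels,
    positive,
    level: float = 0.95,
    replicates: int = 2000,
    seed: int = 0,
) -> BootstrapCI:
    """Stratified nonparametric bootstrap percentile interval for an AUC.

    Resampling is stratified within each class so both classes persist in
    every replicate; the percentile interval brackets the fixed-orientation
    (higher-is-positive) AUC.
    """
    if replicates < 200:
        raise ValueError("need at least 200 bootstrap replicates")
    scores = np.asarray(scores, dtype=float)
    y01 = np.asarray([1 if v == positive else 0 for v in labels])
    pos_idx = np.where(y01 == 1)[0]
    neg_idx = np.where(y01 == 0)[0]
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB007]))
    vals = np.empty(replicates)
    for b in range(replicates):
        p = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        n = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.concatenate([p, n])
        vals[b] = _fixed_orientation_auc(scores[idx], y01[idx], "higher_is_positive")
    alpha = 1.0 - level
    lower, upper = np.quantile(vals, [alpha / 2.0, 1.0 - alpha / 2.0])
    return BootstrapCI(level, float(lower), float(upper), replicates, seed)


@dataclass
class ValidationResult:
    """Per-contrast validation metrics of a frozen panel."""

    contrast: tuple[str, str]
    per_marker_auc: dict[str, float]
    combined_auc: float
    sensitivity: float | None
    specificity: float | None
    n_positive: int
    n_negative: int
    ci: BootstrapCI | None = None

    def to_dict(self) -> dict[str, Any]:
        d = {
            "contrast": list(self.contrast),
            "per_marker_auc": self.per_marker_auc,
            "combined_auc": self.combined_auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }
        if self.ci is not None:
            d["combined_auc_ci"] = {
                "level": self.ci.level,
                "lower": self.ci.lower,
                "upper": self.ci.upper,
                "replicates": self.ci.replicates,
                "seed": self.ci.seed,
            }
        return d


def validate_panel(
    panel: PanelModel,
    tables: Mapping[str, IntensityTable],
    metadata: pd.DataFrame,
    cohort: str | None = "validation",
    bootstrap_replicates: int = 2000,
    seed: int = 0,
) -> tuple[list[ValidationResult], PanelApplication]:
    """Evaluate a frozen panel on every pairwise contrast of a cohort.

    Each contrast drops the third group's samples. Per-marker AUCs use the
    orientation frozen at training; the combined score is the tree's
    predicted class proportion for the contrast's positive class.
    """
    app = apply_panel(panel, tables, metadata, cohort=cohort)
    results = []
    for pos, neg in panel.contrasts:
        mask = np.isin(app.actual, [pos, neg])
        if mask.sum() == 0:
            warnings.warn(f"no samples for contrast {pos} vs {neg}", UserWarning)
            continue
        y = app.actual[mask]
        y01 = (y == pos).astype(int)
        if y01.sum() == 0 or y01.sum() == len(y01):
            warnings.warn(f"one class absent for contrast {pos} vs {neg}", UserWarning)
            continue
        per_marker = {}
        key = f"{pos}_vs_{neg}"
        for _, fid in panel.selected_markers:
            orientation = panel.orientations.get(fid, {}).get(key, "higher_is_positive")
            per_marker[fid] = _fixed_orientation_auc(
                app.marker_values.loc[mask, fid].to_numpy(), y01, orientation
            )
        combined_scores = app.class_scores.loc[mask, pos].to_numpy()
        combined = float(skm.roc_auc_score(y01, combined_scores))
        ss = sensitivity_specificity(app.predicted[mask], y, positive=pos)
        ci = bootstrap_auc_ci(
            combined_scores, y, positive=pos,
            replicates=bootstrap_replicates, seed=seed,
        )
        results.append(ValidationResult(
            contrast=(pos, neg),
            per_marker_auc=per_marker,
            combined_auc=combined,
            sensitivity=ss.sensitivity,
            specificity=ss.specificity,
            n_positive=int(y01.sum()),
            n_negative=int(len(y01) - y01.sum()),
            ci=ci,
        ))
    return results, app
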