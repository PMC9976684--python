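"""Biomarker panel discovery: ROC ranking, CART trees, classifier comparison.

The pipeline ranks candidate features by pairwise ROC AUC, filters them on
fold-change and AUC floors (optionally requiring an immunity / infection /
death-related annotation), builds one classification tree per omics layer to
select that layer's markers, combines the selected markers in a final tree
with a terminal-node cap, and benchmarks the frozen panel features with five
standard classifiers under stratified tenfold cross-validation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import KNNImputer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .io import GROUPS, IntensityTable, align
from .tree import GiniTreeClassifier

logger = logging.getLogger(__name__)

PAIRWISE_CONTRASTS = (("NS_CAP", "CON"), ("S_CAP", "CON"), ("S_CAP", "NS_CAP"))


@dataclass
class RocCurve:
    """An ROC curve with its trapezoidal AUC and score orientation."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    orientation: str  # higher_is_positive | lower_is_positive


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[Any],
    positive: Any,
    orientation: str = "auto",
) -> RocCurve:
    """ROC curve and AUC for one score vector.

    The AUC equals the probability a positive outranks a negative with ties
    counted half (the normalized Mann-Whitney statistic). ``orientation``:
    ``"higher_is_positive"``, ``"lower_is_positive"``, or ``"auto"`` which
    flips the score sign when the raw AUC falls below 0.5 and records the
    flip.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if v == positive else 0 for v in labels])
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present to compute an ROC curve")
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN; remove missing values first")

    def curve(s: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        fpr, tpr, thr = skm.roc_curve(y, s)
        return thr, tpr, fpr, float(skm.auc(fpr, tpr))

    if orientation == "auto":
        thr, tpr, fpr, a = curve(scores)
        if a < 0.5:
            thr, tpr, fpr, a = curve(-scores)
            return RocCurve(-thr, tpr, fpr, a, "lower_is_positive")
        return RocCurve(thr, tpr, fpr, a, "higher_is_positive")
    if orientation == "higher_is_positive":
        thr, tpr, fpr, a = curve(scores)
        return RocCurve(thr, tpr, fpr, a, orientation)
    if orientation == "lower_is_positive":
        thr, tpr, fpr, a = curve(-scores)
        return RocCurve(-thr, tpr, fpr, a, orientation)
    raise ValueError(f"unknown orientation {orientation!r}")


def feature_aucs(
    table: IntensityTable,
    metadata: pd.DataFrame,
    contrasts: Sequence[tuple[str, str]] = PAIRWISE_CONTRASTS,
    cohort: str | None = None,
    feature_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-feature pairwise AUCs on the more-severe-is-positive convention.

    For each contrast (positive group, negative group), missing values are
    dropped pairwise and the AUC is computed with automatic orientation.
    Returns a DataFrame with one ``auc_<pos>_vs_<neg>`` and
    ``orient_<pos>_vs_<neg>`` column per contrast plus ``max_auc``.
    """
    ids = list(feature_ids) if feature_ids is not None else table.feature_ids
    out = pd.DataFrame(index=pd.Index(ids, name="feature_id"))
    max_auc = np.zeros(len(ids))
    for pos, neg in contrasts:
        sub = align(table, metadata, groups=[pos, neg], cohort=cohort)
        meta = metadata.set_index("sample_id")
        y = meta.loc[sub.sample_ids, "group"].to_numpy()
        vals = sub.values.loc[ids].to_numpy()
        aucs = np.full(len(ids), np.nan)
        orients = np.full(len(ids), "", dtype=object)
        for i in range(len(ids)):
            row = vals[i]
            ok = ~np.isnan(row)
            yy = y[ok]
            if (yy == pos).sum() == 0 or (yy == neg).sum() == 0:
                continue
            rc = roc_auc(row[ok], yy, positive=pos, orientation="auto")
            aucs[i] = rc.auc
            orients[i] = rc.orientation
        name = f"{pos}_vs_{neg}"
        out[f"auc_{name}"] = aucs
        out[f"orient_{name}"] = orients
        max_auc = np.fmax(max_auc, np.nan_to_num(aucs))
    out["max_auc"] = max_auc
    return out


def filter_candidates(
    records: pd.DataFrame,
    aucs: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    min_auc: float = 0.8,
    min_fc: float = 1.5,
    require_annotation: bool = False,
) -> pd.DataFrame:
    """Rank biomarker candidates by AUC with FC and annotation gates.

    ``records`` holds one or more stacked :func:`call_differential` frames for
    the layer (the per-feature maximum |log2 FC| over contrasts is used).
    Candidates must reach ``max_auc >= min_auc`` and
    ``max |log2 fc| >= log2(min_fc)``; with ``require_annotation`` they must
    also carry at least one immunity / infection / death-related flag.
    Ranking: AUC descending, ties by |log2 fc| descending, then feature id.
    """
    abs_l2fc = records["log2fc"].abs().groupby(level=0).max()
    cand = pd.DataFrame({"max_auc": aucs["max_auc"]})
    cand["max_abs_log2fc"] = abs_l2fc.reindex(cand.index)
    cand = cand.dropna()
    cand = cand[
        (cand["max_auc"] >= min_auc)
        & (cand["max_abs_log2fc"] >= math.log2(min_fc))
    ]
    if require_annotation:
        if annotations is None:
            raise ValueError("require_annotation set but no annotations given")
        ann = annotations.set_index("feature_id")["flags"]
        flagged = cand.index.map(lambda f: len(ann.get(f, frozenset())) > 0)
        cand = cand[np.asarray(flagged, dtype=bool)]
    if cand.empty:
        warnings.warn("no candidates pass the filters", UserWarning)
    cand = cand.reset_index().rename(columns={"index": "feature_id"})
    cand["feature_id"] = cand["feature_id"].astype(str)
    cand = cand.sort_values(
        by=["max_auc", "max_abs_log2fc", "feature_id"],
        ascending=[False, False, True],
    ).set_index("feature_id")
    return cand


def _marker_matrix(
    tables: Mapping[str, IntensityTable],
    metadata: pd.DataFrame,
    markers: Sequence[tuple[str, str]],
    cohort: str | None = None,
    impute: bool = True,
    medians: Mapping[tuple[str, str], float] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str], dict[tuple[str, str], float], np.ndarray]:
    """Samples x markers matrix plus labels.

    Missing cells are kNN-imputed (k=5, log scale) from samples with a
    similar marker profile, so an imputed value stays on its group's side of
    a between-group gap instead of collapsing to a global center. Returns
    (X, y, sample_ids, per-marker training medians kept for provenance,
    row mask of samples that were complete before imputation).
    """
    cols = []
    sample_ids: list[str] | None = None
    for layer, fid in markers:
        table = tables[layer]
        if fid not in table.values.index:
            raise KeyError(f"marker {fid!r} missing from layer {layer!r}")
        sub = align(table, metadata, cohort=cohort)
        if sample_ids is None:
            sample_ids = sub.sample_ids
        cols.append(sub.values.loc[fid, sample_ids].to_numpy(dtype=float))
    X = np.column_stack(cols)
    complete = ~np.isnan(X).any(axis=1)
    med = dict(medians) if medians is not None else {
        m: float(np.nanmedian(X[:, j])) for j, m in enumerate(markers)
    }
    if impute and not complete.all():
        if X.shape[1] > 1:
            imputer = KNNImputer(n_neighbors=min(5, max(1, int(complete.sum()) - 1)))
            with np.errstate(invalid="ignore"):
                X = np.exp(imputer.fit_transform(np.log(X)))
        for j, m in enumerate(markers):  # fallback for rows kNN cannot reach
            col = X[:, j]
            col[np.isnan(col)] = med[m]
    meta = metadata.set_index("sample_id")
    y = meta.loc[sample_ids, "group"].to_numpy()
    return X, y, sample_ids, med, complete


@dataclass
class PanelModel:
    """A frozen multi-omics marker panel and its combined classification tree.

    ``markers`` are exactly the split variables of the combined tree;
    ``selected_markers`` is the (possibly larger) union of the per-layer
    selections the tree was built on. ``orientations`` record each marker's
    training-time score direction per contrast, frozen for validation.
    """

    markers: list[tuple[str, str]]
    selected_markers: list[tuple[str, str]]
    tree: GiniTreeClassifier
    orientations: dict[str, dict[str, str]]
    training_medians: dict[str, float]
    training_performance: dict[str, dict[str, float]]
    contrasts: tuple[tuple[str, str], ...] = PAIRWISE_CONTRASTS
    seed: int = 0
    config: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "markers": [list(m) for m in self.markers],
            "selected_markers": [list(m) for m in self.selected_markers],
            "tree": self.tree.to_dict(),
            "orientations": self.orientations,
            "training_medians": self.training_medians,
            "training_performance": self.training_performance,
            "contrasts": [list(c) for c in self.contrasts],
            "seed": self.seed,
            "config": self.config,
        }


@dataclass
class SensSpec:
    sensitivity: float | None
    specificity: float | None
    undefined: tuple[str, ...] = ()


def sensitivity_specificity(predicted, actual, positive) -> SensSpec:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP).

    Predictions other than the positive class count as negative calls. A rate
    with an empty denominator is returned as None and named in ``undefined``
    rather than propagating NaN.
    """
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if len(predicted) == 0 or len(predicted) != len(actual):
        raise ValueError("predicted and actual must be equal-length and non-empty")
    pos_pred = predicted == positive
    pos_act = actual == positive
    tp = int((pos_pred & pos_act).sum())
    fn = int((~pos_pred & pos_act).sum())
    tn = int((~pos_pred & ~pos_act).sum())
    fp = int((pos_pred & ~pos_act).sum())
    undefined = []
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    if sens is None:
        undefined.append("sensitivity")
    if spec is None:
        undefined.append("specificity")
    return SensSpec(sens, spec, tuple(undefined))


def select_panel(
    protein_candidates: Sequence[str],
    metabolite_candidates: Sequence[str],
    tables: Mapping[str, IntensityTable],
    metadata: pd.DataFrame,
    layer_budgets: tuple[int, int] = (2, 3),
    combined_max_terminal_nodes: int = 6,
    min_leaf: int = 2,
    cohort: str | None = "train",
    seed: int = 0,
) -> PanelModel:
    """Two-stage panel selection: per-layer trees, then a combined tree.

    Stage 1 builds a classification tree per layer on that layer's candidate
    features (3-class labels); the split variables actually used, shallowest
    first and capped by the layer budget, become the layer's selection.
    Stage 2 fits the combined tree on the union of selections with the
    terminal-node cap. The panel's ``markers`` are the combined tree's split
    variables; if the tree uses fewer markers than were selected the panel
    shrinks (logged) but the selection is retained for provenance.
    """
    layer_inputs = {
        "protein": (list(protein_candidates), layer_budgets[0]),
        "metabolite": (list(metabolite_candidates), layer_budgets[1]),
    }
    selected: list[tuple[str, str]] = []
    for layer, (cands, budget) in layer_inputs.items():
        if not cands:
            raise ValueError(f"no candidates supplied for layer {layer!r}")
        markers = [(layer, f) for f in cands]
        X, y, _, _, _ = _marker_matrix(tables, metadata, markers, cohort=cohort)
        t = GiniTreeClassifier(
            max_leaf_nodes=budget + 1, min_samples_leaf=min_leaf
        ).fit(X, y, feature_names=cands)
        used = [cands[j] for j in t.split_features()][:budget]
        logger.info("layer %s tree selected: %s", layer, used)
        selected.extend((layer, f) for f in used)

    X, y, _, medians, _ = _marker_matrix(tables, metadata, selected, cohort=cohort)
    names = [f for _, f in selected]
    combined = GiniTreeClassifier(
        max_leaf_nodes=combined_max_terminal_nodes, min_samples_leaf=min_leaf
    ).fit(X, y, feature_names=names)
    used_idx = combined.split_features()
    markers = [selected[j] for j in used_idx]
    if len(markers) < len(selected):
        logger.info(
            "combined tree uses %d of %d selected markers; panel shrinks to %s",
            len(markers), len(selected), [f for _, f in markers],
        )

    # freeze per-marker orientations from training AUCs
    orientations: dict[str, dict[str, str]] = {}
    for layer, fid in selected:
        aucs = feature_aucs(
            tables[layer], metadata, cohort=cohort, feature_ids=[fid]
        )
        orientations[fid] = {
            f"{pos}_vs_{neg}": str(aucs[f"orient_{pos}_vs_{neg}"].iloc[0])
            for pos, neg in PAIRWISE_CONTRASTS
        }

    # training-set sensitivity/specificity per pairwise contrast
    pred = combined.predict(X)
    performance: dict[str, dict[str, float]] = {}
    for pos, neg in PAIRWISE_CONTRASTS:
        mask = np.isin(y, [pos, neg])
        ss = sensitivity_specificity(pred[mask], y[mask], positive=pos)
        performance[f"{pos}_vs_{neg}"] = {
            "sensitivity": ss.sensitivity,
            "specificity": ss.specificity,
        }

    return PanelModel(
        markers=markers,
        selected_markers=selected,
        tree=combined,
        orientations=orientations,
        training_medians={f: medians[(l, f)] for l, f in selected},
        training_performance=performance,
        seed=seed,
        config={
            "layer_budgets": list(layer_budgets),
            "combined_max_terminal_nodes": combined_max_terminal_nodes,
            "min_leaf": min_leaf,
        },
    )


CLASSIFIERS = (
    "logistic_regression",
    "random_forest",
    "linear_svm",
    "knn",
    "decision_tree",
)


def _make_classifier(name: str, seed: int):
    # hyperparameters fixed and recorded: L2 logistic regression (C=1),
    # 100-tree random forest, linear-kernel SVM (C=1), k=5 neighbors,
    # unconstrained Gini decision tree; scale-sensitive models are wrapped
    # in a per-fold standard scaler
    if name == "logistic_regression":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(C=1.0, max_iter=2000, random_state=seed)),
        ])
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "linear_svm":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", LinearSVC(C=1.0, max_iter=10000, random_state=seed)),
        ])
    if name == "knn":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", KNeighborsClassifier(n_neighbors=5)),
        ])
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


def compare_classifiers(
    X,
    y,
    folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Five-classifier accuracy comparison on identical stratified folds.

    Returns one row per classifier with the per-fold accuracies, their mean,
    and error rate = 1 - mean accuracy. A fold whose training split misses a
    class triggers a reseeded refold (warned).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_classes = len(np.unique(y))
    min_class = int(min(np.sum(y == cls) for cls in np.unique(y)))
    if folds > min_class:
        warnings.warn(
            f"folds={folds} exceeds smallest class ({min_class}); reduced", UserWarning
        )
        folds = min_class
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        splits = list(skf.split(X, y))
        if all(len(np.unique(y[tr])) == n_classes for tr, _ in splits):
            break
        warnings.warn("degenerate fold (training split missing a class); refolding", UserWarning)
    rows = []
    for name in CLASSIFIERS:
        accs = []
        for tr, te in splits:
            clf = _make_classifier(name, seed)
            clf.fit(X[tr], y[tr])
            accs.append(float(skm.accuracy_score(y[te], clf.predict(X[te]))))
        mean_acc = float(np.mean(accs))
        rows.append({
            "classifier": name,
            "fold_accuracies": accs,
            "mean_accuracy": mean_acc,
            "error_rate": 1.0 - mean_acc,
            "seed": seed,
        })
    return pd.DataFrame(rows)
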