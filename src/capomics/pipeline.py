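"""End-to-end orchestration: simulate/ingest -> differential -> PLS-DA ->
trend clustering -> panel discovery -> independent validation -> enrichment
-> report.

The training/validation separation is structural: every training stage
receives a view of the tables restricted to the training cohort, the panel is
frozen before any validation-cohort access, and a config that points a
training stage at the validation cohort is refused (leakage guard). Reports
are deterministic: the same config always yields a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import differential as de
from . import simulate as sim
from .cluster import FuzzyCMeans, assign_trend_labels, group_mean_profiles
from .enrich import over_representation
from .io import IntensityTable, align, read_gmt, read_metadata, validate_metadata
from .panel import (
    PAIRWISE_CONTRASTS,
    compare_classifiers,
    feature_aucs,
    filter_candidates,
    select_panel,
)
from .plsda import PLSDiscriminant, cross_validated_q2
from .validate import validate_panel

logger = logging.getLogger(__name__)


class LeakageError(RuntimeError):
    """A training stage attempted to touch validation-cohort samples."""


@dataclass
class PipelineConfig:
    """Flat configuration driving every stage; round-trips through YAML.

    Either ``input_tables``/``input_metadata`` point at files, or the
    built-in simulator generates the default two-cohort study from
    ``simulation`` overrides.
    """

    outdir: str | None = None
    input_tables: dict[str, str] | None = None  # layer -> TSV path
    input_metadata: str | None = None
    simulation: dict[str, Any] = field(default_factory=dict)
    train_cohort: str = "train"
    validation_cohort: str = "validation"
    # differential stage
    fc_up: float = 1.5
    fc_down: float = 0.67
    alpha: float = 0.05
    gate: str = "p"
    log_transform: bool = False
    # PLS-DA stage
    plsda_components: int = 2
    plsda_folds: int = 10
    plsda_layer: str = "metabolite"
    # trend clustering stage
    cluster_layer: str = "protein"
    cluster_k: int = 4
    cluster_m: float = 1.25
    membership_floor: float = 0.5
    trend_slack: float = 0.1
    # panel stage
    min_auc: dict[str, float] = field(
        default_factory=lambda: {"protein": 0.8, "metabolite": 0.9}
    )
    max_candidates: dict[str, int] = field(
        default_factory=lambda: {"protein": 9, "metabolite": 4}
    )
    layer_budgets: tuple[int, int] = (2, 3)
    combined_max_terminal_nodes: int = 6
    cv_folds: int = 10
    # validation stage
    bootstrap_replicates: int = 2000
    # enrichment stage
    gmt_path: str | None = None
    enrichment_layer: str = "protein"
    # seeds per stochastic stage
    seeds: dict[str, int] = field(
        default_factory=lambda: {
            "simulate": 0, "plsda": 0, "cluster": 0, "panel": 0, "validate": 0,
        }
    )

    def __post_init__(self) -> None:
        self.layer_budgets = tuple(self.layer_budgets)  # YAML gives a list
        for stage in ("simulate", "plsda", "cluster", "panel", "validate"):
            if stage not in self.seeds:
                raise ValueError(f"missing seed for stochastic stage {stage!r}")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["layer_budgets"] = list(self.layer_budgets)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        return cls(**dict(d))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Re-derive every stage seed from one master seed."""
        d = self.to_dict()
        d["seeds"] = {
            stage: int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
            for i, stage in enumerate(("simulate", "plsda", "cluster", "panel", "validate"))
        }
        return PipelineConfig.from_dict(d)


def _load_or_simulate(config: PipelineConfig):
    if config.input_tables:
        if not config.input_metadata:
            raise ValueError("input_tables given without input_metadata")
        tables = {
            layer: IntensityTable.read_tsv(path, layer)
            for layer, path in config.input_tables.items()
        }
        metadata = read_metadata(config.input_metadata)
        return tables, metadata, None
    overrides = dict(config.simulation)
    overrides["seed"] = config.seeds["simulate"]
    design = sim.CohortDesign(**overrides)
    tables, metadata, truth = sim.generate_cohort(design)
    couplings = sim.default_clinical_couplings(truth)
    metadata = sim.generate_clinical_indices(
        metadata, tables, couplings, seed=config.seeds["simulate"]
    )
    return tables, metadata, truth


def training_view(
    tables: Mapping[str, IntensityTable],
    metadata: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[dict[str, IntensityTable], pd.DataFrame]:
    """Leakage guard: a view of the data containing only training samples.

    Refuses a config whose training cohort is anything but ``"train"`` and
    verifies that no validation sample survives in the view.
    """
    if config.train_cohort != "train":
        raise LeakageError(
            f"leakage guard: training stages must use cohort 'train', "
            f"config requests {config.train_cohort!r}"
        )
    meta_train = metadata[metadata["cohort"] == "train"].reset_index(drop=True)
    out = {}
    for layer, table in tables.items():
        view = align(table, metadata, cohort="train")
        bad = set(view.sample_ids) & set(
            metadata.loc[metadata["cohort"] == "validation", "sample_id"]
        )
        if bad:
            raise LeakageError(f"leakage guard: validation sample(s) in training view: {sorted(bad)[:5]}")
        out[layer] = view
    return out, meta_train


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage in order on one config and return the report document.

    Intermediates (per-contrast differential TSVs, panel JSON, the report)
    are written under ``config.outdir`` when set; partial outputs survive a
    stage failure.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config": config.to_dict()}

    tables, metadata, truth = _load_or_simulate(config)
    validate_metadata(metadata)
    report["cohort"] = {
        cohort: {
            group: int(((metadata["cohort"] == cohort) & (metadata["group"] == group)).sum())
            for group in sorted(metadata["group"].unique())
        }
        for cohort in sorted(metadata["cohort"].unique())
    }
    train_tables, meta_train = training_view(tables, metadata, config)
    if outdir and truth is not None:
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        metadata.to_csv(outdir / "metadata.csv", index=False)
        for layer, table in tables.items():
            table.to_tsv(outdir / f"{layer}.tsv")

    # --- differential abundance on the training cohort ---------------------
    records: dict[str, dict[str, pd.DataFrame]] = {}
    diff_section: dict[str, Any] = {}
    for layer, table in train_tables.items():
        records[layer] = {}
        layer_section = {}
        for pos, neg in PAIRWISE_CONTRASTS:
            rec = de.call_differential(
                table, meta_train, (pos, neg),
                fc_up=config.fc_up, fc_down=config.fc_down,
                alpha=config.alpha, gate=config.gate,
                log_transform=config.log_transform,
            )
            name = f"{pos}_vs_{neg}"
            records[layer][name] = rec
            layer_section[name] = {
                "up": int((rec["status"] == "up").sum()),
                "down": int((rec["status"] == "down").sum()),
                "untestable": int((~rec["testable"]).sum()),
            }
            if outdir:
                rec.to_csv(outdir / f"diffexp_{layer}_{name}.tsv", sep="\t")
        venn = de.venn_partition(records[layer])
        layer_section["venn"] = {
            "regions": venn.regions,
            "set_sizes": venn.set_sizes,
            "union": venn.union_size,
            "triple_overlap": venn.triple_overlap,
        }
        diff_section[layer] = layer_section
    report["differential"] = diff_section

    # --- PLS-DA per pairwise contrast ---------------------------------------
    plsda_section: dict[str, Any] = {}
    layer = config.plsda_layer
    for pos, neg in PAIRWISE_CONTRASTS:
        sub = align(train_tables[layer], meta_train, groups=[pos, neg])
        meta_idx = meta_train.set_index("sample_id")
        y = meta_idx.loc[sub.sample_ids, "group"].to_numpy()
        X = sub.values.to_numpy().T
        X = np.where(np.isnan(X), np.nanmean(X, axis=0, keepdims=True), X)
        model = PLSDiscriminant(n_components=config.plsda_components).fit(X, y)
        q2 = cross_validated_q2(
            X, y, n_components=model.n_components_,
            n_splits=config.plsda_folds, seed=config.seeds["plsda"],
        )
        plsda_section[f"{pos}_vs_{neg}"] = {
            "layer": layer,
            "r2x_cum": [round(float(v), 6) for v in model.r2x_cum_],
            "r2y_cum": [round(float(v), 6) for v in model.r2y_cum_],
            "q2_cum": [round(float(v), 6) for v in q2],
        }
    report["plsda"] = plsda_section

    # --- trend clustering of differential features --------------------------
    layer = config.cluster_layer
    sig = sorted(
        set().union(*(
            set(rec.index[rec["status"] != "ns"])
            for rec in records[layer].values()
        ))
    )
    cluster_section: dict[str, Any] = {"layer": layer, "n_differential": len(sig)}
    if len(sig) > config.cluster_k:
        profiles, excluded = group_mean_profiles(
            train_tables[layer], meta_train, feature_ids=sig
        )
        fcm = FuzzyCMeans(
            n_clusters=config.cluster_k, m=config.cluster_m,
            random_state=config.seeds["cluster"],
        ).fit(profiles.to_numpy())
        labels, center_labels = assign_trend_labels(
            fcm, profiles,
            membership_floor=config.membership_floor, slack=config.trend_slack,
        )
        cluster_section["excluded_constant"] = len(excluded)
        cluster_section["cluster_centers"] = {
            str(j): [round(float(v), 6) for v in fcm.cluster_centers_[j]]
            for j in range(config.cluster_k)
        }
        cluster_section["cluster_trends"] = {str(j): v for j, v in center_labels.items()}
        cluster_section["label_counts"] = {
            k: int(v) for k, v in labels.value_counts().sort_index().items()
        }
        if outdir:
            pd.DataFrame(
                fcm.membership_, index=profiles.index,
                columns=[f"cluster_{j}" for j in range(config.cluster_k)],
            ).to_csv(outdir / f"memberships_{layer}.tsv", sep="\t")
    else:
        cluster_section["status"] = "absent: too few differential features"
    report["trend_clusters"] = cluster_section

    # --- panel discovery -----------------------------------------------------
    stacked = {
        layer: pd.concat(list(recs.values()))
        for layer, recs in records.items()
    }
    aucs = {
        layer: feature_aucs(train_tables[layer], meta_train)
        for layer in train_tables
    }
    candidates = {}
    for layer in ("protein", "metabolite"):
        cand = filter_candidates(
            stacked[layer], aucs[layer],
            min_auc=config.min_auc.get(layer, 0.8), min_fc=config.fc_up,
        )
        candidates[layer] = list(cand.index[: config.max_candidates.get(layer, len(cand))])
    panel = select_panel(
        candidates["protein"], candidates["metabolite"],
        train_tables, meta_train,
        layer_budgets=config.layer_budgets,
        combined_max_terminal_nodes=config.combined_max_terminal_nodes,
        seed=config.seeds["panel"],
    )
    report["panel"] = {
        "candidates": candidates,
        "model": panel.to_dict(),
    }
    if outdir:
        (outdir / "panel.json").write_text(json.dumps(panel.to_dict(), indent=2, sort_keys=True))

    # --- classifier comparison on the frozen panel features ------------------
    from .panel import _marker_matrix  # shared matrix assembly

    Xp, yp, _, _, _ = _marker_matrix(train_tables, meta_train, panel.selected_markers)
    cv = compare_classifiers(Xp, yp, folds=config.cv_folds, seed=config.seeds["panel"])
    report["classifier_cv"] = [
        {
            "classifier": row["classifier"],
            "mean_accuracy": round(float(row["mean_accuracy"]), 6),
            "error_rate": round(float(row["error_rate"]), 6),
        }
        for _, row in cv.iterrows()
    ]

    # --- independent validation ----------------------------------------------
    has_validation = (metadata["cohort"] == "validation").any()
    if has_validation:
        results, app = validate_panel(
            panel, tables, metadata, cohort="validation",
            bootstrap_replicates=config.bootstrap_replicates,
            seed=config.seeds["validate"],
        )
        report["validation"] = {
            "excluded_samples": app.excluded,
            "contrasts": {f"{r.contrast[0]}_vs_{r.contrast[1]}": r.to_dict() for r in results},
        }
    else:
        report["validation"] = {"status": "absent: no validation cohort"}

    # --- enrichment ------------------------------------------------------------
    layer = config.enrichment_layer
    if config.gmt_path:
        collection = read_gmt(config.gmt_path)
    elif truth is not None:
        collection = sim.truth_gene_sets(truth, layer=layer)
    else:
        collection = None
    if collection is not None and len(collection):
        any_rec = next(iter(records[layer].values()))
        background = set(any_rec.index[any_rec["testable"]])
        query = set().union(*(
            set(rec.index[rec["status"] != "ns"]) for rec in records[layer].values()
        )) & background
        enr = over_representation(query, collection, background) if query else pd.DataFrame()
        report["enrichment"] = {
            "layer": layer,
            "n_query": len(query),
            "n_background": len(background),
            "top": [
                {k: (round(v, 8) if isinstance(v, float) else v) for k, v in row.items()}
                for row in enr.head(20).to_dict(orient="records")
            ],
        }
        if outdir:
            enr.to_csv(outdir / f"enrichment_{layer}.tsv", sep="\t", index=False)
    else:
        report["enrichment"] = {"status": "absent: no gene sets supplied"}

    if outdir:
        write_report(report, outdir / "report.json")
    return report


def write_report(report: Mapping[str, Any], path: str | Path) -> None:
    """Serialize a report deterministically (sorted keys, no timestamps)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def report_summary(report: Mapping[str, Any]) -> str:
    """A short human-readable view of a report document."""
    lines = []
    cohort = report.get("cohort", {})
    for name, groups in cohort.items():
        total = sum(groups.values())
        parts = ", ".join(f"{g}: {n}" for g, n in groups.items())
        lines.append(f"cohort {name}: {total} samples ({parts})")
    for layer, sec in report.get("differential", {}).items():
        venn = sec.get("venn", {})
        lines.append(
            f"{layer}: union of differential features {venn.get('union')} "
            f"(triple overlap {venn.get('triple_overlap')})"
        )
    for contrast, sec in report.get("plsda", {}).items():
        lines.append(
            f"PLS-DA {contrast}: cumulative R2Y {sec['r2y_cum'][-1]:.2f}, "
            f"Q2 {sec['q2_cum'][-1]:.2f}"
        )
    panel = report.get("panel", {}).get("model", {})
    if panel:
        markers = ", ".join(f"{l}:{f}" for l, f in panel.get("markers", []))
        lines.append(f"panel markers: {markers}")
    val = report.get("validation", {}).get("contrasts", {})
    for contrast, sec in val.items():
        pct = 100.0 * sec["combined_auc"]
        lines.append(f"validation {contrast}: combined AUC {pct:.1f}%")
    return "\n".join(lines)
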