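"""Synthetic serum multi-omics cohorts with planted group effects.

Real pediatric-pneumonia serum cohorts are not publicly deposited, so this
module generates cohorts with the same structure: three diagnostic groups
(healthy controls CON, non-severe NS_CAP, severe S_CAP), a training cohort of
15/15/20 and an independent validation cohort of 37/39/53, a protein layer of
hundreds of features and a metabolite layer of thousands, log-normal
intensities with planted group-dependent fold changes, trend patterns across
CON -> NS_CAP -> S_CAP, and missing values. Every planted effect is recorded
in a truth table so downstream stages can be scored against ground truth.

Intensities are multiplicative (log-normal): a feature's value in a sample of
group g is ``exp(mu_f + log FC_g + eps)`` with ``eps ~ Normal(0, base_log_sd)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GROUPS, GeneSetCollection, IntensityTable, validate_metadata

logger = logging.getLogger(__name__)

PATTERNS = ("increasing", "decreasing", "inverted_V", "flat")


@dataclass
class CohortDesign:
    """Sizes, noise, and missingness of a simulated two-cohort study.

    Defaults mirror the study conditions the pipeline targets: training
    groups CON/NS_CAP/S_CAP = 15/15/20, validation groups = 37/39/53,
    500 protein and 2500 metabolite features, natural-log baseline mean 14
    (median intensity ~1.2e6, a typical MS1 scale), per-feature baseline
    spread 1.5, within-group log-sd 0.35, and 5% missing completely at
    random.
    """

    group_sizes: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            "train": {"CON": 15, "NS_CAP": 15, "S_CAP": 20},
            "validation": {"CON": 37, "NS_CAP": 39, "S_CAP": 53},
        }
    )
    n_features: dict[str, int] = field(
        default_factory=lambda: {"protein": 500, "metabolite": 2500}
    )
    base_log_mean: float = 14.0
    feature_log_mean_sd: float = 1.5
    base_log_sd: float = 0.35
    missing_rate: float = 0.05
    intensity_dependent_missing: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for cohort, sizes in self.group_sizes.items():
            for group, n in sizes.items():
                if group not in GROUPS:
                    raise ValueError(f"unknown group {group!r} in cohort {cohort!r}")
                if n < 2:
                    raise ValueError(
                        f"group size must be >= 2 (Welch t needs within-group "
                        f"variance); got {n} for {group!r} in {cohort!r}"
                    )
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError(f"missing_rate must be in [0, 1); got {self.missing_rate}")
        if self.base_log_sd <= 0:
            raise ValueError("base_log_sd must be positive")
        for layer, n in self.n_features.items():
            if n < 1:
                raise ValueError(f"n_features[{layer!r}] must be positive")


@dataclass(frozen=True)
class PlantedEffect:
    """A feature's group-dependent fold changes relative to CON."""

    feature_id: str
    layer: str
    pattern: str
    fc_ns_vs_con: float = 1.0
    fc_s_vs_con: float = 1.0
    is_panel_marker: bool = False

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; allowed: {PATTERNS}")
        ns, s = self.fc_ns_vs_con, self.fc_s_vs_con
        if ns <= 0 or s <= 0:
            raise ValueError(f"{self.feature_id}: fold changes must be positive")
        if self.pattern == "flat" and not (ns == 1.0 and s == 1.0):
            raise ValueError(f"{self.feature_id}: flat pattern requires both FCs = 1")
        if self.pattern == "increasing" and not (s >= ns > 1.0):
            raise ValueError(
                f"{self.feature_id}: increasing requires fc_s >= fc_ns > 1"
            )
        if self.pattern == "decreasing" and not (s <= ns < 1.0):
            raise ValueError(
                f"{self.feature_id}: decreasing requires fc_s <= fc_ns < 1"
            )
        if self.pattern == "inverted_V" and not (ns > 1.0 and s < ns):
            raise ValueError(
                f"{self.feature_id}: inverted_V requires fc_ns > 1 and fc_s < fc_ns"
            )


def default_effects(design: CohortDesign | None = None) -> list[PlantedEffect]:
    """The default planted-signal layout: ~10% non-flat features per layer.

    Non-flat features are split evenly across four trend patterns (two
    increasing variants with distinct shapes, one decreasing, one inverted-V)
    with moderate fold changes (<= 2). Five panel markers (2 protein,
    3 metabolite) carry large effects (peak FC 3-5) with complementary
    patterns, so a multi-marker rule is needed to resolve all three group
    contrasts.
    """
    design = design or CohortDesign()
    effects: list[PlantedEffect] = []
    pattern_fcs = {
        "increasing_early": ("increasing", 1.8, 2.0),
        "increasing_late": ("increasing", 1.3, 2.0),
        "decreasing": ("decreasing", 0.6, 0.5),
        "inverted_V": ("inverted_V", 2.0, 0.9),
    }
    # each pairwise contrast is covered by at least one marker whose log
    # fold change is ~4x the within-group log-sd, so a multi-marker rule can
    # approach complete three-class separation at n=50
    panel = {
        "protein": [
            ("increasing", 1.2, 5.0),  # severity marker: up mainly in S_CAP
            ("increasing", 4.0, 4.5),  # infection marker: up in any CAP
        ],
        "metabolite": [
            ("decreasing", 0.25, 0.20),
            ("inverted_V", 4.0, 0.95),
            ("increasing", 2.5, 5.0),
        ],
    }
    for layer, n in design.n_features.items():
        min_needed = 4 + len(panel.get(layer, []))
        if n < min_needed:
            raise ValueError(
                f"layer {layer!r} needs >= {min_needed} features for the "
                f"default planted layout; got {n}"
            )
        prefix = layer[0].upper()
        width = len(str(n))
        ids = [f"{prefix}{i + 1:0{width}d}" for i in range(n)]
        n_signal = max(4, int(round(0.10 * n)))
        per_pattern = n_signal // 4
        pos = 0
        for _, (pattern, fc_ns, fc_s) in pattern_fcs.items():
            for _ in range(per_pattern):
                effects.append(
                    PlantedEffect(ids[pos], layer, pattern, fc_ns, fc_s)
                )
                pos += 1
        for pattern, fc_ns, fc_s in panel.get(layer, []):
            effects.append(
                PlantedEffect(ids[pos], layer, pattern, fc_ns, fc_s, is_panel_marker=True)
            )
            pos += 1
        for fid in ids[pos:]:
            effects.append(PlantedEffect(fid, layer, "flat"))
    return effects


def _sample_ids(cohort: str, group: str, n: int) -> list[str]:
    tag = {"train": "T", "validation": "V"}[cohort]
    g = group.replace("_", "")
    return [f"{tag}_{g}_{i + 1:02d}" for i in range(n)]


def generate_cohort(
    design: CohortDesign,
    effects: Sequence[PlantedEffect] | None = None,
) -> tuple[dict[str, IntensityTable], pd.DataFrame, pd.DataFrame]:
    """Simulate both cohorts of a study.

    Returns
    -------
    tables : dict layer -> IntensityTable
        Intensity matrices covering training and validation samples.
    metadata : DataFrame
        Columns sample_id, group, cohort.
    truth : DataFrame
        One row per planted effect (including flat features).
    """
    if effects is None:
        effects = default_effects(design)
    by_layer: dict[str, list[PlantedEffect]] = {}
    for e in effects:
        if e.layer not in design.n_features:
            raise ValueError(f"effect {e.feature_id!r} references unknown layer {e.layer!r}")
        seen = by_layer.setdefault(e.layer, [])
        if any(prev.feature_id == e.feature_id for prev in seen):
            raise ValueError(f"duplicate feature id {e.feature_id!r} in layer {e.layer!r}")
        seen.append(e)

    meta_rows = []
    for cohort in ("train", "validation"):
        for group in GROUPS:
            n = design.group_sizes.get(cohort, {}).get(group, 0)
            for sid in _sample_ids(cohort, group, n):
                meta_rows.append({"sample_id": sid, "group": group, "cohort": cohort})
    metadata = validate_metadata(pd.DataFrame(meta_rows))

    # independent, reproducible substreams per layer
    root = np.random.SeedSequence(design.seed)
    layer_seeds = {layer: ss for layer, ss in zip(sorted(by_layer), root.spawn(len(by_layer)))}

    group_vec = metadata["group"].to_numpy()
    shift_cols = {g: i for i, g in enumerate(GROUPS)}
    tables: dict[str, IntensityTable] = {}
    truth_rows = []
    for layer in sorted(by_layer):
        layer_effects = by_layer[layer]
        rng = np.random.default_rng(layer_seeds[layer])
        n_feat, n_samp = len(layer_effects), len(metadata)
        baselines = design.base_log_mean + design.feature_log_mean_sd * rng.standard_normal(n_feat)
        shifts = np.zeros((n_feat, len(GROUPS)))
        for i, e in enumerate(layer_effects):
            shifts[i, shift_cols["NS_CAP"]] = math.log(e.fc_ns_vs_con)
            shifts[i, shift_cols["S_CAP"]] = math.log(e.fc_s_vs_con)
        col_shift = np.array([shift_cols[g] for g in group_vec])
        log_means = baselines[:, None] + shifts[:, col_shift]
        log_vals = log_means + design.base_log_sd * rng.standard_normal((n_feat, n_samp))
        values = np.exp(log_vals)
        if design.missing_rate > 0:
            if design.intensity_dependent_missing:
                # logistic in centered log intensity: low-abundance cells drop more
                z = (log_vals - log_vals.mean()) / max(log_vals.std(), 1e-12)
                prob = design.missing_rate * 2.0 / (1.0 + np.exp(2.0 * z))
                mask = rng.random((n_feat, n_samp)) < prob
            else:
                mask = rng.random((n_feat, n_samp)) < design.missing_rate
            values = np.where(mask, np.nan, values)
        df = pd.DataFrame(
            values,
            index=[e.feature_id for e in layer_effects],
            columns=metadata["sample_id"].to_numpy(),
        )
        tables[layer] = IntensityTable(layer, df)
        for e in layer_effects:
            truth_rows.append(asdict(e))
        logger.info(
            "simulated layer %s: %d features x %d samples (%.1f%% missing)",
            layer, n_feat, n_samp, 100 * float(np.isnan(values).mean()),
        )
    truth = pd.DataFrame(truth_rows)
    return tables, metadata, truth


@dataclass(frozen=True)
class ClinicalCoupling:
    """How a clinical index tracks a source feature.

    ``rho`` is the target Spearman correlation between the index and the
    (log) source feature; its sign sets the direction. ``offset``/``scale``
    place the index on a plausible clinical unit scale.
    """

    layer: str
    feature_id: str
    rho: float
    offset: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.rho <= 1.0) or self.rho == 0.0:
            raise ValueError("rho must be nonzero and in [-1, 1]")


def default_clinical_couplings(truth: pd.DataFrame) -> dict[str, ClinicalCoupling]:
    """Couple PCIS, TT, FIB, FDP to planted severity/platelet-like markers.

    PCIS (pediatric critical illness score) falls with severity, so it is
    negatively coupled to the strongest severity-increasing protein;
    thrombin time rises and fibrinogen falls with severity; FDP tracks a
    degradation-product-like increasing metabolite.
    """
    prot = truth[(truth["layer"] == "protein") & truth["is_panel_marker"]]
    metab = truth[(truth["layer"] == "metabolite") & truth["is_panel_marker"]]
    inc_prot = prot.sort_values("fc_s_vs_con", ascending=False)["feature_id"].iloc[0]
    dec = truth[(truth["layer"] == "protein") & (truth["pattern"] == "decreasing")]
    dec_prot = dec["feature_id"].iloc[0] if len(dec) else inc_prot
    inc_metab = metab.sort_values("fc_s_vs_con", ascending=False)["feature_id"].iloc[0]
    return {
        "PCIS": ClinicalCoupling("protein", inc_prot, rho=-0.6, offset=90.0, scale=-6.0),
        "TT": ClinicalCoupling("protein", inc_prot, rho=0.6, offset=18.0, scale=2.0),
        "FIB": ClinicalCoupling("protein", dec_prot, rho=0.6, offset=3.0, scale=0.8),
        "FDP": ClinicalCoupling("metabolite", inc_metab, rho=0.6, offset=4.0, scale=2.5),
    }


def _pearson_for_spearman(rho_s: float) -> float:
    """Bivariate-normal Pearson correlation with the given Spearman rho."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def generate_clinical_indices(
    metadata: pd.DataFrame,
    tables: Mapping[str, IntensityTable],
    couplings: Mapping[str, ClinicalCoupling],
    seed: int = 0,
) -> pd.DataFrame:
    """Append clinical-index columns correlated with source features.

    Each index is a linear transform of the source feature's standardized
    log intensity plus Gaussian noise sized so the population Spearman
    correlation equals the coupling's ``rho`` (via the bivariate-normal
    relation rho_pearson = 2 sin(pi rho_s / 6)). ``rho = +/-1`` gives a
    noise-free monotone transform.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x10D1CE5]))
    out = metadata.copy()
    for name in sorted(couplings):
        c = couplings[name]
        if c.layer not in tables:
            raise ValueError(f"index {name!r}: unknown layer {c.layer!r}")
        table = tables[c.layer]
        if c.feature_id not in table.values.index:
            raise ValueError(f"index {name!r}: unknown source feature {c.feature_id!r}")
        vals = table.values.loc[c.feature_id].reindex(out["sample_id"]).to_numpy()
        logv = np.log(np.where(np.isnan(vals), np.nanmean(vals), vals))
        z = (logv - logv.mean()) / max(logv.std(), 1e-12)
        r = _pearson_for_spearman(abs(c.rho))
        sigma = math.sqrt(max(1.0 / r**2 - 1.0, 0.0)) if r < 1.0 else 0.0
        signal = z if c.rho > 0 else -z
        index = signal + sigma * rng.standard_normal(len(z))
        out[name] = c.offset + c.scale * index
    return validate_metadata(out)


def truth_gene_sets(truth: pd.DataFrame, layer: str = "protein") -> GeneSetCollection:
    """Gene sets grouping each layer's planted trend patterns (for ORA demos)."""
    sets = {}
    sub = truth[truth["layer"] == layer]
    for pattern in ("increasing", "decreasing", "inverted_V"):
        members = tuple(sub.loc[sub["pattern"] == pattern, "feature_id"])
        if members:
            sets[f"planted_{pattern}"] = (f"features planted with a {pattern} trend", members)
    n_flat = int((sub["pattern"] == "flat").sum())
    if n_flat:
        members = tuple(sub.loc[sub["pattern"] == "flat", "feature_id"][: max(5, n_flat // 10)])
        sets["flat_decoy"] = ("a decoy set of flat features", members)
    return GeneSetCollection(sets)


def two_group_design(
    n_x: int = 20,
    n_y: int = 15,
    n_up: int = 100,
    n_down: int = 100,
    n_flat: int = 800,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    base_log_sd: float = 0.35,
    missing_rate: float = 0.0,
    seed: int = 7,
) -> tuple[CohortDesign, list[PlantedEffect]]:
    """A single-layer two-group benchmark design for differential calling.

    Group x is S_CAP (size ``n_x``), group y is CON (size ``n_y``); up/down
    features are planted via the S_CAP-vs-CON fold change.
    """
    n = n_up + n_down + n_flat
    design = CohortDesign(
        group_sizes={"train": {"CON": n_y, "NS_CAP": 2, "S_CAP": n_x}},
        n_features={"protein": n},
        base_log_sd=base_log_sd,
        missing_rate=missing_rate,
        seed=seed,
    )
    width = len(str(n))
    ids = [f"P{i + 1:0{width}d}" for i in range(n)]
    effects = []
    for i, fid in enumerate(ids):
        if i < n_up:
            effects.append(PlantedEffect(fid, "protein", "increasing", fc_up, fc_up))
        elif i < n_up + n_down:
            effects.append(PlantedEffect(fid, "protein", "decreasing", fc_down, fc_down))
        else:
            effects.append(PlantedEffect(fid, "protein", "flat"))
    return design, effects
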