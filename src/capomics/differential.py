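"""Fold-change / Welch-t / BH-FDR differential abundance calling.

For each pairwise group contrast, a feature's fold change is the ratio of raw
group-mean intensities, significance comes from a two-sided unpaired Welch t
test, and p-values are BH-adjusted across all testable features of the layer.
A feature is called up when FC > 1.5 and p < 0.05, down when FC < 0.67 and
p < 0.05 (strict inequalities); the raw p gates the call by default, with the
BH q reported alongside (``gate="q"`` switches the rule).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import IntensityTable, align

logger = logging.getLogger(__name__)

DEFAULT_CONTRASTS = (("NS_CAP", "CON"), ("S_CAP", "CON"), ("S_CAP", "NS_CAP"))


class UntestableError(ValueError):
    """A sample pair cannot support a Welch t test."""


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Two-sided unpaired Welch t test.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom.
    Raises :class:`UntestableError` instead of propagating NaN when either
    sample has fewer than two values or both have zero spread with equal
    means undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise UntestableError(f"need >= 2 values per group, got {len(x)} and {len(y)}")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        raise UntestableError("zero spread in both groups")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    table: IntensityTable,
    metadata: pd.DataFrame,
    contrast: tuple[str, str],
    fc_up: float = 1.5,
    fc_down: float = 0.67,
    alpha: float = 0.05,
    gate: str = "p",
    log_transform: bool = False,
    min_per_group: int = 2,
    cohort: str | None = None,
) -> pd.DataFrame:
    """Call differential features for one pairwise contrast.

    Parameters
    ----------
    contrast : (numerator group, denominator group)
        E.g. ``("S_CAP", "CON")``: FC = mean(S_CAP) / mean(CON).
    gate : {"p", "q"}
        Which adjusted/unadjusted p gates the up/down call; q is always
        reported.
    log_transform : bool
        Apply the Welch t on log2 intensities instead of raw values (fold
        changes always use raw group means).

    Returns
    -------
    DataFrame indexed by feature id with columns mean_num, mean_den, fc,
    log2fc, t_stat, df, p, q, status and a ``testable`` flag; untestable
    features carry NaN statistics, status ``"ns"``, and a reason in
    ``skip_reason``.
    """
    num, den = contrast
    if num == den:
        raise ValueError("contrast groups must differ")
    if gate not in ("p", "q"):
        raise ValueError("gate must be 'p' or 'q'")
    sub_num = align(table, metadata, groups=[num], cohort=cohort)
    sub_den = align(table, metadata, groups=[den], cohort=cohort)
    xn = sub_num.values.to_numpy()
    xd = sub_den.values.to_numpy()

    import warnings as _warnings

    with _warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
        _warnings.filterwarnings("ignore", message="Mean of empty slice")
        _warnings.filterwarnings("ignore", message="Degrees of freedom <= 0")
        mean_num = np.nanmean(xn, axis=1)
        mean_den = np.nanmean(xd, axis=1)
        fc = mean_num / mean_den
        tn, td = (np.log2(xn), np.log2(xd)) if log_transform else (xn, xd)
        n_num = np.sum(~np.isnan(tn), axis=1)
        n_den = np.sum(~np.isnan(td), axis=1)
        var_num = np.nanvar(tn, axis=1, ddof=1)
        var_den = np.nanvar(td, axis=1, ddof=1)
    testable = (n_num >= max(2, min_per_group)) & (n_den >= max(2, min_per_group))
    zero_spread = testable & (var_num == 0) & (var_den == 0)
    testable &= ~zero_spread

    t_stat = np.full(len(fc), np.nan)
    df = np.full(len(fc), np.nan)
    p = np.full(len(fc), np.nan)
    if testable.any():
        res = stats.ttest_ind(
            tn[testable], td[testable], axis=1, equal_var=False, nan_policy="omit"
        )
        t_stat[testable] = res.statistic
        df[testable] = res.df
        p[testable] = res.pvalue
    q = np.full(len(fc), np.nan)
    if testable.any():
        q[testable] = bh_fdr(p[testable])

    gate_val = p if gate == "p" else q
    status = np.full(len(fc), "ns", dtype=object)
    up = testable & (fc > fc_up) & (gate_val < alpha)
    down = testable & (fc < fc_down) & (gate_val < alpha)
    status[up] = "up"
    status[down] = "down"

    reason = np.full(len(fc), "", dtype=object)
    reason[~testable & ~zero_spread] = "fewer than 2 present values in a group"
    reason[zero_spread] = "zero spread in both groups"
    n_skip = int((~testable).sum())
    if n_skip:
        logger.info(
            "contrast %s vs %s (%s): skipped %d untestable feature(s)",
            num, den, table.layer, n_skip,
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        log2fc = np.log2(fc)
    return pd.DataFrame(
        {
            "mean_num": mean_num,
            "mean_den": mean_den,
            "fc": fc,
            "log2fc": log2fc,
            "t_stat": t_stat,
            "df": df,
            "p": p,
            "q": q,
            "status": status,
            "testable": testable,
            "skip_reason": reason,
        },
        index=pd.Index(table.feature_ids, name="feature_id"),
    )


@dataclass
class VennPartition:
    """Disjoint region counts of three significant-feature sets.

    Region keys are 3-bit strings over (NS_vs_CON, S_vs_CON, S_vs_NS):
    e.g. ``"110"`` counts features significant in the first two contrasts
    only; ``"111"`` is the triple overlap.
    """

    contrast_names: tuple[str, str, str]
    regions: dict[str, int]
    set_sizes: dict[str, int]

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())

    @property
    def triple_overlap(self) -> int:
        return self.regions["111"]


def venn_partition(
    records: Mapping[str, pd.DataFrame] | Mapping[str, Iterable[str]],
) -> VennPartition:
    """Partition three contrasts' significant features into 7 disjoint regions.

    ``records`` maps exactly three contrast names either to
    :func:`call_differential` frames (significant = status != ``"ns"``) or
    directly to feature-id collections. Record frames must share a feature
    universe (same layer).
    """
    if len(records) != 3:
        raise ValueError(f"expected exactly 3 contrasts, got {len(records)}")
    names = tuple(records)
    sets: list[frozenset[str]] = []
    universes: list[frozenset[str]] = []
    for name in names:
        rec = records[name]
        if isinstance(rec, pd.DataFrame):
            sets.append(frozenset(rec.index[rec["status"] != "ns"]))
            universes.append(frozenset(rec.index))
        else:
            sets.append(frozenset(rec))
    if universes and len(set(universes)) > 1:
        raise ValueError("contrasts cover different feature universes (mixed layers?)")
    a, b, c = sets
    union = a | b | c
    regions = {}
    for bits in ("100", "010", "001", "110", "101", "011", "111"):
        sel = set(union)
        for bit, s in zip(bits, (a, b, c)):
            sel &= s if bit == "1" else (union - s)
        regions[bits] = len(sel)
    return VennPartition(
        contrast_names=names,
        regions=regions,
        set_sizes={n: len(s) for n, s in zip(names, sets)},
    )


def spearman_clinical(
    table: IntensityTable,
    metadata: pd.DataFrame,
    feature_ids: Sequence[str],
    index_names: Sequence[str],
    min_pairs: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spearman correlation of feature intensities with clinical indices.

    Missing values are removed pairwise; a pair with fewer than ``min_pairs``
    joint observations is marked untestable (NaN rho and p). Returns
    (rho, p, n_pairs) DataFrames indexed by feature, columns by index name.
    """
    meta = metadata.set_index("sample_id")
    samples = [s for s in table.sample_ids if s in meta.index]
    rho = pd.DataFrame(index=pd.Index(feature_ids, name="feature_id"), columns=index_names, dtype=float)
    pval = rho.copy()
    npairs = pd.DataFrame(0, index=rho.index, columns=index_names, dtype=int)
    for fid in feature_ids:
        if fid not in table.values.index:
            raise KeyError(f"unknown feature {fid!r}")
        x_all = table.values.loc[fid, samples].to_numpy(dtype=float)
        for name in index_names:
            if name not in meta.columns:
                raise KeyError(f"unknown clinical index {name!r}")
            y_all = meta.loc[samples, name].to_numpy(dtype=float)
            ok = ~np.isnan(x_all) & ~np.isnan(y_all)
            npairs.loc[fid, name] = int(ok.sum())
            if ok.sum() < min_pairs:
                continue
            r, p = stats.spearmanr(x_all[ok], y_all[ok])
            rho.loc[fid, name] = float(r)
            pval.loc[fid, name] = float(p)
    return rho, pval, npairs
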