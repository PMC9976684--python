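"""Hypergeometric over-representation analysis against gene-set collections.

Database-agnostic: any GMT collection can be tested against a query of
differential features. The background defaults to all testable features of
the layer (not a genome); sets are intersected with the background before
testing, the p-value is the one-sided hypergeometric upper tail P(X >= k),
and q-values are BH-adjusted across tested sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_fdr
from .io import GeneSetCollection

logger = logging.getLogger(__name__)


def over_representation(
    query: set | list,
    collection: GeneSetCollection,
    background: set | list,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a query set in each gene set.

    Parameters
    ----------
    query : feature ids of interest (must be a subset of the background)
    collection : gene sets; members outside the background are ignored
    background : the feature universe N

    Returns
    -------
    DataFrame sorted by p (stable tie order by set name) with columns
    set_name, description, k (overlap), K (set size in background), n (query
    size), N (background size), p, q.
    """
    background = set(map(str, background))
    query = set(map(str, query))
    if not background:
        raise ValueError("background is empty")
    if not query:
        raise ValueError("query is empty")
    stray = query - background
    if stray:
        raise ValueError(
            f"query contains {len(stray)} feature(s) outside the background, "
            f"e.g. {sorted(stray)[:3]}"
        )
    N = len(background)
    n = len(query)
    rows = []
    for name in sorted(collection.sets):
        desc, members = collection.sets[name]
        in_bg = set(members) & background
        K = len(in_bg)
        if K == 0:
            logger.info("set %r has no members in the background; skipped", name)
            continue
        k = len(in_bg & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "set_name": name, "description": desc,
            "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0),
        })
    if not rows:
        return pd.DataFrame(
            columns=["set_name", "description", "k", "K", "n", "N", "p", "q"]
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out = out.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)
    return out
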