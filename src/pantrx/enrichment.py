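"""Preranked gene-set enrichment (weighted Kolmogorov-Smirnov running sum).

Genes are ranked by a score (abundance, dispersion or log2 fold change);
the enrichment score of a set is the maximum deviation of the running-sum
statistic with hit increments weighted by |score|**weight.  The null is
built by drawing random gene-label sets of matching size; p-values compare
the observed ES against null scores of the same sign (with a +1
pseudocount) and NES divides ES by the mean |null ES| of that sign, so a
calibrated null ranking yields uniform p-values.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["preranked_gsea", "enrichment_score"]


def _es_from_positions(pos: np.ndarray, weights: np.ndarray, n: int):
    """ES for hit positions in a ranked list (vectorized over rows).

    ``pos`` is (n_rows, k) of 0-based positions, ``weights`` the
    |score|**w vector over the whole ranking.  Returns (es, peak_index)
    where peak_index is the hit index attaining the extreme (row-wise).
    """
    pos = np.sort(pos, axis=1)
    k = pos.shape[1]
    w = weights[pos]
    nr = w.sum(axis=1, keepdims=True)
    zero = nr[:, 0] == 0
    if zero.any():  # all-zero scores in the set: hits contribute equally
        w = w.copy()
        w[zero] = 1.0
        nr = w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) / nr
    miss_denom = max(n - k, 1)
    i = np.arange(k)
    # deviation just after each hit, and just before each hit
    after = cum - (pos - i) / miss_denom
    before = np.concatenate(
        [np.zeros((pos.shape[0], 1)), cum[:, :-1]], axis=1
    ) - (pos - i) / miss_denom
    hi = after.max(axis=1)
    lo = before.min(axis=1)
    es = np.where(hi >= -lo, hi, lo)
    peak = np.where(hi >= -lo, after.argmax(axis=1), before.argmin(axis=1))
    return es, peak


def enrichment_score(ranking: pd.Series, gene_set: Iterable, weight: float = 1.0):
    """Observed ES and leading-edge genes for one set.

    ``ranking`` maps gene -> score; genes are ranked by decreasing score.
    """
    order = ranking.sort_values(ascending=False, kind="mergesort")
    genes = order.index.to_numpy()
    weights = np.abs(order.to_numpy(dtype=float)) ** weight
    idx = {g: i for i, g in enumerate(genes)}
    members = [g for g in gene_set if g in idx]
    if not members:
        raise ValueError("gene set has no overlap with the ranking")
    pos = np.array([[idx[g] for g in members]])
    es, peak = _es_from_positions(pos, weights, len(genes))
    sorted_pos = np.sort(pos[0])
    if es[0] >= 0:
        leading = [genes[p] for p in sorted_pos[: peak[0] + 1]]
    else:
        leading = [genes[p] for p in sorted_pos[peak[0] :]]
    return float(es[0]), leading


def preranked_gsea(
    ranking: pd.Series,
    sets: Mapping[str, Iterable],
    n_perm: int = 1000,
    min_size: int = 5,
    max_size: int = 500,
    weight: float = 1.0,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Preranked GSEA over a collection of gene sets.

    Sets are intersected with the ranking universe; sets outside
    [min_size, max_size] after intersection are skipped (reported with
    status ``skipped_size`` / ``skipped_overlap``).  The null for each set
    draws ``n_perm`` random same-size gene subsets.  Deterministic for a
    fixed seed.
    """
    if ranking.index.duplicated().any():
        raise ValueError("ranking has duplicate gene ids")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    order = ranking.sort_values(ascending=False, kind="mergesort")
    genes = order.index.to_numpy()
    n = len(genes)
    weights = np.abs(order.to_numpy(dtype=float)) ** weight
    idx = {g: i for i, g in enumerate(genes)}

    rows = []
    null_cache: Dict[int, np.ndarray] = {}
    for name, members in sets.items():
        overlap = [g for g in members if g in idx]
        k = len(overlap)
        if k == 0:
            rows.append({"set": name, "size": 0, "status": "skipped_overlap"})
            continue
        if not (min_size <= k <= max_size):
            rows.append({"set": name, "size": k, "status": "skipped_size"})
            continue
        pos = np.array([[idx[g] for g in overlap]])
        es_obs, peak = _es_from_positions(pos, weights, n)
        es_obs = float(es_obs[0])
        if k not in null_cache:
            perm_pos = np.argsort(
                rng.random((n_perm, n)), axis=1
            )[:, :k]  # random k-subsets without replacement
            null_cache[k], _ = _es_from_positions(perm_pos, weights, n)
        null = null_cache[k]
        if es_obs >= 0:
            same = null[null >= 0]
            extreme = int((same >= es_obs).sum())
        else:
            same = null[null < 0]
            extreme = int((same <= es_obs).sum())
        p = (1.0 + extreme) / (1.0 + len(same))
        denom = np.abs(same).mean() if len(same) else np.nan
        nes = es_obs / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        sorted_pos = np.sort(pos[0])
        if es_obs >= 0:
            leading = [genes[p_] for p_ in sorted_pos[: peak[0] + 1]]
        else:
            leading = [genes[p_] for p_ in sorted_pos[peak[0] :]]
        rows.append(
            {
                "set": name,
                "size": k,
                "status": "tested",
                "ES": es_obs,
                "NES": nes,
                "p": p,
                "leading_edge": ",".join(map(str, leading)),
            }
        )
    result = pd.DataFrame(rows)
    tested = result["status"] == "tested" if len(result) else pd.Series(dtype=bool)
    if tested.any():
        result.loc[tested, "padj"] = multipletests(
            result.loc[tested, "p"], method="fdr_bh"
        )[1]
    return result
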