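"""Allele-specific expression with a mapping-bias-aware binomial null.

Heterozygous sites carry reference/alternative read counts; the
alternative allele ratio AAR = alt / (ref + alt) is tested for imbalance
with an exact two-sided binomial test.  Residual reference-ward mapping
bias is absorbed by setting the null probability to the mean AAR over all
retained sites rather than 0.5.  The filter chain keeps mappable sites
with coverage > 29, AAR not in {0, 1} (heterozygosity supported), inside
coding sequences, and optionally with genetic allele balance in
[0.33, 0.66] to exclude copy-number-distorted sites.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["compute_aar", "filter_sites", "ase_test", "ab_filtration_sweep"]


def compute_aar(sites: pd.DataFrame) -> pd.DataFrame:
    """Add coverage and AAR columns; drop zero-coverage sites.

    Sites with AAR exactly 0 or 1 are flagged ``aar_supported = False``
    (their heterozygosity is not supported by expression).
    """
    out = sites.copy()
    out["coverage"] = out["ref_count"] + out["alt_count"]
    n_zero = int((out["coverage"] == 0).sum())
    if n_zero:
        logger.warning("dropping %d zero-coverage sites", n_zero)
        out = out[out["coverage"] > 0].copy()
    out["AAR"] = out["alt_count"] / out["coverage"]
    out["aar_supported"] = (out["AAR"] > 0) & (out["AAR"] < 1)
    return out


def filter_sites(
    sites: pd.DataFrame,
    min_coverage_exclusive: int = 29,
    ab_bounds: Sequence[float] | None = (0.33, 0.66),
    require_coding: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Apply the ASE filter chain; returns (survivors, attrition report).

    Rules are applied in order: mappability -> AAR support -> coverage
    strictly greater than ``min_coverage_exclusive`` -> coding sequence ->
    genetic allele balance within ``ab_bounds`` inclusive (skipped when
    None).  The attrition report counts removals per rule.
    """
    if "AAR" not in sites.columns:
        sites = compute_aar(sites)
    report = {}
    current = sites
    if "mappable" in current.columns:
        keep = current["mappable"].astype(bool)
        report["mappability"] = int((~keep).sum())
        current = current[keep]
    else:
        report["mappability"] = 0
    keep = current["aar_supported"]
    report["aar_support"] = int((~keep).sum())
    current = current[keep]
    keep = current["coverage"] > min_coverage_exclusive
    report["coverage"] = int((~keep).sum())
    current = current[keep]
    if require_coding and "gene_id" in current.columns:
        keep = current["gene_id"].notna() & (current["gene_id"] != "")
        report["coding"] = int((~keep).sum())
        current = current[keep]
    else:
        report["coding"] = 0
    if ab_bounds is not None and "genetic_AB" in current.columns:
        lo, hi = ab_bounds
        keep = (current["genetic_AB"] >= lo) & (current["genetic_AB"] <= hi)
        report["allele_balance"] = int((~keep).sum())
        current = current[keep]
    else:
        report["allele_balance"] = 0
    report["retained"] = len(current)
    return current.copy(), pd.Series(report, name="n_removed")


def _binom_p_two_sided(k: np.ndarray, n: np.ndarray, p0: float) -> np.ndarray:
    """Exact two-sided binomial p by the minimum-likelihood method, i.e. the
    sum of the probabilities of all outcomes no more likely than the
    observed one (scipy's binomtest convention), vectorized over sites."""
    out = np.empty(len(k), dtype=float)
    cache: dict[int, np.ndarray] = {}
    for i, (ki, ni) in enumerate(zip(k, n)):
        pmf = cache.get(ni)
        if pmf is None:
            pmf = stats.binom.pmf(np.arange(ni + 1), ni, p0)
            cache[ni] = pmf
        out[i] = pmf[pmf <= pmf[ki] * (1 + 1e-7)].sum()
    return np.minimum(out, 1.0)


def ase_test(sites: pd.DataFrame, p0: float | None = None, fdr: float = 0.05):
    """Exact binomial test of allelic imbalance per site + BH correction.

    ``p0`` defaults to the empirical mean AAR over all tested sites (pooled
    across isolates), which absorbs a global mapping bias; pass 0.5 for the
    naive symmetric null.  Returns (table with p / q / significant columns,
    summary dict).
    """
    if "AAR" not in sites.columns:
        sites = compute_aar(sites)
    if p0 is None:
        p0 = float(sites["AAR"].mean())
    if not 0 < p0 < 1:
        raise ValueError(f"null probability must be in (0, 1), got {p0}")
    out = sites.copy()
    k = out["alt_count"].to_numpy(dtype=int)
    n = out["coverage"].to_numpy(dtype=int)
    out["p"] = _binom_p_two_sided(k, n, p0)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < fdr
    summary = {
        "p0": p0,
        "n_sites": len(out),
        "n_significant": int(out["significant"].sum()),
        "mean_aar": float(out["AAR"].mean()),
    }
    return out, summary


def ab_filtration_sweep(
    sites: pd.DataFrame,
    filtration_values: Sequence[float] = (0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45),
    group: pd.Series | None = None,
) -> pd.DataFrame:
    """Diagnostic sweep of symmetric genetic-AB filtration.

    At filtration value v, sites with genetic AB outside [v, 1 - v] are
    discarded; the sweep reports the number retained and the mean AAR (per
    group when ``group`` labels are given), mirroring the exploration that
    motivates a final AB window such as [0.33, 0.66].
    """
    rows = []
    for v in filtration_values:
        keep = (sites["genetic_AB"] >= v) & (sites["genetic_AB"] <= 1 - v)
        sub = sites[keep]
        row = {"filtration": v, "n_retained": len(sub), "mean_aar": sub["AAR"].mean()}
        if group is not None:
            for lab, grp in sub.groupby(group.reindex(sub.index)):
                row[f"mean_aar_{lab}"] = grp["AAR"].mean()
        rows.append(row)
    return pd.DataFrame(rows)
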