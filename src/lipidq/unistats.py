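"""Per-feature univariate testing and differential-feature selection.

Two-sided unpaired Wilcoxon (Mann–Whitney) per feature, Benjamini–
Hochberg multiplicity correction, disease/healthy intensity ratios, and
the selection rule VIP ≥ 1 (inclusive) AND BH q < 0.05 (strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

from .tableio import FeatureTable

__all__ = [
    "UniResult",
    "wilcoxon_unpaired",
    "bh_adjust",
    "group_ratio",
    "select_differential",
    "univariate_table",
]

EXACT_N_MAX = 20  # combined sample size below which the exact null is used


@dataclass
class UniResult:
    """One feature's univariate statistics and selection verdict."""

    feature_id: str
    p_value: float
    q_value: float
    vip: float
    ratio_disease_over_healthy: float
    significant: bool


def wilcoxon_unpaired(x, y) -> float:
    """Two-sided Mann–Whitney p-value for two independent samples.

    Exact enumeration when the combined n ≤ 20 and there are no ties
    across the pooled sample; otherwise the normal approximation with
    tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_N_MAX and no_ties) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def group_ratio(values, groups, numerator: str = "disease",
                denominator: str = "healthy") -> float:
    """Ratio of raw-scale group means, disease over healthy."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    num = values[groups == numerator]
    den = values[groups == denominator]
    if num.size == 0 or den.size == 0:
        raise ValueError("both groups must be nonempty")
    den_mean = den.mean()
    if den_mean == 0:
        raise ValueError("healthy group mean is zero; ratio undefined")
    return float(num.mean() / den_mean)


def select_differential(
    results: list[UniResult] | pd.DataFrame, vip_min: float = 1.0, q_max: float = 0.05
):
    """Keep features with VIP ≥ vip_min (inclusive) and q < q_max (strict)."""
    if isinstance(results, pd.DataFrame):
        keep = (results["vip"] >= vip_min) & (results["q_value"] < q_max)
        return results[keep]
    return [r for r in results if r.vip >= vip_min and r.q_value < q_max]


def univariate_table(
    table: FeatureTable,
    samples: pd.DataFrame,
    vip_scores: pd.Series | None = None,
    vip_min: float = 1.0,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon p, BH q, ratio and significance flag for every feature.

    ``vip_scores`` (indexed by feature id) supplies the multivariate
    importance; features missing from it get VIP = NaN and are never
    flagged significant.
    """
    meta = samples.set_index("sample_id")
    study_cols = [c for c in table.intensities.columns if meta.loc[c, "role"] == "study"]
    groups = meta.loc[study_cols, "group"].to_numpy()
    vals = table.intensities[study_cols]

    p = np.empty(table.n_features)
    ratio = np.empty(table.n_features)
    for i, (_, row) in enumerate(vals.iterrows()):
        v = row.to_numpy(dtype=float)
        p[i] = wilcoxon_unpaired(v[groups == "disease"], v[groups == "healthy"])
        ratio[i] = group_ratio(v, groups)
    q = bh_adjust(p)
    out = pd.DataFrame(
        {"p_value": p, "q_value": q, "ratio": ratio}, index=table.feature_ids
    )
    if vip_scores is not None:
        out["vip"] = vip_scores.reindex(out.index)
    else:
        out["vip"] = np.nan
    out["significant"] = (out["vip"] >= vip_min) & (out["q_value"] < q_max)
    return out
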