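"""Feature-level quality control: detection filter, kNN imputation,
QC-RSD retention, and the SNR / mean-shift "data clean" rules.

All rules are driven by :func:`compute_feature_qc`, which summarizes
each feature over the pooled-QC and study injections.  The pipeline
order is fixed: detection filter → kNN imputation → drift correction →
batch adjustment → RSD filter → SNR clean → mean-shift clean.

Boundary semantics (deliberate and tested):

* detection: removed iff rate strictly below the threshold;
* QC RSD: retained iff strictly below 30%;
* SNR (= study SD / QC SD): removed iff strictly below 1;
* mean shift: removed iff |mean_QC − mean_study| strictly exceeds
  3 × study SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tableio import FeatureTable

__all__ = [
    "FilterReport",
    "compute_feature_qc",
    "filter_by_detection",
    "impute_knn",
    "filter_by_qc_rsd",
    "clean_snr",
    "clean_mean_shift",
    "summarize_filters",
]


@dataclass
class FilterReport:
    """Accounting for one filtering stage (or a chained summary)."""

    stage: str
    n_input: int
    n_removed: int
    n_retained: int
    removed: dict[str, str] = field(default_factory=dict)  # feature id -> reason
    stages: list["FilterReport"] | None = None

    def __post_init__(self) -> None:
        if self.n_input != self.n_removed + self.n_retained:
            raise ValueError(
                f"stage '{self.stage}': {self.n_input} != "
                f"{self.n_removed} + {self.n_retained}"
            )

    @property
    def pct_removed(self) -> float:
        return round(100.0 * self.n_removed / self.n_input, 2) if self.n_input else 0.0


def _split_roles(samples: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    roles = samples.set_index("sample_id")["role"]
    qc_ids = roles.index[roles == "qc"].to_numpy()
    study_ids = roles.index[roles == "study"].to_numpy()
    return qc_ids, study_ids


def compute_feature_qc(table: FeatureTable, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-feature detection rates, means, SDs, QC RSD and SNR.

    SDs are sample SDs (ddof=1); missing cells are excluded throughout.
    ``rsd_qc`` is in percent (100 × sd/mean over QC injections) and
    ``snr = sd_study / sd_qc``.  Features with fewer than two observed
    QC or study values have the affected statistics set to NaN and
    ``undefined=True`` rather than raising.
    """
    qc_ids, study_ids = _split_roles(samples)
    qc = table.intensities[[c for c in table.intensities.columns if c in set(qc_ids)]]
    st = table.intensities[[c for c in table.intensities.columns if c in set(study_ids)]]

    stats = pd.DataFrame(index=table.feature_ids)
    stats["det_rate_qc"] = qc.notna().mean(axis=1)
    stats["det_rate_study"] = st.notna().mean(axis=1)
    stats["mean_qc"] = qc.mean(axis=1)
    stats["sd_qc"] = qc.std(axis=1, ddof=1)
    stats["mean_study"] = st.mean(axis=1)
    stats["sd_study"] = st.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stats["rsd_qc"] = 100.0 * stats["sd_qc"] / stats["mean_qc"]
        stats["snr"] = stats["sd_study"] / stats["sd_qc"]
    # snr undefined when QC SD is zero
    stats.loc[stats["sd_qc"] == 0, "snr"] = np.nan
    n_qc_obs = qc.notna().sum(axis=1)
    n_st_obs = st.notna().sum(axis=1)
    stats["undefined"] = (n_qc_obs < 2) | (n_st_obs < 2)
    stats.loc[n_qc_obs < 2, ["mean_qc", "sd_qc", "rsd_qc", "snr"]] = np.nan
    stats.loc[n_st_obs < 2, ["mean_study", "sd_study", "snr"]] = np.nan
    return stats


def _apply_removal(
    table: FeatureTable, remove: pd.Series, stage: str, reason: str
) -> tuple[FeatureTable, FilterReport]:
    remove = remove.reindex(table.feature_ids).fillna(False).astype(bool)
    keep_ids = table.feature_ids[~remove]
    report = FilterReport(
        stage=stage,
        n_input=table.n_features,
        n_removed=int(remove.sum()),
        n_retained=len(keep_ids),
        removed={fid: reason for fid in table.feature_ids[remove]},
    )
    return table.subset(keep_ids), report


def filter_by_detection(
    table: FeatureTable,
    samples: pd.DataFrame,
    qc_min: float = 0.5,
    study_min: float = 0.2,
) -> tuple[FeatureTable, FilterReport]:
    """Remove features detected in < 50% of QC or < 20% of study injections.

    Both comparisons are strict: a feature sitting exactly on a threshold
    is retained.  Study detection rate is computed over study injections
    only.
    """
    stats = compute_feature_qc(table, samples)
    remove = (stats["det_rate_qc"] < qc_min) | (stats["det_rate_study"] < study_min)
    return _apply_removal(table, remove, "detection", "low detection rate")


def impute_knn(
    table: FeatureTable, samples: pd.DataFrame | None = None, k: int = 10
) -> FeatureTable:
    """Fill each missing cell with the mean of the k nearest features'
    values in that injection.

    Nearness is plain Euclidean distance between feature rows on the
    log2 scale, summed over mutually observed injections; pairs with no
    overlap are treated as infinitely far.  Only neighbor features
    observed in the target injection contribute; if fewer than ``k``
    such neighbors exist, all of them are used.  Imputing a complete
    table is the identity.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = table.intensities.to_numpy(dtype=float)
    if not np.isnan(vals).any():
        return table.copy()
    if np.isnan(vals).all(axis=1).any():
        bad = table.feature_ids[np.isnan(vals).all(axis=1)].tolist()
        raise ValueError(f"features with no observed values cannot be imputed: {bad[:5]}")

    log_vals = np.log2(vals)
    mask = (~np.isnan(log_vals)).astype(float)
    x0 = np.where(np.isnan(log_vals), 0.0, log_vals)
    # sum over mutual overlap of (xi - xj)^2, via masked matrix products
    sq = (x0**2) @ mask.T
    d2 = sq + sq.T - 2.0 * (x0 @ x0.T)
    overlap = mask @ mask.T
    dist = np.sqrt(np.maximum(d2, 0.0))
    dist[overlap == 0] = np.inf
    np.fill_diagonal(dist, np.inf)

    out = vals.copy()
    miss_rows, miss_cols = np.where(np.isnan(vals))
    for i, j in zip(miss_rows, miss_cols):
        observed_here = ~np.isnan(vals[:, j])
        cand = np.where(observed_here)[0]
        if cand.size == 0:
            # no feature observed in this injection: fall back to row mean
            out[i, j] = np.nanmean(vals[i])
            continue
        order = cand[np.argsort(dist[i, cand], kind="stable")]
        finite = order[np.isfinite(dist[i, order])]
        chosen = (finite if finite.size else order)[:k]
        out[i, j] = vals[chosen, j].mean()
    grid = pd.DataFrame(out, index=table.intensities.index, columns=table.intensities.columns)
    return table.with_values(grid)


def filter_by_qc_rsd(
    table: FeatureTable, samples: pd.DataFrame, max_rsd: float = 30.0
) -> tuple[FeatureTable, FilterReport]:
    """Retain features whose QC RSD is strictly below ``max_rsd`` percent.

    A feature at exactly the threshold is removed; undefined RSD
    (insufficient QC observations) is removed as unassessable.
    """
    stats = compute_feature_qc(table, samples)
    retain = stats["rsd_qc"] < max_rsd
    return _apply_removal(table, ~retain, "qc_rsd", f"QC RSD >= {max_rsd}%")


def clean_snr(
    table: FeatureTable, samples: pd.DataFrame
) -> tuple[FeatureTable, FilterReport]:
    """Remove features with SNR = sd_study/sd_qc strictly below 1.

    Such features vary less across subjects than across identical pooled
    QCs — their spread is technical, not biological.  Undefined SNR
    (QC SD of zero) is retained and flagged in the report reasons.
    """
    stats = compute_feature_qc(table, samples)
    remove = stats["snr"] < 1.0  # NaN compares False -> retained
    return _apply_removal(table, remove, "snr_clean", "SNR < 1")


def clean_mean_shift(
    table: FeatureTable, samples: pd.DataFrame, n_sd: float = 3.0
) -> tuple[FeatureTable, FilterReport]:
    """Remove features whose QC mean sits more than ``n_sd`` study SDs
    from the study mean (strict >): the pooled QC no longer represents
    the cohort for that feature."""
    stats = compute_feature_qc(table, samples)
    shift = (stats["mean_qc"] - stats["mean_study"]).abs()
    remove = shift > n_sd * stats["sd_study"]
    return _apply_removal(table, remove, "mean_shift_clean", f"|QC-study mean| > {n_sd} SD")


def summarize_filters(reports: list[FilterReport]) -> FilterReport:
    """Chain stage reports into one summary; validates conservation.

    Stage i's retained count must equal stage i+1's input count, and the
    initial feature count must equal the final count plus everything
    removed along the way.
    """
    if not reports:
        raise ValueError("no reports to summarize")
    for a, b in zip(reports, reports[1:]):
        if a.n_retained != b.n_input:
            raise ValueError(
                f"inconsistent chaining: stage '{a.stage}' retained {a.n_retained} "
                f"but stage '{b.stage}' saw {b.n_input}"
            )
    removed: dict[str, str] = {}
    for r in reports:
        removed.update({fid: f"{r.stage}: {reason}" for fid, reason in r.removed.items()})
    return FilterReport(
        stage="pipeline",
        n_input=reports[0].n_input,
        n_removed=sum(r.n_removed for r in reports),
        n_retained=reports[-1].n_retained,
        removed=removed,
        stages=list(reports),
    )
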