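"""End-to-end orchestration of the lipidomics analysis.

Stage order is fixed: detection filter → kNN imputation → drift
correction → batch adjustment → QC-RSD filter → SNR clean → mean-shift
clean → log2+Pareto scaling → PCA / PLS-DA (+ optional permutation
validation) → Wilcoxon/BH + VIP selection → ROC and random-forest panel
→ lipid annotation.  The report bundle carries the per-stage filter
accounting, the differential-feature table, ROC results and an
auditable echo of every threshold and seed actually applied.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier_roc, lipid_id, multivar, normalize, qcfilter, unistats
from .qcfilter import FilterReport
from .tableio import FeatureTable, write_results

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "subset_by_group", "stage_seed"]


@dataclass
class PipelineConfig:
    """All thresholds, sizes and seeds for one pipeline run."""

    qc_min: float = 0.5
    study_min: float = 0.2
    knn_k: int = 10
    max_rsd: float = 30.0
    vip_min: float = 1.0
    q_max: float = 0.05
    ms1_tol: float = 10.0
    n_components: int = 2
    n_perm: int = 200
    folds: int = 7
    panel_size: int = 10
    train_frac: float = 2.0 / 3.0
    n_trees: int = 500
    seed: int = 0
    mode: str | None = None       # restrict to one ion mode; None = all features
    apply_drift_correction: bool = True
    apply_batch_adjustment: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


def stage_seed(master: int, stage: str) -> int:
    """Derived per-stage seed: stable under reordering of optional stages."""
    return (zlib.crc32(f"{stage}:{master}".encode()) ^ master) % (2**31)


@dataclass
class PipelineReport:
    """Everything one run produced, plus the config that produced it."""

    config: PipelineConfig
    filter_reports: list[FilterReport]
    filter_summary: FilterReport
    qc_rsd_before: float
    qc_rsd_after: float
    pca: multivar.PcaResult
    plsda: multivar.PLSDAResults
    q2: float
    permutation: multivar.PermutationSummary | None
    results: pd.DataFrame                 # per-feature p, q, vip, ratio, auc, ci
    selected: pd.DataFrame
    panel: classifier_roc.PanelSelection | None
    annotations: list[lipid_id.LipidAnnotation]
    log: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        res = self.results.reset_index().rename(columns={"index": "feature_id"})
        write_results(outdir / "results.tsv", res)
        sel = self.selected.reset_index().rename(columns={"index": "feature_id"})
        write_results(outdir / "selected.tsv", sel)
        if self.annotations:
            write_results(
                outdir / "annotations.tsv",
                pd.DataFrame([vars(a) for a in self.annotations]),
            )
        stages = pd.DataFrame(
            [
                {
                    "stage": r.stage,
                    "n_input": r.n_input,
                    "n_removed": r.n_removed,
                    "n_retained": r.n_retained,
                    "pct_removed": r.pct_removed,
                }
                for r in self.filter_reports
            ]
        )
        stages.to_csv(outdir / "filter_stages.tsv", sep="\t", index=False)
        (outdir / "run_log.txt").write_text("\n".join(self.log) + "\n")
        return outdir


def _median_qc_rsd(table: FeatureTable, samples: pd.DataFrame) -> float:
    stats = qcfilter.compute_feature_qc(table, samples)
    return float(stats["rsd_qc"].median())


def run_pipeline(
    table: FeatureTable,
    samples: pd.DataFrame,
    config: PipelineConfig | None = None,
    candidates: list[lipid_id.LipidCandidate] | None = None,
) -> PipelineReport:
    """Run the full analysis on one feature table.

    Aborts with the stage name on any stage error.  With ``n_perm=0``
    the permutation section is skipped and marked as such; everything
    else is unchanged.
    """
    config = config or PipelineConfig()
    log: list[str] = [f"config: {asdict(config)}"]
    reports: list[FilterReport] = []

    if config.mode is not None:
        keep = table.features.index[table.features["ion_mode"] == config.mode]
        table = table.subset(keep)
        log.append(f"mode={config.mode}: {table.n_features} features")

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    # --- QC filtering / normalization ------------------------------
    table, rep = _stage("detection", qcfilter.filter_by_detection,
                        table, samples, config.qc_min, config.study_min)
    reports.append(rep)
    table = _stage("imputation", qcfilter.impute_knn, table, samples, config.knn_k)
    rsd_before = _median_qc_rsd(table, samples)

    if config.apply_drift_correction:
        fits = _stage("drift_fit", normalize.fit_drift_all, table, samples)
        table = _stage("drift_correct", normalize.correct_drift, table, fits, samples)
    if config.apply_batch_adjustment:
        table = _stage("batch_adjust", normalize.combat_adjust, table, samples)
    rsd_after = _median_qc_rsd(table, samples)
    log.append(f"median QC RSD: {rsd_before:.2f}% -> {rsd_after:.2f}%")

    table, rep = _stage("qc_rsd", qcfilter.filter_by_qc_rsd, table, samples, config.max_rsd)
    reports.append(rep)
    table, rep = _stage("snr_clean", qcfilter.clean_snr, table, samples)
    reports.append(rep)
    table, rep = _stage("mean_shift_clean", qcfilter.clean_mean_shift, table, samples)
    reports.append(rep)
    summary = qcfilter.summarize_filters(reports)
    log.append(
        f"features: {summary.n_input} -> {summary.n_retained} "
        f"({summary.n_removed} removed)"
    )

    # --- multivariate ----------------------------------------------
    meta = samples.set_index("sample_id")
    study_cols = [c for c in table.intensities.columns if meta.loc[c, "role"] == "study"]
    groups = meta.loc[study_cols, "group"]

    scaled_all = _stage("scaling", multivar.log2_pareto, table)
    pca_res = _stage("pca", multivar.pca, scaled_all, min(2, table.n_injections - 1))

    study_vals = table.intensities[study_cols]
    log_study = np.log2(study_vals.to_numpy(dtype=float).T)
    scaled_study = _stage("scaling", multivar.log2_pareto, study_vals)
    pls = _stage(
        "plsda", multivar.plsda_fit, scaled_study, groups.to_numpy(), config.n_components
    )
    q2 = _stage(
        "q2", multivar.plsda_cv_q2, log_study, groups.to_numpy(), config.n_components,
        config.folds, stage_seed(config.seed, "q2"), True,
    )
    perm = None
    if config.n_perm > 0:
        perm = _stage(
            "permutation", multivar.permutation_test, log_study, groups.to_numpy(),
            config.n_components, config.n_perm, config.folds,
            stage_seed(config.seed, "permutation"), True,
        )
        log.append(
            f"permutation: p(R2Y)={perm.p_r2y:.4f} p(Q2)={perm.p_q2:.4f} "
            f"({config.n_perm} permutations)"
        )
    else:
        log.append("permutation: skipped (n_perm=0)")
    vip_scores = pd.Series(pls.vip(), index=scaled_study.feature_ids)
    log.append(f"PLS-DA: R2Y={pls.R2Y:.3f} Q2={q2:.3f}")

    # --- univariate + selection ------------------------------------
    results = _stage(
        "univariate", unistats.univariate_table, table, samples, vip_scores,
        config.vip_min, config.q_max,
    )
    # univariate ROC per feature
    y = groups.to_numpy()
    aucs, ci_lo, ci_hi = [], [], []
    for fid in results.index:
        curve = classifier_roc.roc_auc(
            np.log2(study_vals.loc[fid].to_numpy(dtype=float)), y
        )
        aucs.append(curve.auc)
        ci_lo.append(curve.ci_low)
        ci_hi.append(curve.ci_high)
    results["auc"] = aucs
    results["ci_low"] = ci_lo
    results["ci_high"] = ci_hi
    selected = unistats.select_differential(results, config.vip_min, config.q_max)
    log.append(f"selected: {len(selected)} differential features")

    # --- panel ------------------------------------------------------
    panel = None
    if len(selected) >= config.panel_size:
        panel = _stage(
            "panel", classifier_roc.rf_select_panel,
            table.subset(selected.index.tolist()).with_values(
                table.intensities.loc[selected.index, study_cols]
            ),
            y, config.train_frac, config.folds, config.panel_size,
            stage_seed(config.seed, "panel"), config.n_trees,
        )
        log.append(
            f"panel: {config.panel_size} features, cv AUC={panel.cv_auc:.3f}, "
            f"test AUC={panel.test_auc:.3f}"
        )
    else:
        log.append("panel: skipped (fewer selected features than panel_size)")

    # --- annotation -------------------------------------------------
    annotations = _stage(
        "annotation", lipid_id.match_features,
        table.features.loc[selected.index], candidates, config.ms1_tol,
    )
    log.append(f"annotation: {len(annotations)} candidate matches")

    return PipelineReport(
        config=config,
        filter_reports=reports,
        filter_summary=summary,
        qc_rsd_before=rsd_before,
        qc_rsd_after=rsd_after,
        pca=pca_res,
        plsda=pls,
        q2=q2,
        permutation=perm,
        results=results,
        selected=selected,
        panel=panel,
        annotations=annotations,
        log=log,
    )


def subset_by_group(samples: pd.DataFrame, pasi_cut: float = 10.0) -> dict[str, pd.DataFrame]:
    """Split disease subjects into mild (PASI ≤ cut) and moderate-severe.

    Returns sample subsets keyed ``"mild"``, ``"moderate_severe"`` and
    ``"healthy"`` (QCs pass through with healthy) for pairwise re-runs.
    Raises if a disease sample lacks a PASI score.
    """
    disease = samples[samples["group"] == "disease"]
    if disease["pasi"].isna().any():
        bad = disease.loc[disease["pasi"].isna(), "sample_id"].tolist()
        raise ValueError(f"disease samples without PASI: {bad[:5]}")
    mild = disease[disease["pasi"] <= pasi_cut]
    severe = disease[disease["pasi"] > pasi_cut]
    rest = samples[samples["group"] != "disease"]
    if disease.empty:
        import warnings

        warnings.warn("no disease samples: subgroup subsets are empty")
    return {"mild": mild, "moderate_severe": severe, "healthy": rest}
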