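"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure of an untargeted plasma-lipidomics
run on a case/control cohort (default 45 disease vs 45 healthy) with
interspersed pooled-QC injections: per-feature log-normal intensities,
spiked disease/healthy effects, multiplicative injection-order drift,
additive log2-scale batch offsets, intensity-dependent plus random
missingness, and a minority of "noise" features whose study-sample
spread is smaller than their QC spread.

Ground truth (which features are differential or noise, true ratios,
which cells were deleted, the run design) is returned as
:class:`SimTruth` so downstream filters, normalization and selection can
be scored for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .tableio import FeatureTable, validate_samples

__all__ = ["SimConfig", "SimTruth", "generate_cohort", "inject_drift", "inject_missing"]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters for one synthetic cohort.

    Defaults mirror the cohort the analysis assumes: 45 disease vs 45
    healthy subjects, a pooled QC every 10 study injections (plus leading
    and trailing QCs), differential features spiked at disease/healthy
    intensity ratios log-uniform in [0.37, 1.62], QC replicate noise
    tuned to ~10% RSD, and a small fraction of variance-deficient noise
    features.
    """

    n_healthy: int = 45
    n_disease: int = 45
    n_features: int = 500
    frac_differential: float = 0.1
    ratio_range: tuple[float, float] = (0.37, 1.62)
    n_batches: int = 2
    batch_shift_sd: float = 0.3        # log2 units
    drift_amplitude: float = 0.5       # peak-to-trough fraction of intensity
    qc_interval: int = 10              # study injections between pooled QCs
    mcar_rate: float = 0.02
    mnar_strength: float = 0.5
    frac_noise_features: float = 0.05
    baseline_log2_mean_range: tuple[float, float] = (14.0, 22.0)
    cv_qc_target: float = 0.10
    biological_cv: float = 0.25        # subject-to-subject spread, non-noise features
    noise_feature_sep: float = 2.5     # QC-to-study SD margin for noise features
    min_effect_ratio: float = 1.25     # spiked effects are at least this fold change
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_healthy", "n_disease", "n_features", "n_batches", "qc_interval"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("frac_differential", "mcar_rate", "frac_noise_features"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.ratio_range
        if not (0 < lo <= hi):
            raise ValueError("ratio_range must satisfy 0 < min <= max")
        if self.mnar_strength < 0 or self.drift_amplitude < 0:
            raise ValueError("mnar_strength and drift_amplitude must be nonnegative")
        if self.frac_differential + self.frac_noise_features > 1.0:
            raise ValueError("differential and noise fractions exceed the feature count")


@dataclass
class SimTruth:
    """Ground truth for a generated cohort.

    ``features``: per-feature frame with ``is_differential``,
    ``true_ratio``, ``is_noise``, ``drift_applied``.
    ``injections``: per-injection frame with ``sample_id``, ``role``,
    ``group``, ``batch``, ``injection_order``.
    ``removed_mask``: boolean frame marking cells deleted by the
    missingness step; ``removed_values`` stores what was deleted.
    """

    features: pd.DataFrame
    injections: pd.DataFrame
    removed_mask: pd.DataFrame | None = None
    removed_values: pd.DataFrame | None = None
    config: SimConfig | None = None

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.features.to_csv(path, sep="\t")
        return path


def _qc_design(config: SimConfig) -> pd.DataFrame:
    """Run order: leading QC, a QC after every ``qc_interval`` study
    injections, and a trailing QC."""
    n_study = config.n_healthy + config.n_disease
    if config.qc_interval > n_study:
        raise ValueError("no QC coverage: qc_interval exceeds the study injection count")
    rows: list[tuple[str, str]] = [("qc", "none")]
    placed = 0
    while placed < n_study:
        take = min(config.qc_interval, n_study - placed)
        rows.extend([("study", "")] * take)
        placed += take
        rows.append(("qc", "none"))
    design = pd.DataFrame(rows, columns=["role", "group"])
    design["injection_order"] = np.arange(1, len(design) + 1)
    return design


def generate_cohort(
    config: SimConfig,
) -> tuple[FeatureTable, pd.DataFrame, SimTruth]:
    """Generate one cohort: peak table, sample sheet, and ground truth.

    The clean signal is built first (log-normal baselines, spiked group
    ratios, replicate noise calibrated so QC RSD ≈ ``cv_qc_target``),
    then instrument artifacts are layered on by :func:`inject_drift`
    (smooth multiplicative run-order drift), additive log2 batch offsets,
    and :func:`inject_missing`.  Identical config and seed give
    byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    n_study = config.n_healthy + config.n_disease

    design = _qc_design(config)
    n_inj = len(design)

    # randomize case/control positions in the run
    groups = np.array(["healthy"] * config.n_healthy + ["disease"] * config.n_disease)
    rng.shuffle(groups)
    study_rows = design.index[design["role"] == "study"]
    design.loc[study_rows, "group"] = groups

    # contiguous batches over run order
    batch_edges = np.array_split(np.arange(n_inj), config.n_batches)
    batch = np.empty(n_inj, dtype=int)
    for b, idx in enumerate(batch_edges, start=1):
        batch[idx] = b
    design["batch"] = batch

    ids = []
    qc_counter = study_counter = 0
    for role in design["role"]:
        if role == "qc":
            qc_counter += 1
            ids.append(f"QC{qc_counter:02d}")
        else:
            study_counter += 1
            ids.append(f"S{study_counter:03d}")
    design.insert(0, "sample_id", ids)
    samples = validate_samples(
        design[["sample_id", "role", "group", "batch", "injection_order"]].copy()
    )
    # PASI only for disease subjects: mild (<=10) and moderate-severe mixed
    pasi = np.full(n_inj, np.nan)
    disease_idx = design.index[design["group"] == "disease"]
    pasi[disease_idx] = np.round(rng.gamma(2.0, 5.0, size=len(disease_idx)) + 0.5, 2)
    samples["pasi"] = pasi

    # --- feature truth --------------------------------------------
    n_diff = int(round(config.frac_differential * config.n_features))
    n_noise = int(round(config.frac_noise_features * config.n_features))
    feat_ids = [f"F{i:05d}" for i in range(1, config.n_features + 1)]
    perm = rng.permutation(config.n_features)
    diff_idx = perm[:n_diff]
    noise_idx = perm[n_diff : n_diff + n_noise]
    is_diff = np.zeros(config.n_features, dtype=bool)
    is_diff[diff_idx] = True
    is_noise = np.zeros(config.n_features, dtype=bool)
    is_noise[noise_idx] = True
    # spiked effects: magnitude of the log-ratio uniform between the
    # minimum meaningful fold change and the range bound, random sign —
    # a "differential" feature with ratio ~1 would be a contradiction
    lo, hi = config.ratio_range
    true_ratio = np.ones(config.n_features)
    if n_diff:
        up = rng.random(n_diff) < 0.5
        min_eff = np.log(config.min_effect_ratio)
        up_hi = np.log(max(hi, config.min_effect_ratio))
        dn_hi = np.log(max(1.0 / lo, config.min_effect_ratio))
        up_mag = rng.uniform(min(min_eff, up_hi), up_hi, size=n_diff)
        dn_mag = rng.uniform(min(min_eff, dn_hi), dn_hi, size=n_diff)
        true_ratio[diff_idx] = np.where(up, np.exp(up_mag), np.exp(-dn_mag))

    # --- clean expected intensities -------------------------------
    b_lo, b_hi = config.baseline_log2_mean_range
    base_log2 = rng.uniform(b_lo, b_hi, size=config.n_features)
    healthy_mean = 2.0**base_log2                                # raw scale
    disease_mean = healthy_mean * true_ratio
    pooled_mean = (
        config.n_healthy * healthy_mean + config.n_disease * disease_mean
    ) / n_study

    # log-normal noise SDs (natural-log scale): technical (QC + study)
    # calibrated so QC RSD ~ cv_qc_target; biological added for study.
    sd_tech = np.full(config.n_features, np.sqrt(np.log1p(config.cv_qc_target**2)))
    sd_bio = np.full(config.n_features, np.sqrt(np.log1p(config.biological_cv**2)))
    # noise features: study spread deliberately below QC spread
    sd_tech_study = sd_tech.copy()
    sd_bio[is_noise] = 0.0
    sd_tech_study[is_noise] = sd_tech[is_noise] / config.noise_feature_sep

    is_qc = (samples["role"] == "qc").to_numpy()
    grp = samples["group"].to_numpy()

    values = np.empty((config.n_features, n_inj))
    for j in range(n_inj):
        if is_qc[j]:
            mu = pooled_mean
            sd = sd_tech
        else:
            mu = disease_mean if grp[j] == "disease" else healthy_mean
            sd = np.sqrt(sd_tech_study**2 + sd_bio**2)
        noise = rng.normal(0.0, 1.0, size=config.n_features)
        # mean-preserving log-normal: E[exp(sd*z - sd^2/2)] = 1
        values[:, j] = mu * np.exp(sd * noise - sd**2 / 2.0)

    mz = np.round(rng.uniform(200.0, 1000.0, size=config.n_features), 6)
    rt = np.round(rng.uniform(0.5, 9.5, size=config.n_features), 2)
    mode = np.where(rng.random(config.n_features) < 0.5, "positive", "negative")
    feat_meta = pd.DataFrame(
        {"mz": mz, "rt": rt, "ion_mode": mode}, index=pd.Index(feat_ids, name="feature_id")
    )
    grid = pd.DataFrame(values, index=feat_meta.index, columns=samples["sample_id"])
    table = FeatureTable(grid, feat_meta)

    truth = SimTruth(
        features=pd.DataFrame(
            {
                "is_differential": is_diff,
                "true_ratio": true_ratio,
                "is_noise": is_noise,
                "drift_applied": np.zeros(config.n_features, dtype=bool),
            },
            index=feat_meta.index,
        ),
        injections=samples.copy(),
        config=config,
    )

    # --- instrument artifacts -------------------------------------
    if config.drift_amplitude > 0:
        table = inject_drift(
            table, truth, config.drift_amplitude, samples=samples,
            rng=np.random.default_rng(rng.integers(2**31)),
        )
    if config.n_batches > 1 and config.batch_shift_sd > 0:
        shifts = rng.normal(
            0.0, config.batch_shift_sd, size=(config.n_features, config.n_batches)
        )
        factor = 2.0 ** shifts[:, samples["batch"].to_numpy() - 1]
        table = table.with_values(table.intensities * factor)
    if config.mcar_rate > 0 or config.mnar_strength > 0:
        table = inject_missing(
            table, config.mcar_rate, config.mnar_strength,
            truth=truth, rng=np.random.default_rng(rng.integers(2**31)),
        )
    return table, samples, truth


def inject_drift(
    table: FeatureTable,
    truth: SimTruth | None,
    amplitude: float,
    *,
    samples: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> FeatureTable:
    """Multiply each feature by a smooth positive function of run order.

    The kernel is a rising half-cosine over the run: injection order ``o``
    in ``[1, N]`` maps to ``1 + (a/2) * (-cos(pi*(o-1)/(N-1)))`` so the
    peak-to-trough relative range equals the feature's amplitude.  QC and
    study injections are affected identically.  Per-feature amplitudes
    are jittered in ``[0.5, 1] × amplitude`` (same monotone shape) so the
    drift is not a rank-one artifact.
    """
    if amplitude < 0:
        raise ValueError("drift amplitude must be nonnegative")
    if amplitude == 0:
        return table.copy()
    if samples is not None:
        orders = samples.set_index("sample_id").loc[
            table.intensities.columns, "injection_order"
        ].to_numpy(dtype=float)
    elif truth is not None and truth.injections is not None:
        orders = truth.injections.set_index("sample_id").loc[
            table.intensities.columns, "injection_order"
        ].to_numpy(dtype=float)
    else:
        raise ValueError("injection orders unavailable: pass samples or truth")
    rng = rng or np.random.default_rng(0)
    n = orders.max()
    x = (orders - 1.0) / max(n - 1.0, 1.0)          # [0, 1] over the run
    kernel = -np.cos(np.pi * x)                      # rising, [-1, 1]
    amps = amplitude * rng.uniform(0.5, 1.0, size=table.n_features)
    factors = 1.0 + np.outer(amps / 2.0, kernel)     # strictly positive for a < 2
    out = table.with_values(table.intensities * factors)
    if truth is not None:
        truth.features["drift_applied"] = True
    return out


def inject_missing(
    table: FeatureTable,
    mcar_rate: float,
    mnar_strength: float,
    *,
    truth: SimTruth | None = None,
    rng: np.random.Generator | None = None,
    mnar_quantile: float = 0.15,
) -> FeatureTable:
    """Delete cells completely at random plus preferentially at low intensity.

    MCAR: each observed cell deleted with probability ``mcar_rate``.
    MNAR: for cells below the per-feature ``mnar_quantile`` intensity
    quantile ``t``, additional deletion probability
    ``min(1, mnar_strength * (1 - x/t))`` — rising as the value falls
    further below the quantile.  Deleted cells and their values are
    recorded on ``truth``.
    """
    if mcar_rate < 0 or mnar_strength < 0:
        raise ValueError("missingness parameters must be nonnegative")
    rng = rng or np.random.default_rng(0)
    vals = table.intensities.to_numpy(dtype=float)
    observed = ~np.isnan(vals)

    p = np.full(vals.shape, mcar_rate)
    if mnar_strength > 0:
        with np.errstate(invalid="ignore"):
            t = np.nanquantile(vals, mnar_quantile, axis=1, keepdims=True)
        low = vals < t
        p_mnar = np.where(low, np.minimum(1.0, mnar_strength * (1.0 - vals / t)), 0.0)
        p = 1.0 - (1.0 - p) * (1.0 - p_mnar)
    drop = observed & (rng.random(vals.shape) < p)

    out_vals = vals.copy()
    out_vals[drop] = np.nan
    out = table.with_values(
        pd.DataFrame(out_vals, index=table.intensities.index, columns=table.intensities.columns)
    )
    if truth is not None:
        truth.removed_mask = pd.DataFrame(
            drop, index=table.intensities.index, columns=table.intensities.columns
        )
        truth.removed_values = table.intensities.where(truth.removed_mask)
    return out
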