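"""Signal-drift correction against pooled QCs and batch adjustment.

Drift correction follows the QC-robust-spline idea: per feature, a
cubic smoothing spline is fitted to log2 QC intensity versus injection
order (smoothing chosen by leave-one-out error over a small grid), and
every injection is divided by the fitted curve relative to the median
QC level.  Features with too few QCs fall back to a linear fit (< 4
QCs) or are left untouched (< 2).

Batch adjustment is parametric empirical-Bayes location/scale
adjustment (the ComBat model) on the log2 scale: per-feature
standardization, shrinkage of per-batch means and variances toward
their across-feature priors, then adjustment to the grand mean and
pooled variance.  QC injections participate — they carry batch signal
too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .tableio import FeatureTable

__all__ = ["DriftFit", "fit_drift", "fit_drift_all", "correct_drift", "combat_adjust"]

# leave-one-out grid for the spline penalty; run order is rescaled to
# [0, 1] before fitting so these are scale-free
LAM_GRID = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0)


@dataclass
class DriftFit:
    """Fitted drift curve for one feature (log2 scale over run order)."""

    kind: str                      # "spline" | "linear" | "none"
    reference: float               # median QC intensity, raw scale
    loo_error: float
    _coeffs: tuple[float, float] | None = None   # linear: (intercept, slope)
    _spline: object | None = None
    _order_span: tuple[float, float] = (1.0, 1.0)

    def curve_log2(self, orders: np.ndarray) -> np.ndarray:
        """Fitted log2 intensity at the given injection orders."""
        orders = np.asarray(orders, dtype=float)
        lo, hi = self._order_span
        x = (orders - lo) / max(hi - lo, 1.0)
        if self.kind == "spline":
            return np.asarray(self._spline(x))
        if self.kind == "linear":
            b0, b1 = self._coeffs
            return b0 + b1 * x
        return np.full(orders.shape, np.log2(self.reference))

    def factor(self, orders: np.ndarray) -> np.ndarray:
        """Multiplicative correction divisor: curve(order) / reference."""
        return 2.0 ** self.curve_log2(orders) / self.reference


def fit_drift(
    qc_values: np.ndarray, qc_orders: np.ndarray, lam_grid: tuple[float, ...] = LAM_GRID
) -> DriftFit:
    """Fit one feature's drift curve from its QC intensities.

    >= 4 observed QCs: cubic smoothing spline on log2 intensity, penalty
    chosen by leave-one-out squared error over ``lam_grid``; 2–3 QCs:
    least-squares line; < 2: no correction (flagged ``"none"``).
    """
    qc_values = np.asarray(qc_values, dtype=float)
    qc_orders = np.asarray(qc_orders, dtype=float)
    keep = ~np.isnan(qc_values)
    qc_values, qc_orders = qc_values[keep], qc_orders[keep]
    if np.any(qc_values <= 0):
        raise ValueError("QC intensities must be positive for drift fitting")
    n = qc_values.size
    if n < 2:
        ref = float(np.median(qc_values)) if n else 1.0
        return DriftFit(kind="none", reference=ref, loo_error=np.nan)

    srt = np.argsort(qc_orders)
    qc_orders, qc_values = qc_orders[srt], qc_values[srt]
    y = np.log2(qc_values)
    lo, hi = float(qc_orders[0]), float(qc_orders[-1])
    x = (qc_orders - lo) / max(hi - lo, 1.0)
    ref = float(np.median(qc_values))

    if n < 4:
        b1, b0 = np.polyfit(x, y, 1)
        resid = y - (b0 + b1 * x)
        return DriftFit(
            kind="linear", reference=ref, loo_error=float(np.mean(resid**2)),
            _coeffs=(float(b0), float(b1)), _order_span=(lo, hi),
        )

    best_lam, best_err = None, np.inf
    for lam in lam_grid:
        err = 0.0
        for i in range(n):
            idx = np.arange(n) != i
            try:
                sp = make_smoothing_spline(x[idx], y[idx], lam=lam)
            except Exception:
                err = np.inf
                break
            err += float((sp(x[i]) - y[i]) ** 2)
        if err < best_err:
            best_err, best_lam = err, lam
    spline = make_smoothing_spline(x, y, lam=best_lam)
    return DriftFit(
        kind="spline", reference=ref, loo_error=best_err / n,
        _spline=spline, _order_span=(lo, hi),
    )


def fit_drift_all(
    table: FeatureTable, samples: pd.DataFrame, lam_grid: tuple[float, ...] = LAM_GRID
) -> dict[str, DriftFit]:
    """Fit drift curves for every feature from the QC injections."""
    samples = samples.set_index("sample_id")
    qc_cols = [c for c in table.intensities.columns if samples.loc[c, "role"] == "qc"]
    qc_orders = samples.loc[qc_cols, "injection_order"].to_numpy(dtype=float)
    fits = {}
    for fid, row in table.intensities[qc_cols].iterrows():
        fits[fid] = fit_drift(row.to_numpy(dtype=float), qc_orders, lam_grid)
    return fits


def correct_drift(table: FeatureTable, fits: dict[str, DriftFit],
                  samples: pd.DataFrame) -> FeatureTable:
    """Divide every intensity by its feature's fitted drift factor.

    The factor is ``curve(order)/reference`` so a flat fit is the
    identity; positivity is preserved because the curve is an
    exponentiated log2 fit.  Features flagged ``"none"`` are untouched.
    """
    missing = [fid for fid in table.feature_ids if fid not in fits]
    if missing:
        raise ValueError(f"drift fits missing for features: {missing[:5]}")
    orders = samples.set_index("sample_id").loc[
        table.intensities.columns, "injection_order"
    ].to_numpy(dtype=float)
    out = table.intensities.copy()
    for fid in table.feature_ids:
        fit = fits[fid]
        if fit.kind == "none":
            continue
        out.loc[fid] = out.loc[fid].to_numpy() / fit.factor(orders)
    return table.with_values(out)


def _combat_it_sol(
    s_data: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
    g_bar: float, t2: float, a: float, b: float,
    conv: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative EB solution for one batch's shrunken location/scale."""
    n = np.sum(~np.isnan(s_data), axis=1)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = np.nansum((s_data - g_new[:, None]) ** 2, axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.abs(g_old).clip(min=1e-12)),
            np.max(np.abs(d_new - d_old) / d_old.clip(min=1e-12)),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat_adjust(
    table: FeatureTable,
    samples: pd.DataFrame,
    mean_only: bool = False,
) -> FeatureTable:
    """Empirical-Bayes batch adjustment on the log2 scale.

    Parametric priors, no covariates; per-batch location and (unless
    ``mean_only``) scale are shrunk across features and removed, then
    values are returned to the grand mean / pooled variance and
    back-transformed to the intensity scale.  A single batch is returned
    unchanged; a batch with one injection raises.
    """
    batches = samples.set_index("sample_id").loc[
        table.intensities.columns, "batch"
    ].to_numpy()
    levels = np.unique(batches)
    if len(levels) < 2:
        return table.copy()
    counts = {int(b): int((batches == b).sum()) for b in levels}
    tiny = [b for b, c in counts.items() if c < 2]
    if tiny:
        raise ValueError(f"batch {tiny[0]} has a single injection; cannot adjust")

    vals = table.intensities.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("batch adjustment requires a complete (imputed) table")
    if np.any(vals <= 0):
        raise ValueError("batch adjustment requires positive intensities")
    x = np.log2(vals)                                  # features x samples
    n_feat, n_samp = x.shape
    n_b = np.array([counts[int(b)] for b in levels], dtype=float)

    batch_means = np.column_stack([x[:, batches == b].mean(axis=1) for b in levels])
    grand_mean = batch_means @ (n_b / n_samp)
    resid = x - np.column_stack(
        [batch_means[:, list(levels).index(b)] for b in batches]
    )
    var_pooled = (resid**2).sum(axis=1) / n_samp
    var_pooled = var_pooled.clip(min=1e-12)

    s_data = (x - grand_mean[:, None]) / np.sqrt(var_pooled)[:, None]

    bayes = s_data.copy()
    for bi, b in enumerate(levels):
        cols = batches == b
        sb = s_data[:, cols]
        g_hat = sb.mean(axis=1)
        d_hat = sb.var(axis=1, ddof=1)
        g_bar, t2 = float(g_hat.mean()), float(g_hat.var(ddof=1))
        m, s2 = float(d_hat.mean()), float(d_hat.var(ddof=1))
        if mean_only or s2 <= 0 or t2 <= 0:
            n = float(cols.sum())
            g_star = (t2 * n * g_hat + 1.0 * g_bar) / (t2 * n + 1.0) if t2 > 0 else g_hat
            d_star = np.ones(n_feat)
        else:
            a_prior = (2.0 * s2 + m**2) / s2
            b_prior = (m * s2 + m**3) / s2
            g_star, d_star = _combat_it_sol(sb, g_hat, d_hat, g_bar, t2, a_prior, b_prior)
        bayes[:, cols] = (sb - g_star[:, None]) / np.sqrt(d_star)[:, None]

    adjusted = bayes * np.sqrt(var_pooled)[:, None] + grand_mean[:, None]
    out = pd.DataFrame(
        2.0**adjusted, index=table.intensities.index, columns=table.intensities.columns
    )
    return table.with_values(out)
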