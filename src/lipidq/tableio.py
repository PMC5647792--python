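"""Peak-table and sample-sheet I/O and the shared in-memory data model.

The central object is :class:`FeatureTable`: a features × injections
intensity grid (``NaN`` marks a missing cell) plus per-feature metadata
(m/z in Da, retention time in minutes, ion mode).  Every processing stage
consumes and returns this object; positive- and negative-mode tables are
handled as independent instances end to end.

On-disk formats are plain CSV: the peak table has the feature-metadata
columns (``feature_id``, ``mz``, ``rt``, ``ion_mode``) followed by one
column per injection, mirroring what feature-extraction software exports;
the sample sheet has one row per injection.  Whether an on-disk ``0`` or
an empty cell means "missing" varies between export dialects, so the
reader takes an explicit ``missing_policy`` and never guesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "SampleInfo",
    "read_peak_table",
    "read_sample_info",
    "write_peak_table",
    "write_sample_info",
    "write_results",
    "validate_samples",
]

META_COLUMNS = ("feature_id", "mz", "rt", "ion_mode")
SAMPLE_COLUMNS = ("sample_id", "role", "group", "batch", "injection_order")

ROLES = frozenset({"study", "qc"})
GROUPS = frozenset({"healthy", "disease", "none"})
ION_MODES = frozenset({"positive", "negative"})


@dataclass
class FeatureTable:
    """Intensity matrix plus feature metadata.

    Parameters
    ----------
    intensities
        DataFrame of shape (n_features, n_injections); index is the
        feature id, columns are injection/sample ids.  Missing cells are
        ``NaN``; observed cells are nonnegative floats.
    features
        DataFrame indexed by feature id with columns ``mz`` (Da), ``rt``
        (minutes) and ``ion_mode`` ("positive" / "negative").
    """

    intensities: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------
    def validate(self) -> None:
        ids = self.intensities.index
        if ids.has_duplicates:
            dups = ids[ids.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if not ids.equals(self.features.index):
            raise ValueError("intensity rows and feature metadata do not align")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("negative intensities are not allowed")
        mz = self.features["mz"].to_numpy(dtype=float)
        rt = self.features["rt"].to_numpy(dtype=float)
        if np.any(mz <= 0):
            raise ValueError("m/z must be positive")
        if np.any(rt < 0):
            raise ValueError("retention time must be nonnegative")
        bad = set(self.features["ion_mode"]) - ION_MODES
        if bad:
            raise ValueError(f"unknown ion mode(s): {sorted(bad)}")

    # -- convenience ------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_injections(self) -> int:
        return self.intensities.shape[1]

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.intensities.copy(), self.features.copy())

    def subset(self, ids: Sequence[str]) -> "FeatureTable":
        ids = list(ids)
        missing = [i for i in ids if i not in self.intensities.index]
        if missing:
            raise KeyError(f"unknown feature ids: {missing[:5]}")
        return FeatureTable(self.intensities.loc[ids], self.features.loc[ids])

    def with_values(self, values: pd.DataFrame) -> "FeatureTable":
        """Return a new table with the same metadata and new intensities."""
        return FeatureTable(values, self.features.copy())


@dataclass(frozen=True)
class SampleInfo:
    """One injection: identity, role, group, batch and run-order slot."""

    sample_id: str
    role: Literal["study", "qc"]
    group: Literal["healthy", "disease", "none"]
    batch: int
    injection_order: int
    pasi: float | None = None


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet; returns it with canonical dtypes.

    Raises ``ValueError`` on a missing column, duplicate injection order,
    unknown role/group token, a QC row carrying a group label, or a
    non-positive batch/order.
    """
    for col in SAMPLE_COLUMNS:
        if col not in samples.columns:
            raise ValueError(f"sample sheet is missing required column '{col}'")
    out = samples.copy()
    out["batch"] = out["batch"].astype(int)
    out["injection_order"] = out["injection_order"].astype(int)
    if "pasi" not in out.columns:
        out["pasi"] = np.nan
    out["pasi"] = pd.to_numeric(out["pasi"], errors="coerce")

    if out["injection_order"].duplicated().any():
        dup = out.loc[out["injection_order"].duplicated(), "injection_order"].tolist()
        raise ValueError(f"duplicate injection_order values: {dup[:5]}")
    if (out["injection_order"] < 1).any() or (out["batch"] < 1).any():
        raise ValueError("batch and injection_order must be positive integers")
    bad_role = set(out["role"]) - ROLES
    if bad_role:
        raise ValueError(f"unknown role token(s): {sorted(bad_role)}")
    bad_group = set(out["group"]) - GROUPS
    if bad_group:
        raise ValueError(f"unknown group token(s): {sorted(bad_group)}")
    qc_grouped = out[(out["role"] == "qc") & (out["group"] != "none")]
    if len(qc_grouped):
        raise ValueError(
            f"QC injections must have group 'none': {qc_grouped['sample_id'].tolist()[:5]}"
        )
    healthy_pasi = out[(out["group"] == "healthy") & out["pasi"].notna()]
    if len(healthy_pasi):
        raise ValueError("PASI may only be present for disease samples")
    return out


def sample_records(samples: pd.DataFrame) -> list[SampleInfo]:
    """Sample sheet rows as typed records (validates first)."""
    samples = validate_samples(samples)
    recs = []
    for row in samples.itertuples(index=False):
        pasi = getattr(row, "pasi", np.nan)
        recs.append(
            SampleInfo(
                sample_id=str(row.sample_id),
                role=row.role,
                group=row.group,
                batch=int(row.batch),
                injection_order=int(row.injection_order),
                pasi=None if pd.isna(pasi) else float(pasi),
            )
        )
    return recs


def read_peak_table(
    path: str | Path,
    missing_policy: Literal["empty", "zero"] = "empty",
) -> FeatureTable:
    """Read a wide peak-intensity CSV into a :class:`FeatureTable`.

    ``missing_policy`` controls how the export encodes a missing cell:
    ``"empty"`` (blank cell; an explicit 0 is a real intensity) or
    ``"zero"`` (0 additionally treated as missing).
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype={"feature_id": str})
    for col in META_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"peak table is missing metadata column '{col}'")
    injection_cols = [c for c in raw.columns if c not in META_COLUMNS]
    if not injection_cols:
        raise ValueError("peak table has no injection columns")
    if raw["feature_id"].duplicated().any():
        dups = raw.loc[raw["feature_id"].duplicated(), "feature_id"].tolist()
        raise ValueError(f"duplicate feature ids: {dups[:5]}")

    grid = raw[injection_cols].copy()
    for col in injection_cols:
        coerced = pd.to_numeric(grid[col], errors="coerce")
        bad = coerced.isna() & grid[col].notna() & (grid[col].astype(str).str.strip() != "")
        if bad.any():
            row = raw.loc[bad, "feature_id"].iloc[0]
            raise ValueError(
                f"non-numeric intensity at feature '{row}', injection '{col}'"
            )
        grid[col] = coerced
    if missing_policy == "zero":
        grid = grid.mask(grid == 0)
    elif missing_policy != "empty":
        raise ValueError(f"unknown missing_policy '{missing_policy}'")

    features = raw[list(META_COLUMNS)].set_index("feature_id")
    features["mz"] = features["mz"].astype(float)
    features["rt"] = features["rt"].astype(float)
    grid.index = features.index
    return FeatureTable(grid.astype(float), features)


def write_peak_table(table: FeatureTable, path: str | Path) -> Path:
    """Write a :class:`FeatureTable` as the wide CSV ``read_peak_table`` reads.

    Missing cells are written as empty strings (the ``"empty"`` policy).
    """
    path = Path(path)
    out = table.features.reset_index()
    out = pd.concat([out, table.intensities.reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False, float_format="%.6f")
    return path


def read_sample_info(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample sheet CSV."""
    samples = pd.read_csv(Path(path), dtype={"sample_id": str})
    return validate_samples(samples)


def write_sample_info(samples: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_samples(samples).to_csv(path, index=False)
    return path


# formatting for the results TSV: masses to 6 decimals, ratios/AUC to 2,
# p/q in scientific notation
_RESULT_FORMATS: Mapping[str, str] = {
    "mz": "{:.6f}",
    "neutral_mass": "{:.6f}",
    "theoretical_mz": "{:.6f}",
    "rt": "{:.2f}",
    "ratio": "{:.2f}",
    "auc": "{:.2f}",
    "ci_low": "{:.2f}",
    "ci_high": "{:.2f}",
    "vip": "{:.2f}",
    "p_value": "{:.6g}",
    "q_value": "{:.6g}",
    "ppm_error": "{:.2f}",
}


def write_results(path: str | Path, records: Iterable[Mapping] | pd.DataFrame) -> Path:
    """Write per-feature result records as TSV.

    Column order follows the first record; known numeric columns are
    formatted at conventional precision (6 decimals for masses, 2 for
    ratios/AUC/VIP, scientific notation for p and q).
    """
    path = Path(path)
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records))
    out = records.copy()
    for col, fmt in _RESULT_FORMATS.items():
        if col in out.columns:
            out[col] = out[col].map(
                lambda v, fmt=fmt: "" if pd.isna(v) else fmt.format(float(v))
            )
    out.to_csv(path, sep="\t", index=False)
    return path
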