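"""In-memory containers for LC-MS peak tables and sample run metadata.

A :class:`PeakTable` couples a per-feature annotation frame (compound name,
formula, m/z, retention time, ionization mode) with a features × samples
intensity matrix. A :class:`SampleMetadata` records, per sample, the
injection order within the analytical run, the sample type (``study``,
``qc`` or ``blank``) and, for study samples, the binary outcome label
(1 = serum creatinine > 1.5 mg/dL at six months).

Both are thin, validated wrappers around :class:`pandas.DataFrame` with a
documented CSV dialect; all operations elsewhere in the package treat them
as immutable and return new objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import MetadataError, PeakTableError

FEATURE_COLUMNS = ["compound", "formula", "mz", "rt", "mode"]
SAMPLE_TYPES = ("study", "qc", "blank")


@dataclass
class PeakTable:
    """Feature annotations plus a features × samples intensity matrix.

    Parameters
    ----------
    features : pandas.DataFrame
        Indexed by unique ``feature_id``; columns ``compound``, ``formula``,
        ``mz`` (mass-to-charge), ``rt`` (retention time, minutes) and
        ``mode`` (``pos`` or ``neg``).
    intensities : pandas.DataFrame
        Same index as ``features``; one column per sample id. Non-negative
        floats; NaN marks a missing measurement.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.features.index.is_unique:
            dupes = self.features.index[self.features.index.duplicated()].tolist()
            raise PeakTableError(f"duplicate feature_id(s): {dupes}")
        if not self.intensities.columns.is_unique:
            dupes = self.intensities.columns[self.intensities.columns.duplicated()].tolist()
            raise PeakTableError(f"duplicate sample id(s): {dupes}")
        if not self.features.index.equals(self.intensities.index):
            raise PeakTableError("features and intensities must share the same feature index")
        missing_cols = [c for c in FEATURE_COLUMNS if c not in self.features.columns]
        if missing_cols:
            raise PeakTableError(f"feature table missing columns: {missing_cols}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            rows, cols = np.where(np.nan_to_num(vals, nan=0.0) < 0)
            fid = self.features.index[rows[0]]
            sid = self.intensities.columns[cols[0]]
            raise PeakTableError(f"negative intensity at feature {fid!r}, sample {sid!r}")

    # ------------------------------------------------------------------
    @property
    def feature_ids(self) -> list:
        return list(self.features.index)

    @property
    def sample_ids(self) -> list:
        return list(self.intensities.columns)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def copy(self) -> "PeakTable":
        return PeakTable(self.features.copy(), self.intensities.copy())

    def subset_features(self, feature_ids) -> "PeakTable":
        ids = list(feature_ids)
        unknown = [f for f in ids if f not in self.features.index]
        if unknown:
            raise PeakTableError(f"unknown feature id(s): {unknown}")
        return PeakTable(self.features.loc[ids].copy(), self.intensities.loc[ids].copy())

    def subset_samples(self, sample_ids) -> "PeakTable":
        ids = list(sample_ids)
        unknown = [s for s in ids if s not in self.intensities.columns]
        if unknown:
            raise PeakTableError(f"unknown sample id(s): {unknown}")
        return PeakTable(self.features.copy(), self.intensities[ids].copy())

    def with_intensities(self, values: np.ndarray) -> "PeakTable":
        """Return a copy whose intensity values are replaced (same shape/labels)."""
        new = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=self.intensities.index,
            columns=self.intensities.columns,
        )
        return PeakTable(self.features.copy(), new)

    def equals(self, other: "PeakTable") -> bool:
        return self.features.equals(other.features) and self.intensities.equals(
            other.intensities
        )

    # ------------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write the documented dialect: one row per feature, annotation
        columns first, then one intensity column per sample."""
        out = pd.concat([self.features, self.intensities], axis=1)
        out.index.name = "feature_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "PeakTable":
        raw = pd.read_csv(path, dtype={"feature_id": str}, keep_default_na=True)
        if "feature_id" not in raw.columns:
            raise PeakTableError(f"{path}: missing required column 'feature_id'")
        missing = [c for c in FEATURE_COLUMNS if c not in raw.columns]
        if missing:
            raise PeakTableError(f"{path}: missing required column(s) {missing}")
        raw = raw.set_index("feature_id")
        features = raw[FEATURE_COLUMNS].copy()
        features["compound"] = features["compound"].fillna("")
        features["formula"] = features["formula"].fillna("")
        intensities = raw.drop(columns=FEATURE_COLUMNS).astype(float)
        return cls(features, intensities)


@dataclass
class SampleMetadata:
    """Per-sample run structure and outcome labels.

    Wraps a frame indexed by unique ``sample_id`` with columns
    ``injection_order`` (positive int, unique across the run),
    ``sample_type`` (``study``/``qc``/``blank``) and ``outcome_label``
    (0/1 for study samples, missing for QC and blank).
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        if not df.index.is_unique:
            dupes = df.index[df.index.duplicated()].tolist()
            raise MetadataError(f"duplicate sample id(s): {dupes}")
        for col in ("injection_order", "sample_type", "outcome_label"):
            if col not in df.columns:
                raise MetadataError(f"metadata missing column {col!r}")
        df["sample_type"] = df["sample_type"].astype(str).str.lower()
        bad_type = df.loc[~df["sample_type"].isin(SAMPLE_TYPES), "sample_type"]
        if len(bad_type):
            raise MetadataError(f"unknown sample_type value(s): {sorted(set(bad_type))}")
        orders = df["injection_order"]
        if orders.isna().any() or (orders <= 0).any():
            raise MetadataError("injection_order must be a positive integer for every sample")
        if orders.duplicated().any():
            raise MetadataError("injection orders must be unique across the run")
        df["injection_order"] = orders.astype(int)
        study = df["sample_type"] == "study"
        labels = df["outcome_label"]
        if labels[study].isna().any():
            missing = df.index[study & labels.isna()].tolist()
            raise MetadataError(f"study sample(s) without outcome label: {missing}")
        if not labels[study].isin([0, 1]).all():
            raise MetadataError("outcome_label must be 0 or 1 for study samples")
        if labels[~study].notna().any():
            labelled = df.index[~study & labels.notna()].tolist()
            raise MetadataError(f"QC/blank sample(s) must not carry outcome labels: {labelled}")

    # ------------------------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    def ids_of_type(self, sample_type: str) -> list:
        """Sample ids of one type, in injection order."""
        sub = self.frame[self.frame["sample_type"] == sample_type]
        return list(sub.sort_values("injection_order").index)

    @property
    def study_ids(self) -> list:
        return self.ids_of_type("study")

    @property
    def qc_ids(self) -> list:
        return self.ids_of_type("qc")

    @property
    def blank_ids(self) -> list:
        return self.ids_of_type("blank")

    def injection_order(self, sample_ids) -> np.ndarray:
        return self.frame.loc[list(sample_ids), "injection_order"].to_numpy(dtype=float)

    def outcome(self, sample_ids=None) -> np.ndarray:
        """Binary outcome vector (1 = creatinine > 1.5 mg/dL) for study samples."""
        ids = self.study_ids if sample_ids is None else list(sample_ids)
        y = self.frame.loc[ids, "outcome_label"]
        if y.isna().any():
            raise MetadataError("outcome requested for unlabelled (non-study) samples")
        return y.to_numpy(dtype=float)

    def copy(self) -> "SampleMetadata":
        return SampleMetadata(self.frame.copy())

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.index.name = "sample_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SampleMetadata":
        raw = pd.read_csv(path, dtype={"sample_id": str})
        if "sample_id" not in raw.columns:
            raise MetadataError(f"{path}: missing required column 'sample_id'")
        return cls(raw.set_index("sample_id"))


def impute_missing(table: PeakTable, strategy: str = "half_min_feature") -> PeakTable:
    """Fill missing intensities.

    ``half_min_feature`` replaces each NaN with half the smallest observed
    intensity of that feature (a conventional stand-in for values below the
    detection limit); ``none`` returns the table unchanged, leaving any NaN
    for downstream steps to reject.
    """
    if strategy not in ("half_min_feature", "none"):
        raise PeakTableError(f"unknown imputation strategy {strategy!r}")
    if strategy == "none" or not table.intensities.isna().any().any():
        return table.copy()
    vals = table.intensities.to_numpy(dtype=float)
    all_missing = np.isnan(vals).all(axis=1)
    if all_missing.any():
        ids = [table.feature_ids[i] for i in np.where(all_missing)[0]]
        raise PeakTableError(f"feature(s) entirely missing, cannot impute: {ids}")
    fill = 0.5 * np.nanmin(vals, axis=1)
    filled = np.where(np.isnan(vals), fill[:, None], vals)
    return table.with_intensities(filled)
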