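"""Peak-table preprocessing: QC-based filtering, drift correction, merging
and autoscaling.

The canonical order, mirroring routine LC-MS practice for a single-batch
run with pooled QC injections, is::

    read -> impute -> qc_cv_filter -> loess_drift_correct -> merge -> autoscale

Every step is pure: inputs are never modified, a new object is returned.
Blank samples are carried through the tables but never enter any
computation (CVs, LOESS fits or scaling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .exceptions import PreprocessError
from .peaks import PeakTable, SampleMetadata, impute_missing


@dataclass
class FilterReport:
    """Per-feature QC coefficient of variation and the retention decision."""

    frame: pd.DataFrame  # index feature_id; columns qc_cv_pct, retained, note
    threshold_pct: float

    @property
    def retained_ids(self) -> list:
        return list(self.frame.index[self.frame["retained"]])

    @property
    def n_retained(self) -> int:
        return int(self.frame["retained"].sum())

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["threshold_pct"] = self.threshold_pct
        out.index.name = "feature_id"
        out.to_csv(path)


@dataclass
class ScaledMatrix:
    """Autoscaled samples × features matrix with its centering/scale.

    ``X`` holds study samples only, each column mean-centered and divided
    by its sample (n−1) standard deviation, so fitted coefficients are on
    the standardized scale. ``center``/``scale`` are stored for applying the
    training transform to new data at prediction time.
    """

    X: np.ndarray
    feature_ids: list
    sample_ids: list
    center: np.ndarray
    scale: np.ndarray

    @property
    def shape(self):
        return self.X.shape

    def transform(self, raw: np.ndarray) -> np.ndarray:
        """Apply the stored center/scale to a raw samples × features array."""
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        if raw.shape[1] != len(self.feature_ids):
            raise PreprocessError(
                f"expected {len(self.feature_ids)} features, got {raw.shape[1]}"
            )
        return (raw - self.center) / self.scale


def _qc_matrix(table: PeakTable, metadata: SampleMetadata) -> np.ndarray:
    qc_ids = [s for s in metadata.qc_ids if s in table.intensities.columns]
    if len(qc_ids) < 2:
        raise PreprocessError(f"need at least 2 QC samples, found {len(qc_ids)}")
    return table.intensities[qc_ids].to_numpy(dtype=float), qc_ids


def qc_cv_filter(
    table: PeakTable, metadata: SampleMetadata, threshold_pct: float = 30.0
):
    """Drop features whose QC replicate CV exceeds ``threshold_pct``.

    CV% = 100 · sd(QC intensities, ddof=1) / mean(QC intensities), per
    feature. The comparison is strict: a feature at exactly the threshold is
    retained. A feature whose QC mean is zero has no defined CV and is
    excluded with the note ``undefined CV``.

    Returns the filtered table and a :class:`FilterReport` covering every
    input feature.
    """
    qc, _ = _qc_matrix(table, metadata)
    if np.isnan(qc).any():
        raise PreprocessError("QC intensities contain missing values; impute first")
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv_pct = 100.0 * sd / mean
    undefined = mean == 0
    retained = ~undefined & (cv_pct <= threshold_pct)
    note = np.where(undefined, "undefined CV", "")
    report = FilterReport(
        pd.DataFrame(
            {
                "qc_cv_pct": np.where(undefined, np.nan, cv_pct),
                "retained": retained,
                "note": note,
            },
            index=table.features.index,
        ),
        threshold_pct=float(threshold_pct),
    )
    kept = [fid for fid, keep in zip(table.feature_ids, retained) if keep]
    return table.subset_features(kept), report


def loess_drift_correct(
    table: PeakTable,
    metadata: SampleMetadata,
    span: float = 0.75,
) -> PeakTable:
    """QC-anchored LOESS (QC-RLSC) correction of injection-order drift.

    Per feature, a degree-1 locally weighted regression (tricube weights,
    window fraction ``span``) of QC intensity on injection order is fitted;
    the fitted trend is evaluated at every sample's injection order by
    linear interpolation between QC anchors, held flat beyond the first and
    last QC. Each intensity is multiplied by ``reference / trend`` where the
    reference is that feature's median QC intensity, so a drift-free feature
    is returned unchanged up to floating point.

    A feature whose fitted trend is non-positive anywhere is left
    uncorrected and a warning names it. Requires at least 4 QC injections.
    """
    qc_ids = [s for s in metadata.qc_ids if s in table.intensities.columns]
    if len(qc_ids) < 4:
        raise PreprocessError(
            f"LOESS drift correction needs >= 4 QC samples, found {len(qc_ids)}"
        )
    vals = table.intensities.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise PreprocessError("intensities contain missing values; impute first")
    qc_order = metadata.injection_order(qc_ids)
    sort = np.argsort(qc_order)
    qc_order = qc_order[sort]
    qc_ids = [qc_ids[i] for i in sort]
    qc_vals = table.intensities[qc_ids].to_numpy(dtype=float)
    all_order = metadata.injection_order(table.sample_ids)

    corrected = vals.copy()
    flagged = []
    for i, fid in enumerate(table.feature_ids):
        fit = lowess(qc_vals[i], qc_order, frac=span, it=0, return_sorted=False)
        trend = np.interp(all_order, qc_order, fit)  # flat beyond first/last QC
        if np.any(trend <= 0):
            flagged.append(fid)
            continue
        reference = np.median(qc_vals[i])
        corrected[i] = vals[i] * (reference / trend)
    if flagged:
        warnings.warn(
            f"non-positive LOESS trend; left uncorrected: {flagged}", stacklevel=2
        )
    return table.with_intensities(corrected)


def merge_ion_modes(pos: PeakTable, neg: PeakTable) -> PeakTable:
    """Concatenate positive- and negative-mode tables feature-wise.

    Both tables must cover exactly the same samples; the merged table uses
    the positive table's sample order. Feature ids are kept as-is when the
    two id sets are disjoint and are prefixed with their ionization mode
    (``pos_`` / ``neg_``) when they collide, so ids are always unique.
    """
    pos_samples, neg_samples = set(pos.sample_ids), set(neg.sample_ids)
    if pos_samples != neg_samples:
        only_pos = sorted(pos_samples - neg_samples)
        only_neg = sorted(neg_samples - pos_samples)
        raise PreprocessError(
            f"sample sets differ between modes; only in pos: {only_pos}, "
            f"only in neg: {only_neg}"
        )
    if neg.n_features == 0:
        return pos.copy()
    if pos.n_features == 0:
        return neg.subset_samples(pos.sample_ids)
    p, n = pos.copy(), neg.subset_samples(pos.sample_ids)
    if set(p.features.index) & set(n.features.index):
        p.features.index = ["pos_" + str(f) for f in p.features.index]
        p.intensities.index = p.features.index
        n.features.index = ["neg_" + str(f) for f in n.features.index]
        n.intensities.index = n.features.index
    return PeakTable(
        pd.concat([p.features, n.features]), pd.concat([p.intensities, n.intensities])
    )


def autoscale(
    table: PeakTable, metadata: SampleMetadata, log_transform: bool = False
) -> ScaledMatrix:
    """Autoscale (unit-variance scale) the study samples of a peak table.

    Produces the samples × features matrix X for PLS-DA: study samples only
    (QCs and blanks dropped), each feature mean-centered and divided by its
    sample SD. ``log_transform`` applies a natural log before scaling for
    users who prefer modelling on the log scale; the default is off.
    """
    study_ids = [s for s in metadata.study_ids if s in table.intensities.columns]
    if len(study_ids) < 2:
        raise PreprocessError("autoscaling needs at least 2 study samples")
    X = table.intensities[study_ids].to_numpy(dtype=float).T  # samples x features
    if np.isnan(X).any():
        raise PreprocessError("intensities contain missing values; impute first")
    if log_transform:
        if np.any(X <= 0):
            raise PreprocessError("log transform requires strictly positive intensities")
        X = np.log(X)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    zero = scale == 0
    if zero.any():
        ids = [table.feature_ids[j] for j in np.where(zero)[0]]
        raise PreprocessError(f"zero-variance feature(s), drop before scaling: {ids}")
    return ScaledMatrix(
        X=(X - center) / scale,
        feature_ids=list(table.feature_ids),
        sample_ids=study_ids,
        center=center,
        scale=scale,
    )


def run_preprocess(
    pos: PeakTable,
    metadata: SampleMetadata,
    neg: PeakTable | None = None,
    cv_threshold_pct: float = 30.0,
    loess_span: float = 0.75,
    order: str = "filter_then_correct",
    impute_strategy: str = "half_min_feature",
    log_transform: bool = False,
):
    """Full preprocessing chain on one or two (pos/neg mode) peak tables.

    ``order`` selects whether the QC-CV filter runs before
    (``filter_then_correct``, the default) or after
    (``correct_then_filter``) LOESS drift correction; both orders are in
    routine use and the choice is reported alongside the result.

    Returns ``(ScaledMatrix, FilterReport, y)`` where ``y`` is the study
    outcome vector aligned with the matrix rows.
    """
    if order not in ("filter_then_correct", "correct_then_filter"):
        raise PreprocessError(f"unknown preprocessing order {order!r}")

    def one_mode(tab: PeakTable):
        tab = impute_missing(tab, impute_strategy)
        if order == "filter_then_correct":
            tab, rep = qc_cv_filter(tab, metadata, cv_threshold_pct)
            tab = loess_drift_correct(tab, metadata, loess_span)
        else:
            tab = loess_drift_correct(tab, metadata, loess_span)
            tab, rep = qc_cv_filter(tab, metadata, cv_threshold_pct)
        return tab, rep

    pos_f, pos_rep = one_mode(pos)
    if neg is not None and neg.n_features > 0:
        neg_f, neg_rep = one_mode(neg)
        merged = merge_ion_modes(pos_f, neg_f)
        report = FilterReport(
            pd.concat([pos_rep.frame, neg_rep.frame]), float(cv_threshold_pct)
        )
    else:
        merged, report = pos_f, pos_rep
    scaled = autoscale(merged, metadata, log_transform=log_transform)
    y = metadata.outcome(scaled.sample_ids)
    return scaled, report, y
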