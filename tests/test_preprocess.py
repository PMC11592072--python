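"""Preprocessing: QC-CV filter, LOESS drift correction, merging, autoscaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabopls import (
    CohortSimConfig,
    PeakTable,
    PreprocessError,
    SampleMetadata,
    autoscale,
    generate_cohort,
    inject_drift,
    loess_drift_correct,
    merge_ion_modes,
    qc_cv_filter,
)


def _table(qc_rows: dict, study_rows: dict | None = None):
    """Build a table whose QC intensities per feature are given explicitly."""
    study_rows = study_rows or {f: [1.0, 2.0] for f in qc_rows}
    ids = list(qc_rows)
    feats = pd.DataFrame(
        {
            "compound": ids,
            "formula": [""] * len(ids),
            "mz": np.arange(len(ids), dtype=float) + 100,
            "rt": np.arange(len(ids), dtype=float) + 1,
            "mode": ["pos"] * len(ids),
        },
        index=pd.Index(ids, name="feature_id"),
    )
    n_qc = len(next(iter(qc_rows.values())))
    n_study = len(next(iter(study_rows.values())))
    cols = {}
    for i in range(n_study):
        cols[f"S{i + 1}"] = [study_rows[f][i] for f in ids]
    for i in range(n_qc):
        cols[f"Q{i + 1}"] = [qc_rows[f][i] for f in ids]
    intens = pd.DataFrame(cols, index=feats.index, dtype=float)
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "injection_order": np.arange(1, n_study + n_qc + 1),
                "sample_type": ["study"] * n_study + ["qc"] * n_qc,
                "outcome_label": [float(i % 2) for i in range(n_study)]
                + [np.nan] * n_qc,
            },
            index=pd.Index(list(cols), name="sample_id"),
        )
    )
    return PeakTable(feats, intens), meta


class TestQcCvFilter:
    def test_worked_examples(self):
        """CV 0% kept; CV 50% dropped; CV exactly 30% kept (strict rule)."""
        # (50,100,150): sd=50, mean=100 -> CV 50%
        # choose QCs with sd/mean = 0.30 exactly: (70, 100, 130) has sd 30
        table, meta = _table(
            {
                "zero_cv": [100.0, 100.0, 100.0],
                "fifty_cv": [50.0, 100.0, 150.0],
                "thirty_cv": [70.0, 100.0, 130.0],
            }
        )
        filtered, report = qc_cv_filter(table, meta, threshold_pct=30.0)
        assert report.frame.loc["zero_cv", "qc_cv_pct"] == pytest.approx(0.0)
        assert report.frame.loc["fifty_cv", "qc_cv_pct"] == pytest.approx(50.0)
        assert report.frame.loc["thirty_cv", "qc_cv_pct"] == pytest.approx(30.0)
        assert filtered.feature_ids == ["zero_cv", "thirty_cv"]

    def test_zero_mean_flagged_undefined(self):
        table, meta = _table({"dead": [0.0, 0.0, 0.0], "ok": [10.0, 10.0, 10.0]})
        filtered, report = qc_cv_filter(table, meta)
        assert filtered.feature_ids == ["ok"]
        assert report.frame.loc["dead", "note"] == "undefined CV"

    def test_fewer_than_two_qcs_rejected(self):
        table, meta = _table({"f": [1.0]})
        with pytest.raises(PreprocessError, match="2 QC"):
            qc_cv_filter(table, meta)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_threshold_monotonicity(self, seed):
        """A stricter threshold never retains more features."""
        rng = np.random.default_rng(seed)
        table, meta = _table(
            {f"f{j}": list(rng.uniform(50, 150, 4)) for j in range(12)}
        )
        counts = [
            qc_cv_filter(table, meta, thr)[1].n_retained for thr in (10, 20, 30, 50)
        ]
        assert counts == sorted(counts)

    def test_filter_and_merge_commute(self):
        rng = np.random.default_rng(0)
        pos, meta = _table({f"p{j}": list(rng.uniform(50, 150, 4)) for j in range(8)})
        neg_tab, _ = _table({f"n{j}": list(rng.uniform(50, 150, 4)) for j in range(8)})
        merged_then_filtered, _ = qc_cv_filter(merge_ion_modes(pos, neg_tab), meta, 30)
        fp, _ = qc_cv_filter(pos, meta, 30)
        fn, _ = qc_cv_filter(neg_tab, meta, 30)
        filtered_then_merged = merge_ion_modes(fp, fn)
        assert merged_then_filtered.feature_ids == filtered_then_merged.feature_ids
        assert np.allclose(
            merged_then_filtered.intensities, filtered_then_merged.intensities
        )

    def test_blanks_never_enter_cv(self):
        table, meta = _table({"f": [100.0, 100.0, 100.0]})
        # add a wild blank sample; the CV must stay 0
        intens = table.intensities.copy()
        intens["BL1"] = [1e6]
        frame = meta.frame.copy()
        frame.loc["BL1"] = [len(frame) + 1, "blank", np.nan]
        table2 = PeakTable(table.features, intens)
        meta2 = SampleMetadata(frame)
        _, report = qc_cv_filter(table2, meta2)
        assert report.frame.loc["f", "qc_cv_pct"] == pytest.approx(0.0)


class TestLoessDriftCorrect:
    def _drifted_cohort(self, seed=0):
        table, meta, _ = generate_cohort(
            CohortSimConfig(
                seed=seed, drift_amplitude=0.0, noise_cv_range=(0.05, 0.45)
            )
        )
        drifted = inject_drift(table, meta, lambda o: 1 + 0.01 * o)
        return table, drifted, meta

    def test_flat_qcs_leave_table_unchanged(self):
        table, meta, _ = generate_cohort(
            CohortSimConfig(seed=1, drift_amplitude=0.0, noise_cv_range=(0.0, 0.0))
        )
        out = loess_drift_correct(table, meta)
        assert np.allclose(out.intensities, table.intensities, rtol=1e-9)

    def test_linear_drift_reduces_qc_cv_on_most_features(self):
        """Correcting an injected 1% per-injection linear drift lowers the
        QC CV for at least 95% of features."""
        _, drifted, meta = self._drifted_cohort()
        corrected = loess_drift_correct(drifted, meta, span=0.75)
        qc = meta.qc_ids

        def cvs(tab):
            q = tab.intensities[qc].to_numpy()
            return q.std(axis=1, ddof=1) / q.mean(axis=1)

        improved = cvs(corrected) < cvs(drifted)
        assert improved.mean() >= 0.95

    def test_scale_equivariance(self):
        _, drifted, meta = self._drifted_cohort()
        doubled = drifted.with_intensities(2 * drifted.intensities.to_numpy())
        out1 = loess_drift_correct(drifted, meta)
        out2 = loess_drift_correct(doubled, meta)
        assert np.allclose(out2.intensities, 2 * out1.intensities, rtol=1e-9)

    def test_too_few_qcs_rejected(self, small_table):
        table, meta = small_table
        with pytest.raises(PreprocessError, match="4 QC"):
            loess_drift_correct(table, meta)

    def test_input_not_modified(self):
        _, drifted, meta = self._drifted_cohort()
        before = drifted.intensities.copy()
        loess_drift_correct(drifted, meta)
        assert drifted.intensities.equals(before)


class TestMergeIonModes:
    def test_feature_counts_add(self):
        rng = np.random.default_rng(1)
        pos, _ = _table({f"p{j}": list(rng.uniform(50, 150, 3)) for j in range(150)})
        neg, _ = _table({f"n{j}": list(rng.uniform(50, 150, 3)) for j in range(76)})
        merged = merge_ion_modes(pos, neg)
        assert merged.n_features == 226

    def test_empty_neg_is_identity(self):
        pos, _ = _table({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        empty = pos.subset_features([])
        merged = merge_ion_modes(pos, empty)
        assert merged.equals(pos)

    def test_colliding_ids_kept_distinct(self):
        pos, _ = _table({"same": [1.0, 2.0]})
        neg, _ = _table({"same": [3.0, 4.0]})
        merged = merge_ion_modes(pos, neg)
        assert merged.n_features == 2
        assert set(merged.feature_ids) == {"pos_same", "neg_same"}

    def test_sample_mismatch_lists_difference(self):
        pos, _ = _table({"a": [1.0, 2.0]})
        neg, _ = _table({"b": [1.0, 2.0, 3.0]})
        with pytest.raises(PreprocessError, match="Q3"):
            merge_ion_modes(pos, neg)


class TestAutoscale:
    def test_columns_standardized(self, rng):
        table, meta, _ = generate_cohort(CohortSimConfig(seed=0, n_features=20))
        scaled = autoscale(table, meta)
        assert np.all(np.abs(scaled.X.mean(axis=0)) < 1e-10)
        assert np.all(np.abs(scaled.X.std(axis=0, ddof=1) - 1) < 1e-10)
        assert scaled.X.shape[0] == 48  # study samples only

    def test_closed_form_three_points(self):
        table, meta = _table({"f": [1.0, 1.0]}, study_rows={"f": [1.0, 2.0, 3.0]})
        scaled = autoscale(table, meta)
        assert np.allclose(scaled.X.ravel(), [-1.0, 0.0, 1.0])

    def test_stored_transform_reproduces_matrix(self):
        table, meta, _ = generate_cohort(
            CohortSimConfig(seed=7, n_features=10, n_discriminative=4)
        )
        scaled = autoscale(table, meta)
        raw = table.intensities[scaled.sample_ids].to_numpy().T
        assert np.allclose(scaled.transform(raw), scaled.X)

    def test_zero_variance_feature_listed(self):
        table, meta = _table(
            {"flat": [5.0, 5.0], "ok": [1.0, 2.0]},
            study_rows={"flat": [5.0, 5.0, 5.0], "ok": [1.0, 2.0, 4.0]},
        )
        with pytest.raises(PreprocessError, match="flat"):
            autoscale(table, meta)
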