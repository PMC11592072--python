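"""Model validation and performance reporting.

Three independent checks of a fitted PLS-DA panel:

* a label-permutation test of the model's training R²Y (is the apparent
  fit better than chance relabelings?), with the +1-corrected empirical
  p-value p = (1 + #{R²_perm >= R²_obs}) / (B + 1);
* delete-one jackknife standard errors, t-based confidence intervals and
  p-values for the standardized regression coefficients;
* threshold classification metrics (confusion matrix, accuracy,
  sensitivity, specificity) and the ROC curve with AUC computed by the
  rank (Mann–Whitney) formula, ties counted one half.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ModelError
from .pipeline import PipelineConfig, run_two_stage
from .pls import PLSDA
from .preprocess import ScaledMatrix


def _as_array(X) -> np.ndarray:
    if isinstance(X, ScaledMatrix):
        return np.asarray(X.X, dtype=float)
    return np.atleast_2d(np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# Permutation test


@dataclass
class PermutationResult:
    observed_r2y: float
    permuted_r2y: np.ndarray
    p_value: float
    n_permutations: int
    seed: int | None

    def summary(self) -> str:
        frac = float(np.mean(self.permuted_r2y < self.observed_r2y))
        return (
            f"Permutation test ({self.n_permutations} relabelings)\n"
            f"  observed R2Y: {self.observed_r2y:.4f}\n"
            f"  permuted R2Y exceeded by observed in {frac:.1%} of cases\n"
            f"  empirical p: {self.p_value:.4g}"
        )


def permutation_test(
    X,
    y,
    n_components: int,
    feature_set=None,
    n_permutations: int = 1000,
    seed: int | None = None,
    full_pipeline: bool = False,
    config: PipelineConfig | None = None,
) -> PermutationResult:
    """Empirical significance of the model's R²Y under label permutation.

    By default the final model is refitted at fixed features and component
    count for every permuted label vector — the statistic compares the R²
    obtained with the original response against permuted responses. With
    ``full_pipeline=True`` the entire two-stage procedure (component
    selection and VIP selection) is re-run per permutation, which also
    accounts for selection optimism at substantially higher cost.
    """
    B = int(n_permutations)
    if B < 1:
        raise ModelError("n_permutations must be >= 1")
    Xa = _as_array(X)
    if feature_set is not None:
        Xa = Xa[:, list(feature_set)]
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)

    if full_pipeline:
        cfg = config or PipelineConfig()

        def r2(yv):
            return run_two_stage(Xa, yv, cfg).stage2.r2y

    else:

        def r2(yv):
            return PLSDA(Xa, yv).fit(int(n_components)).r2y

    observed = r2(y)
    permuted = np.empty(B)
    for b in range(B):
        permuted[b] = r2(rng.permutation(y))
    p = (1.0 + float(np.sum(permuted >= observed))) / (B + 1.0)
    return PermutationResult(
        observed_r2y=observed,
        permuted_r2y=permuted,
        p_value=p,
        n_permutations=B,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Jackknife coefficients


@dataclass
class CoefficientTable:
    """Standardized coefficients with jackknife uncertainty.

    Columns: ``coefficient`` (full-data fit), ``jackknife_mean``,
    ``jackknife_se``, ``ci_lower``/``ci_upper`` (t-based, level 1−alpha),
    ``p_value`` (two-sided t with n−1 df) and ``significant``.
    """

    frame: pd.DataFrame
    alpha: float
    n_components: int

    @property
    def feature_ids(self) -> list:
        return list(self.frame.index)

    def to_csv(self, path, annotations: pd.DataFrame | None = None) -> None:
        out = self.frame.copy()
        if annotations is not None:
            out = annotations.reindex(out.index).join(out)
        out.index.name = "feature_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path, alpha: float = 0.05, n_components: int = 0):
        raw = pd.read_csv(path).set_index("feature_id")
        cols = [
            "coefficient",
            "jackknife_mean",
            "jackknife_se",
            "ci_lower",
            "ci_upper",
            "p_value",
            "significant",
        ]
        return cls(raw[cols], alpha=alpha, n_components=n_components)


def jackknife_statistics(estimates: np.ndarray, alpha: float = 0.05):
    """Delete-one jackknife SE, CI and two-sided t p-value.

    ``estimates`` is the n × p array of delete-one statistics. Returns
    ``(mean, se, ci_lower, ci_upper, p)`` with
    SE_j = sqrt((n−1)/n · Σ_i (b_(i)j − b̄_j)²) and the CI/p using the t
    distribution with n−1 degrees of freedom.
    """
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    n = est.shape[0]
    mean = est.mean(axis=0)
    se = np.sqrt((n - 1) / n * np.sum((est - mean) ** 2, axis=0))
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    lo, hi = mean - tcrit * se, mean + tcrit * se
    p = np.empty_like(mean)
    nonzero_se = se > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(nonzero_se, mean / np.where(nonzero_se, se, 1.0), np.inf)
    p[nonzero_se] = 2 * stats.t.sf(np.abs(tstat[nonzero_se]), n - 1)
    # degenerate folds: identical estimate in every fit
    p[~nonzero_se] = np.where(mean[~nonzero_se] != 0, 0.0, 1.0)
    return mean, se, lo, hi, p


def jackknife_coefficients(
    X,
    y,
    n_components: int,
    alpha: float = 0.05,
    feature_ids=None,
) -> CoefficientTable:
    """Jackknife the standardized PLS coefficients by delete-one refits.

    Each leave-one-out refit re-autoscales its training fold, so every
    coefficient vector is on its fold's standardized scale; the full-data
    coefficient (same re-scaling) is reported alongside the jackknife mean
    since published tables may print either.
    """
    Xa = _as_array(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xa.shape
    if n < 3:
        raise ModelError("jackknife needs at least 3 samples")
    ids = list(feature_ids) if feature_ids is not None else [f"x{j}" for j in range(p)]

    def coef(mask):
        Xi, yi = Xa[mask], y[mask]
        center = Xi.mean(axis=0)
        scale = Xi.std(axis=0, ddof=1)
        if np.any(scale == 0):
            raise ModelError("zero-variance feature in a jackknife fold")
        return PLSDA((Xi - center) / scale, yi).fit(int(n_components)).coefficients

    full = coef(np.ones(n, dtype=bool))
    boots = np.empty((n, p))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        boots[i] = coef(mask)
    mean, se, lo, hi, pval = jackknife_statistics(boots, alpha)
    frame = pd.DataFrame(
        {
            "coefficient": full,
            "jackknife_mean": mean,
            "jackknife_se": se,
            "ci_lower": lo,
            "ci_upper": hi,
            "p_value": pval,
            "significant": pval < alpha,
        },
        index=pd.Index(ids, name="feature_id"),
    )
    return CoefficientTable(frame, alpha=alpha, n_components=int(n_components))


# ---------------------------------------------------------------------------
# Classification metrics / ROC


@dataclass
class PerformanceReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc_points: pd.DataFrame = field(repr=False)  # columns threshold, fpr, tpr
    cutoff: float = 0.5

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "cutoff": self.cutoff,
        }

    def summary(self) -> str:
        return (
            f"Classification at cutoff {self.cutoff}\n"
            f"  TP={self.tp} TN={self.tn} FP={self.fp} FN={self.fn}\n"
            f"  accuracy   : {self.accuracy:.4f}\n"
            f"  sensitivity: {self.sensitivity:.4f}\n"
            f"  specificity: {self.specificity:.4f}\n"
            f"  AUC        : {self.auc:.4f}"
        )


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Accuracy, sensitivity and specificity from raw confusion counts."""
    n = tp + tn + fp + fn
    if n == 0:
        raise ModelError("empty confusion matrix")
    return {
        "accuracy": (tp + tn) / n,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


def _rank_auc(y: np.ndarray, score: np.ndarray) -> float:
    """Mann–Whitney AUC: P(score_pos > score_neg) + ½ P(tie)."""
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    ranks = stats.rankdata(score)  # midranks -> ties counted one half
    r1 = float(np.sum(ranks[y == 1]))
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def roc_curve(y: np.ndarray, score: np.ndarray) -> pd.DataFrame:
    """ROC points from sweeping every distinct prediction value.

    A sample is called positive when its score is >= the threshold; the
    frame runs from (0, 0) (threshold +inf) to (1, 1).
    """
    y = np.asarray(y, dtype=float).ravel()
    score = np.asarray(score, dtype=float).ravel()
    thresholds = np.concatenate(([np.inf], np.unique(score)[::-1]))
    n1 = float(np.sum(y == 1))
    n0 = float(np.sum(y == 0))
    rows = []
    for thr in thresholds:
        call = score >= thr
        rows.append(
            {
                "threshold": thr,
                "fpr": float(np.sum(call & (y == 0))) / n0,
                "tpr": float(np.sum(call & (y == 1))) / n1,
            }
        )
    return pd.DataFrame(rows)


def classification_metrics(
    labels, predictions, cutoff: float = 0.5
) -> PerformanceReport:
    """Confusion matrix, accuracy/sensitivity/specificity, ROC and AUC.

    ``predictions`` are continuous model outputs; a sample is classified as
    positive (class 1, creatinine > 1.5 mg/dL) when its prediction is at or
    above the cutoff. The AUC uses the rank formula and, by construction,
    equals the trapezoidal area under the returned ROC points.
    """
    y = np.asarray(labels, dtype=float).ravel()
    s = np.asarray(predictions, dtype=float).ravel()
    if y.shape != s.shape:
        raise ModelError(f"{y.size} labels vs {s.size} predictions")
    if np.isnan(s).any():
        raise ModelError("predictions contain NaN (skipped folds?)")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ModelError("labels must be coded {0,1}")
    if len(np.unique(y)) < 2:
        raise ModelError("both classes must be present to score a classifier")
    call = s >= cutoff
    tp = int(np.sum(call & (y == 1)))
    tn = int(np.sum(~call & (y == 0)))
    fp = int(np.sum(call & (y == 0)))
    fn = int(np.sum(~call & (y == 1)))
    m = confusion_metrics(tp, tn, fp, fn)
    return PerformanceReport(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=m["accuracy"],
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        auc=_rank_auc(y, s),
        roc_points=roc_curve(y, s),
        cutoff=float(cutoff),
    )


# ---------------------------------------------------------------------------
# Significance summary / report writing


@dataclass
class SignificanceSummary:
    n_significant: int
    n_negative: int
    n_positive: int
    negative_ids: list
    positive_ids: list
    alpha: float


def significant_metabolites(
    table: CoefficientTable, alpha: float = 0.05
) -> SignificanceSummary:
    """Partition features with p < alpha by the sign of their coefficient.

    Negative standardized coefficients mark features associated with the
    favorable outcome (creatinine <= 1.5 mg/dL); positive ones with the
    adverse outcome. Order of the id lists follows the table.
    """
    df = table.frame
    sig = df[df["p_value"] < alpha]
    neg = list(sig.index[sig["coefficient"] < 0])
    pos = list(sig.index[sig["coefficient"] > 0])
    return SignificanceSummary(
        n_significant=len(sig),
        n_negative=len(neg),
        n_positive=len(pos),
        negative_ids=neg,
        positive_ids=pos,
        alpha=alpha,
    )


def write_report(
    out_dir,
    coefficient_table: CoefficientTable,
    performance: PerformanceReport,
    permutation: PermutationResult | None = None,
    pipeline_results=None,
    feature_annotations: pd.DataFrame | None = None,
    config: dict | None = None,
) -> dict:
    """Write the standard report bundle and return the file paths.

    Emits ``coefficients.csv`` (annotations + coefficient/p/CI columns),
    ``metrics.json``, ``roc_points.csv`` and ``run_log.json`` (config,
    seed, package versions). Deterministic given identical inputs.
    """
    import pathlib

    import metabopls

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "coefficients": out / "coefficients.csv",
        "metrics": out / "metrics.json",
        "roc": out / "roc_points.csv",
        "log": out / "run_log.json",
    }
    coefficient_table.to_csv(paths["coefficients"], annotations=feature_annotations)
    metrics = performance.to_dict()
    if permutation is not None:
        metrics["permutation_p"] = permutation.p_value
        metrics["observed_r2y"] = permutation.observed_r2y
    if pipeline_results is not None:
        metrics["n_components_stage1"] = pipeline_results.n_components_stage1
        metrics["n_components_stage2"] = pipeline_results.n_components_stage2
        metrics["n_selected_features"] = len(pipeline_results.selected_ids)
    with open(paths["metrics"], "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    performance.roc_points.to_csv(paths["roc"], index=False)
    log = {
        "package": "metabopls",
        "version": metabopls.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": config or {},
    }
    with open(paths["log"], "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
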