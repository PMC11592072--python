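"""Two-stage PLS-DA pipeline: full-feature fit, VIP selection, reduced fit.

Stage 1 fits PLS-DA on every feature with the component count chosen by
leave-one-out cross-validation (smallest count minimizing LOOCV
misclassifications, capped by configuration). Features with VIP strictly
above the threshold enter stage 2, where the component count is selected
the same way and the final model's LOOCV predictions feed the performance
metrics.

Within every LOOCV fold the held-out sample is excluded from centering and
scaling as well as from fitting; the training fold is re-autoscaled from
scratch, so no information about the held-out sample leaks into the model
that predicts it. The VIP selection itself is performed once on the full
data (not re-run per fold), which is the common single-selection design;
its optimism is a property of that design and is documented rather than
corrected here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, ModelError
from .pls import PLSDA, PLSDAResults
from .preprocess import ScaledMatrix


@dataclass(frozen=True)
class PipelineConfig:
    """Settings of the two-stage procedure.

    vip_threshold : features with VIP strictly greater enter stage 2.
    max_components_stage1 / max_components_stage2 : caps on the
        LOOCV-selected component counts of the two models.
    classification_cutoff : continuous prediction >= cutoff -> class 1.
    seed : default seed handed to downstream resampling (permutation test).
    """

    vip_threshold: float = 1.5
    max_components_stage1: int = 7
    max_components_stage2: int = 10
    classification_cutoff: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        if not self.vip_threshold > 0:
            raise ConfigError("vip_threshold: must be > 0")
        if not (0 < self.classification_cutoff < 1):
            raise ConfigError("classification_cutoff: must lie in (0, 1)")
        for name in ("max_components_stage1", "max_components_stage2"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name}: must be >= 1")


def _as_array(X) -> tuple[np.ndarray, list]:
    if isinstance(X, ScaledMatrix):
        return np.asarray(X.X, dtype=float), list(X.feature_ids)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return X, [f"x{j}" for j in range(X.shape[1])]


def _loocv_prediction_matrix(X: np.ndarray, y: np.ndarray, max_A: int) -> np.ndarray:
    """Out-of-fold continuous predictions for every component count 1..max_A.

    Exploits the nesting of NIPALS components: one deflation pass per fold
    yields the prediction at every truncation. The training fold is
    re-autoscaled each time. Folds whose training labels are single-class
    are skipped with a warning and yield NaN.
    """
    n, p = X.shape
    if n < 3:
        raise ModelError("LOOCV needs at least 3 samples")
    if max_A > min(n - 2, p):
        raise ModelError(
            f"n_components={max_A} infeasible in LOOCV folds; "
            f"achievable maximum is {min(n - 2, p)}"
        )
    preds = np.full((n, max_A), np.nan)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        yi = y[mask]
        if len(np.unique(yi)) < 2:
            warnings.warn(f"LOOCV fold {i}: single-class training set, skipped")
            continue
        Xi = X[mask]
        center = Xi.mean(axis=0)
        scale = Xi.std(axis=0, ddof=1)
        if np.any(scale == 0):
            bad = np.where(scale == 0)[0].tolist()
            raise ModelError(f"zero-variance feature(s) in LOOCV fold {i}: {bad}")
        Xs = (Xi - center) / scale
        xs_new = (X[i] - center) / scale
        res = PLSDA(Xs, yi).fit(max_A)
        # truncated coefficient path: b_A = W_A (P_A' W_A)^{-1} q_A
        W, P, q = res.weights, res.x_loadings, res.y_loadings
        for A in range(1, max_A + 1):
            b = W[:, :A] @ np.linalg.solve(P[:, :A].T @ W[:, :A], q[:A])
            preds[i, A - 1] = xs_new @ b + res.y_mean
    return preds


def loocv_predictions(X, y, n_components: int) -> np.ndarray:
    """Leave-one-out out-of-fold continuous predictions, in sample order."""
    Xa, _ = _as_array(X)
    y = np.asarray(y, dtype=float).ravel()
    return _loocv_prediction_matrix(Xa, y, int(n_components))[:, -1]


def select_n_components(X, y, max_components: int, cutoff: float = 0.5):
    """Choose the component count minimizing LOOCV misclassification.

    Returns ``(best_A, error_curve)`` where ``error_curve[A-1]`` is the
    LOOCV misclassification count at ``A`` components and ``best_A`` is the
    smallest count attaining the minimum (parsimony tie-break). Skipped
    folds are excluded from the counts.
    """
    max_components = int(max_components)
    if max_components < 1:
        raise ModelError("max_components must be >= 1")
    Xa, _ = _as_array(X)
    y = np.asarray(y, dtype=float).ravel()
    preds = _loocv_prediction_matrix(Xa, y, max_components)
    hard = (preds >= cutoff).astype(float)
    valid = ~np.isnan(preds)
    errors = np.where(valid & (hard != y[:, None]), 1, 0).sum(axis=0)
    best = int(np.argmin(errors)) + 1
    return best, errors


def vip_select(results: PLSDAResults, vip_threshold: float) -> list:
    """Feature ids with VIP strictly above the threshold, in input order."""
    vips = results.vip()
    selected = [f for f, v in zip(results.feature_ids, vips) if v > vip_threshold]
    if not selected:
        raise ModelError(
            f"no feature has VIP > {vip_threshold}; lower the threshold"
        )
    return selected


class TwoStagePLSDA:
    """Model object for the two-stage VIP-selection procedure.

    Built from an autoscaled study matrix and 0/1 labels; ``fit()`` runs
    stage-1 component selection and fit, VIP selection, stage-2 selection
    and fit, and the final model's LOOCV predictions, returning a
    :class:`TwoStageResults`.
    """

    def __init__(self, X, y, config: PipelineConfig | None = None):
        self.Xa, self.feature_ids = _as_array(X)
        self.y = np.asarray(y, dtype=float).ravel()
        if self.y.shape[0] != self.Xa.shape[0]:
            raise ModelError("X and y sample counts differ")
        self.config = config or PipelineConfig()

    def fit(self) -> "TwoStageResults":
        cfg = self.config
        n, p = self.Xa.shape
        max1 = min(cfg.max_components_stage1, n - 2, p)
        a1, curve1 = select_n_components(
            self.Xa, self.y, max1, cfg.classification_cutoff
        )
        stage1 = PLSDA(self.Xa, self.y, feature_ids=self.feature_ids).fit(a1)
        vips = stage1.vip()
        selected = vip_select(stage1, cfg.vip_threshold)
        idx = [self.feature_ids.index(f) for f in selected]
        X2 = self.Xa[:, idx]
        max2 = min(cfg.max_components_stage2, n - 2, len(selected))
        a2, curve2 = select_n_components(X2, self.y, max2, cfg.classification_cutoff)
        stage2 = PLSDA(X2, self.y, feature_ids=selected).fit(a2)
        loocv = _loocv_prediction_matrix(X2, self.y, a2)[:, -1]
        return TwoStageResults(
            model=self,
            config=cfg,
            stage1=stage1,
            vip=vips,
            selected_ids=selected,
            selected_index=idx,
            stage2=stage2,
            n_components_stage1=a1,
            n_components_stage2=a2,
            error_curve_stage1=curve1,
            error_curve_stage2=curve2,
            loocv_predictions=loocv,
        )


@dataclass
class TwoStageResults:
    """Everything the two-stage procedure produced, with reporting hooks."""

    model: TwoStagePLSDA = field(repr=False)
    config: PipelineConfig
    stage1: PLSDAResults
    vip: np.ndarray
    selected_ids: list
    selected_index: list
    stage2: PLSDAResults
    n_components_stage1: int
    n_components_stage2: int
    error_curve_stage1: np.ndarray
    error_curve_stage2: np.ndarray
    loocv_predictions: np.ndarray

    @property
    def y(self) -> np.ndarray:
        return self.model.y

    @property
    def X_selected(self) -> np.ndarray:
        return self.model.Xa[:, self.selected_index]

    # -- validation / reporting hooks ----------------------------------
    def performance(self, cutoff: float | None = None):
        from .validation import classification_metrics

        cut = self.config.classification_cutoff if cutoff is None else cutoff
        return classification_metrics(self.y, self.loocv_predictions, cut)

    def permutation_test(self, n_permutations: int = 1000, seed: int | None = None):
        from .validation import permutation_test

        return permutation_test(
            self.X_selected,
            self.y,
            self.n_components_stage2,
            n_permutations=n_permutations,
            seed=self.config.seed if seed is None else seed,
        )

    def jackknife(self, alpha: float = 0.05):
        from .validation import jackknife_coefficients

        return jackknife_coefficients(
            self.X_selected,
            self.y,
            self.n_components_stage2,
            alpha=alpha,
            feature_ids=self.selected_ids,
        )

    def summary(self) -> str:
        lines = [
            "Two-stage PLS-DA with VIP selection",
            f"  stage 1: {self.stage1.model.X.shape[1]} features, "
            f"A = {self.n_components_stage1} "
            f"(LOOCV error curve {self.error_curve_stage1.tolist()})",
            f"  VIP > {self.config.vip_threshold}: "
            f"{len(self.selected_ids)} features selected",
            f"  stage 2: A = {self.n_components_stage2} "
            f"(LOOCV error curve {self.error_curve_stage2.tolist()})",
            f"  stage-2 R2Y (train): {self.stage2.r2y:.4f}",
        ]
        return "\n".join(lines)


def run_two_stage(X, y, config: PipelineConfig | None = None) -> TwoStageResults:
    """Functional entry point; see :class:`TwoStagePLSDA`."""
    return TwoStagePLSDA(X, y, config).fit()
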