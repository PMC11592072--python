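"""NIPALS PLS1 discriminant analysis with VIP scores.

The model regresses a centered 0/1 class membership y on an autoscaled
intensity matrix X by partial least squares with a single response
(PLS1). Components are extracted one at a time: at step a the weight
vector is

    w_a = X_{a-1}' y / ||X_{a-1}' y||,

the score t_a = X_{a-1} w_a, the y-loading q_a = y' t_a / t_a' t_a, the
X-loading p_a = X_{a-1}' t_a / t_a' t_a, and X is deflated,
X_a = X_{a-1} - t_a p_a'. With a single response no y-deflation is needed.
Predictions use the regression vector b = W (P' W)^{-1} q on the training
(standardized) scale, plus the training class mean, so the natural decision
cutoff for a {0,1}-coded outcome is 0.5.

Variable importance in projection (Wold's VIP) aggregates squared weights
across components, weighted by each component's explained y-variance
SSY_a = q_a² t_a' t_a:

    VIP_j = sqrt( p · Σ_a SSY_a w_{ja}² / Σ_a SSY_a ),

which satisfies Σ_j VIP_j² = p.

The public surface follows the model/results convention: build a
:class:`PLSDA` from data, call :meth:`PLSDA.fit`, and read estimates,
diagnostics and ``summary()`` off the returned :class:`PLSDAResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ModelError
from .preprocess import ScaledMatrix

_EPS = 1e-12


class PLSDA:
    """Two-class PLS discriminant analysis model.

    Parameters
    ----------
    X : ScaledMatrix or ndarray
        Samples × features predictor matrix. A :class:`ScaledMatrix` is
        used as-is (it is already autoscaled) and its center/scale are
        stored for prediction on raw data. A plain array is taken as
        already standardized unless ``autoscale=True``, in which case the
        model centers and unit-variance scales it itself.
    y : array-like
        Class labels coded {0, 1}; 1 is the positive class
        (creatinine > 1.5 mg/dL in the motivating application).
    autoscale : bool
        Only meaningful for plain-array ``X``; see above.
    feature_ids : sequence, optional
        Names for the columns; defaults to ``x0..x{p-1}`` or the ids
        carried by the :class:`ScaledMatrix`.
    """

    def __init__(self, X, y, *, autoscale: bool = False, feature_ids=None):
        if isinstance(X, ScaledMatrix):
            self.feature_ids = list(X.feature_ids)
            self._center = np.asarray(X.center, dtype=float)
            self._scale = np.asarray(X.scale, dtype=float)
            Xs = np.asarray(X.X, dtype=float)
        else:
            Xs = np.atleast_2d(np.asarray(X, dtype=float))
            if autoscale:
                self._center = Xs.mean(axis=0)
                self._scale = Xs.std(axis=0, ddof=1)
                zero = self._scale == 0
                if zero.any():
                    raise ModelError(
                        f"zero-variance feature column(s) at index {np.where(zero)[0].tolist()}"
                    )
                Xs = (Xs - self._center) / self._scale
            else:
                self._center = np.zeros(Xs.shape[1])
                self._scale = np.ones(Xs.shape[1])
            self.feature_ids = (
                list(feature_ids)
                if feature_ids is not None
                else [f"x{j}" for j in range(Xs.shape[1])]
            )
        if len(self.feature_ids) != Xs.shape[1]:
            raise ModelError("feature_ids length does not match number of columns")
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != Xs.shape[0]:
            raise ModelError(
                f"y has {y.shape[0]} entries for {Xs.shape[0]} samples"
            )
        if Xs.shape[0] < 3:
            raise ModelError("need at least 3 samples")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ModelError("y must be coded {0,1}")
        if len(np.unique(y)) < 2:
            raise ModelError("both classes must be present in y")
        self.X = Xs
        self.y = y

    @classmethod
    def from_scaled_matrix(cls, scaled: ScaledMatrix, y) -> "PLSDA":
        return cls(scaled, y)

    @property
    def max_components(self) -> int:
        n, p = self.X.shape
        return min(n - 1, p)

    def fit(self, n_components: int) -> "PLSDAResults":
        """Extract ``n_components`` NIPALS components and return results.

        The sign of each component is fixed by requiring the largest-
        magnitude element of its weight vector to be positive, so fits are
        reproducible down to the sign of loading plots.
        """
        A = int(n_components)
        if A < 1:
            raise ModelError("n_components must be >= 1")
        if A > self.max_components:
            raise ModelError(
                f"n_components={A} exceeds the achievable maximum "
                f"{self.max_components} for this matrix"
            )
        n, p = self.X.shape
        Xd = self.X.copy()
        y_mean = self.y.mean()
        yc = self.y - y_mean
        x_tot = float(np.sum(self.X**2))
        W = np.zeros((p, A))
        T = np.zeros((n, A))
        P = np.zeros((p, A))
        q = np.zeros(A)
        for a in range(A):
            w = Xd.T @ yc
            nw = float(np.linalg.norm(w))
            if nw <= _EPS * max(1.0, float(np.abs(Xd).max())):
                raise ModelError(
                    f"residual X carries no covariance with y at component {a + 1}; "
                    f"achievable maximum is {a}"
                )
            w /= nw
            if w[np.argmax(np.abs(w))] < 0:
                w = -w
            t = Xd @ w
            tt = float(t @ t)
            if tt <= _EPS:
                raise ModelError(
                    f"degenerate score at component {a + 1}; achievable maximum is {a}"
                )
            q[a] = float(yc @ t) / tt
            pv = Xd.T @ t / tt
            Xd = Xd - np.outer(t, pv)
            W[:, a], T[:, a], P[:, a] = w, t, pv
        return PLSDAResults(
            model=self,
            n_components=A,
            weights=W,
            scores=T,
            x_loadings=P,
            y_loadings=q,
            y_mean=y_mean,
            x_total_ss=x_tot,
        )


@dataclass
class PLSDAResults:
    """Fitted PLS-DA: component vectors, coefficients, VIPs, diagnostics."""

    model: PLSDA = field(repr=False)
    n_components: int
    weights: np.ndarray  # p x A, unit-norm columns
    scores: np.ndarray  # n x A, mutually orthogonal columns
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # A
    y_mean: float
    x_total_ss: float

    @property
    def feature_ids(self) -> list:
        return self.model.feature_ids

    @property
    def coefficients(self) -> np.ndarray:
        """Regression vector b = W (P'W)^{-1} q on the standardized scale."""
        W, P, q = self.weights, self.x_loadings, self.y_loadings
        M = P.T @ W
        if np.linalg.cond(M) > 1e12:
            raise ModelError("P'W is numerically singular (repeated components?)")
        return W @ np.linalg.solve(M, q)

    def predict(self, X_new, feature_ids=None) -> np.ndarray:
        """Continuous response for new samples (not thresholded).

        ``X_new`` is samples × features on the raw scale of the training
        input; the training center/scale are applied before projecting. If
        ``feature_ids`` is given it must match the training features
        exactly (order included).
        """
        if feature_ids is not None:
            got, want = list(feature_ids), self.feature_ids
            if got != want:
                missing = [f for f in want if f not in got]
                extra = [f for f in got if f not in want]
                raise ModelError(
                    f"feature mismatch; missing: {missing}, extra: {extra}"
                )
        Xn = np.atleast_2d(np.asarray(X_new, dtype=float))
        if Xn.shape[1] != len(self.feature_ids):
            raise ModelError(
                f"expected {len(self.feature_ids)} features, got {Xn.shape[1]}"
            )
        Xs = (Xn - self.model._center) / self.model._scale
        return Xs @ self.coefficients + self.y_mean

    @property
    def fitted_values(self) -> np.ndarray:
        return self.scores @ self.y_loadings + self.y_mean

    # -- diagnostics ----------------------------------------------------
    @property
    def r2y(self) -> float:
        """Fraction of training y-variance explained (R²Y, cumulative)."""
        y = self.model.y
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0:
            raise ModelError("constant y has no variance to explain")
        ss_res = float(np.sum((y - self.fitted_values) ** 2))
        return 1.0 - ss_res / ss_tot

    @property
    def x_variance_explained(self) -> np.ndarray:
        """Per-component fraction of the scaled X's total sum of squares."""
        tt = np.sum(self.scores**2, axis=0)
        pp = np.sum(self.x_loadings**2, axis=0)
        return tt * pp / self.x_total_ss

    @property
    def cumulative_x_variance(self) -> float:
        return float(self.x_variance_explained.sum())

    def vip(self) -> np.ndarray:
        """Wold VIP scores; satisfies sum(VIP²) = number of features."""
        ssy = self.y_loadings**2 * np.sum(self.scores**2, axis=0)
        total = float(ssy.sum())
        if total <= 0:
            raise ModelError("y is orthogonal to X; VIP undefined")
        p = self.weights.shape[0]
        return np.sqrt(p * (self.weights**2 @ ssy) / total)

    # -- presentation / persistence ------------------------------------
    def summary(self) -> str:
        xvar = self.x_variance_explained
        lines = [
            "PLS-DA (NIPALS, single response)",
            f"  samples: {self.model.X.shape[0]}   features: {self.model.X.shape[1]}",
            f"  components: {self.n_components}",
            f"  R2Y (train): {self.r2y:.4f}",
            "  X-variance explained per component: "
            + ", ".join(f"{v:.1%}" for v in xvar)
            + f"  (cumulative {xvar.sum():.1%})",
            "",
            f"  {'component':>9}  {'q (y-loading)':>14}  {'||t||^2':>12}",
        ]
        tt = np.sum(self.scores**2, axis=0)
        for a in range(self.n_components):
            lines.append(f"  {a + 1:>9}  {self.y_loadings[a]:>14.5f}  {tt[a]:>12.4f}")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "n_components": self.n_components,
            "feature_ids": [str(f) for f in self.feature_ids],
            "weights": self.weights.tolist(),
            "scores": self.scores.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "y_mean": self.y_mean,
            "x_total_ss": self.x_total_ss,
            "x_center": self.model._center.tolist(),
            "x_scale": self.model._scale.tolist(),
            "y": self.model.y.tolist(),
            "X": self.model.X.tolist(),
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PLSDAResults":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        model = PLSDA(
            np.asarray(payload["X"], dtype=float),
            np.asarray(payload["y"], dtype=float),
            feature_ids=payload["feature_ids"],
        )
        model._center = np.asarray(payload["x_center"], dtype=float)
        model._scale = np.asarray(payload["x_scale"], dtype=float)
        return cls(
            model=model,
            n_components=int(payload["n_components"]),
            weights=np.asarray(payload["weights"], dtype=float),
            scores=np.asarray(payload["scores"], dtype=float),
            x_loadings=np.asarray(payload["x_loadings"], dtype=float),
            y_loadings=np.asarray(payload["y_loadings"], dtype=float),
            y_mean=float(payload["y_mean"]),
            x_total_ss=float(payload["x_total_ss"]),
        )


# ---------------------------------------------------------------------------
# Thin functional aliases over the model/results objects.


def fit_pls1(X, y, n_components: int, **kwargs) -> PLSDAResults:
    """Fit a PLS1 discriminant model; see :class:`PLSDA`."""
    return PLSDA(X, y, **kwargs).fit(n_components)


def regression_coefficients(results: PLSDAResults) -> np.ndarray:
    return results.coefficients


def predict_response(results: PLSDAResults, X_new, feature_ids=None) -> np.ndarray:
    return results.predict(X_new, feature_ids=feature_ids)


def vip_scores(results: PLSDAResults) -> np.ndarray:
    return results.vip()


def fit_statistics(results: PLSDAResults) -> dict:
    """R²Y plus per-component and cumulative X-variance explained."""
    xvar = results.x_variance_explained
    return {
        "r2y": results.r2y,
        "x_variance_per_component": xvar,
        "cumulative_x_variance": float(xvar.sum()),
    }
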