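"""LCST phase-behavior classification from descriptor tables.

The model chain is the chemometrics standard: autoscale the descriptor
matrix X (center, unit variance), summarize it with PCA (X = TP′ + E)
for exploration, and fit a PLS-DA regression for prediction.  PLS
components are extracted sequentially (NIPALS): each weight vector w is
proportional to X′y for the current deflated X, scores are t = Xw, and
the binary response (1 = LCST phase behavior below 37 °C, 0 = none) is
regressed on the scores, ŷ = ½ + T·b.  The intercept is the midpoint
of the 0/1 class codes rather than the training mean of y: in
leave-one-group-out folds the training classes are unbalanced, and a
training-mean intercept would systematically drag every held-out
prediction toward the majority class.  With centered X the choice of
intercept affects only this constant, not the extracted components.
A continuous prediction above 0.5 is read as class 1.

Model validation uses a nested (double) cross-validation: an outer loop
leaves each ELP out as a test group; an inner loop over the remaining
ELPs leaves each out once as a validation group to pick the number of
components (the smallest count that classifies the validation ELP
correctly).  All rows of an ELP (every replica and time point) always
travel together, so no test observation ever leaks into training.  The
outer predictions per ELP (7 of them for an 8-ELP library) are averaged
and summarized with a 99 % Student-t confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScalingModel",
    "PCAModel",
    "PLSDAModel",
    "DCVResult",
    "autoscale",
    "fit_pca",
    "fit_plsda",
    "predict_plsda",
    "classify",
    "confidence_interval",
    "select_components",
    "double_cross_validate",
]

META_COLUMNS = ("elp", "replica", "time_ns")


def _split_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        cols = [c for c in X.columns if c not in META_COLUMNS]
        return X[cols].to_numpy(dtype=float), cols
    X = np.asarray(X, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


@dataclass
class ScalingModel:
    """Column means/standard deviations (population sd convention)."""

    mean: np.ndarray
    std: np.ndarray
    columns: list[str]
    dropped: list[str] = field(default_factory=list)

    def apply(self, X) -> np.ndarray:
        Xv, cols = _split_matrix(X)
        if cols != self.columns:
            if set(self.columns) <= set(cols):
                if isinstance(X, pd.DataFrame):
                    Xv = X[self.columns].to_numpy(dtype=float)
                else:
                    raise ValueError("column mismatch with scaling model")
            else:
                raise ValueError("column mismatch with scaling model")
        return (Xv - self.mean) / self.std

    def invert(self, X_scaled: np.ndarray) -> np.ndarray:
        return X_scaled * self.std + self.mean


def autoscale(X) -> tuple[np.ndarray, ScalingModel]:
    """Center and scale each column to unit (population) variance.

    Constant columns carry no information and break the scaling, so
    they are dropped with a warning and recorded in the model.
    """
    Xv, cols = _split_matrix(X)
    if Xv.shape[0] < 2:
        raise ValueError("need at least two rows to autoscale")
    mean = Xv.mean(axis=0)
    std = Xv.std(axis=0, ddof=0)
    keep = std > 0
    if not keep.any():
        raise ValueError("all columns are constant")
    dropped = [c for c, k in zip(cols, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant column(s): {dropped}", stacklevel=2)
    model = ScalingModel(
        mean=mean[keep],
        std=std[keep],
        columns=[c for c, k in zip(cols, keep) if k],
        dropped=dropped,
    )
    return (Xv[:, keep] - model.mean) / model.std, model


@dataclass
class PCAModel:
    """X_scaled = T·P′ + E with orthonormal loadings P."""

    loadings: np.ndarray  # (p, k)
    scores: np.ndarray  # (n, k)
    explained_variance_ratio: np.ndarray
    residual: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca(X_scaled: np.ndarray, k: int) -> PCAModel:
    """Principal components via SVD, ordered by explained variance."""
    X = np.asarray(X_scaled, dtype=float)
    n, p = X.shape
    if k > min(n - 1, p):
        raise ValueError(f"k={k} exceeds min(n-1, p)={min(n - 1, p)}")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    loadings = vt[:k].T
    scores = u[:, :k] * s[:k]
    total_var = (s**2).sum()
    ratio = s[:k] ** 2 / total_var if total_var > 0 else np.zeros(k)
    residual = X - scores @ loadings.T
    return PCAModel(loadings, scores, ratio, residual)


@dataclass
class PLSDAModel:
    """Sequentially extracted PLS1 components for a 0/1 response."""

    weights: np.ndarray  # W, (p, k), unit-norm columns
    x_loadings: np.ndarray  # P, (p, k)
    scores: np.ndarray  # T, training scores (n, k)
    coefficients: np.ndarray  # b, (k,)
    intercept: float  # midpoint of the 0/1 class codes
    y_residual: np.ndarray  # F on the training data
    columns: list[str]
    threshold: float = 0.5

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def transform_predict(self, X_scaled: np.ndarray) -> np.ndarray:
        """ŷ per row with all components (deflation-based projection)."""
        return self.predict_path(X_scaled)[:, -1]

    def predict_path(self, X_scaled: np.ndarray) -> np.ndarray:
        """(n, k) cumulative predictions using 1..k components.

        The NIPALS extraction is sequential, so truncating to the first
        a components is itself the a-component model; this is what the
        inner component-selection loop exploits.
        """
        X = np.array(X_scaled, dtype=float, copy=True)
        n = X.shape[0]
        out = np.empty((n, self.n_components))
        yhat = np.full(n, self.intercept)
        for a in range(self.n_components):
            t = X @ self.weights[:, a]
            yhat = yhat + self.coefficients[a] * t
            X -= np.outer(t, self.x_loadings[:, a])
            out[:, a] = yhat
        return out


def fit_plsda(X_scaled: np.ndarray, y: np.ndarray, k: int) -> PLSDAModel:
    """NIPALS PLS1 fit of a 0/1 response on the scaled descriptors.

    Per component: w ∝ X′y (normalized), t = Xw, loading p = X′t/(t′t),
    coefficient b = y′t/(t′t); X and y are deflated before the next
    component.  Requires both classes present.
    """
    X = np.array(X_scaled, dtype=float, copy=True)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in y")
    if k < 1:
        raise ValueError("k must be >= 1")
    n, p = X.shape
    y_mean = float(y.mean())
    yres = y - y_mean

    W = np.empty((p, k))
    P = np.empty((p, k))
    T = np.empty((n, k))
    b = np.empty(k)
    for a in range(k):
        w = X.T @ yres
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            raise ValueError(
                f"k={k} exceeds the effective rank; X'y vanished at component {a + 1}"
            )
        w /= norm
        t = X @ w
        tt = float(t @ t)
        p_a = X.T @ t / tt
        b_a = float(yres @ t / tt)
        X -= np.outer(t, p_a)
        yres = yres - b_a * t
        W[:, a], P[:, a], T[:, a], b[a] = w, p_a, t, b_a
    return PLSDAModel(
        weights=W, x_loadings=P, scores=T, coefficients=b,
        intercept=0.5, y_residual=yres, columns=[],
    )


def classify(value: float, threshold: float = 0.5) -> int:
    """1 iff the continuous prediction exceeds the threshold.

    An exact tie at the threshold is read as class 0 (absence).
    """
    if not np.isfinite(value):
        raise ValueError("prediction must be finite")
    return int(value > threshold)


def predict_plsda(
    model: PLSDAModel,
    scaler: ScalingModel,
    X_new: pd.DataFrame,
    n_components: Optional[int] = None,
) -> pd.Series:
    """Continuous prediction per ELP: mean over all of its rows.

    Each ELP contributes many observations (replicas × time points);
    the per-ELP value is the arithmetic mean of the row predictions.
    """
    if "elp" not in X_new.columns:
        raise ValueError("X_new must carry an 'elp' metadata column")
    Xs = scaler.apply(X_new)
    k = model.n_components if n_components is None else n_components
    yhat = model.predict_path(Xs)[:, k - 1]
    return pd.Series(yhat).groupby(X_new["elp"].to_numpy()).mean()


def confidence_interval(
    predictions: Sequence[float], level: float = 0.99
) -> tuple[float, float]:
    """Student-t interval, mean ± t(1−α/2, n−1)·sd/√n (sample sd)."""
    preds = np.asarray(predictions, dtype=float)
    n = len(preds)
    if n < 2:
        raise ValueError("need at least two predictions for an interval")
    m = preds.mean()
    sd = preds.std(ddof=1)
    half = stats.t.ppf(0.5 + level / 2.0, n - 1) * sd / np.sqrt(n)
    return float(m - half), float(m + half)


def select_components(
    val_path: np.ndarray, y_val: int, k_max: int
) -> tuple[int, bool]:
    """Pick the smallest component count that classifies the validation
    ELP correctly.

    ``val_path``: aggregated validation-ELP prediction using 1..k
    components.  If no count classifies it correctly the fallback is the
    count whose prediction is closest to the correct class value
    (maximum margin toward the correct side); the second return value
    flags that fallback.
    """
    k_cap = min(k_max, len(val_path))
    for a in range(k_cap):
        if classify(float(val_path[a])) == y_val:
            return a + 1, False
    dist = np.abs(val_path[:k_cap] - y_val)
    return int(np.argmin(dist)) + 1, True


@dataclass
class ELPPrediction:
    elp: str
    predictions: list[float]
    mean: float
    ci99: tuple[float, float]
    predicted_class: int
    true_class: int
    ci_correct_side: bool


@dataclass
class DCVResult:
    """Outcome of the nested leave-one-ELP-out validation."""

    per_elp: dict[str, ELPPrediction]
    chosen_components: dict[str, list[int]]  # per outer test ELP
    fallback_folds: int
    accuracy: float  # %

    @property
    def fraction_ci_correct(self) -> float:
        vals = [p.ci_correct_side for p in self.per_elp.values()]
        return sum(vals) / len(vals)

    def to_report(self) -> dict:
        return {
            "accuracy_percent": self.accuracy,
            "fraction_ci_correct_side": self.fraction_ci_correct,
            "fallback_folds": self.fallback_folds,
            "per_elp": {
                e: {
                    "predictions": p.predictions,
                    "mean": p.mean,
                    "ci99": list(p.ci99),
                    "predicted_class": p.predicted_class,
                    "true_class": p.true_class,
                    "ci_correct_side": p.ci_correct_side,
                    "chosen_components": self.chosen_components[e],
                }
                for e, p in self.per_elp.items()
            },
        }


def double_cross_validate(
    data: pd.DataFrame,
    labels: dict[str, int],
    k_max: int = 10,
    ci_level: float = 0.99,
) -> DCVResult:
    """Nested leave-one-ELP-out cross-validation of the PLS-DA model.

    Outer loop: each ELP is held out as the test group once.  Inner
    loop: each remaining ELP serves as validation once; the model is
    fitted on the other ELPs, the component count is chosen on the
    validation ELP, and the test ELP is predicted with that model.
    With 8 ELPs this yields 8 × 7 = 56 fits and 7 predictions per ELP.
    """
    elps = sorted(labels)
    present = set(data["elp"].unique())
    missing = [e for e in elps if e not in present]
    if missing:
        raise ValueError(f"no descriptor rows for ELP(s): {missing}")
    if len(elps) < 3:
        raise ValueError("double cross-validation needs at least 3 ELPs")
    if len(set(labels.values())) < 2:
        raise ValueError("both classes must be present")

    feature_cols = [c for c in data.columns if c not in META_COLUMNS]
    by_elp = {e: data[data["elp"] == e] for e in elps}

    per_elp_preds: dict[str, list[float]] = {e: [] for e in elps}
    chosen: dict[str, list[int]] = {e: [] for e in elps}
    fallback_folds = 0

    for test in elps:
        inner_elps = [e for e in elps if e != test]
        for val in inner_elps:
            model_elps = [e for e in inner_elps if e != val]
            y_model = np.concatenate(
                [np.full(len(by_elp[e]), labels[e]) for e in model_elps]
            )
            if len(set(y_model.tolist())) < 2:
                warnings.warn(
                    f"fold (test={test}, val={val}) has a single class; skipped",
                    stacklevel=2,
                )
                continue
            X_model = pd.concat([by_elp[e] for e in model_elps], ignore_index=True)
            Xs, scaler = autoscale(X_model[feature_cols])
            k_cap = max(1, min(k_max, Xs.shape[1], Xs.shape[0] - 1))
            try:
                model = fit_plsda(Xs, y_model, k_cap)
            except ValueError:
                # rank-deficient beyond some component count: refit smaller
                k_cap = max(1, np.linalg.matrix_rank(Xs) - 1)
                model = fit_plsda(Xs, y_model, k_cap)
            model.columns = scaler.columns

            val_path = model.predict_path(scaler.apply(by_elp[val][feature_cols]))
            val_agg = val_path.mean(axis=0)
            k_sel, fell_back = select_components(val_agg, labels[val], k_cap)
            fallback_folds += int(fell_back)

            test_path = model.predict_path(scaler.apply(by_elp[test][feature_cols]))
            per_elp_preds[test].append(float(test_path[:, k_sel - 1].mean()))
            chosen[test].append(k_sel)

    per_elp: dict[str, ELPPrediction] = {}
    n_correct = 0
    scored_elps = []
    for e in elps:
        preds = per_elp_preds[e]
        if not preds:
            warnings.warn(
                f"ELP {e} received no predictions (all folds skipped); excluded",
                stacklevel=2,
            )
            continue
        scored_elps.append(e)
        mean = float(np.mean(preds))
        ci = (
            confidence_interval(preds, level=ci_level)
            if len(preds) >= 2
            else (float("nan"), float("nan"))
        )
        pred_class = classify(mean)
        true = int(labels[e])
        correct_side = bool(
            np.isfinite(ci).all()
            and ((ci[0] > 0.5) if true == 1 else (ci[1] < 0.5))
        )
        n_correct += int(pred_class == true)
        per_elp[e] = ELPPrediction(
            elp=e, predictions=preds, mean=mean, ci99=ci,
            predicted_class=pred_class, true_class=true,
            ci_correct_side=correct_side,
        )
    if not scored_elps:
        raise ValueError("no ELP received any prediction")
    accuracy = 100.0 * n_correct / len(scored_elps)
    return DCVResult(
        per_elp=per_elp, chosen_components=chosen,
        fallback_folds=fallback_folds, accuracy=accuracy,
    )
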