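"""PCA, OPLS / OPLS-DA latent-variable models, and MANOVA on PC scores.

OPLS (orthogonal projections to latent structures) splits predictor
variation into a part predictive of the response and a part orthogonal to
it. Orthogonal components are estimated from NIPALS PLS loadings projected
off the response-weight subspace and removed from X before the final
predictive PLS fit, so orthogonal scores are exactly uncorrelated with the
response. For discriminant analysis (OPLS-DA) the response is a class dummy
matrix and the model carries n_classes - 1 predictive components; class
assignment is by nearest centroid in the cross-validated training-score
plane. For regression on age a single predictive component is used and the
prediction is the "metabolomic age" of a sample.

Per-variable correlation loadings R — the Pearson correlation between each
(centered) input variable and each predictive score — are retained for the
permutation-calibrated significance analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PCAModel",
    "OPLSModel",
    "ClassPrediction",
    "AgePrediction",
    "fit_pca",
    "fit_opls",
    "fit_oplsda",
    "fit_opls_age",
    "transform",
    "predict_class",
    "predict_age",
    "select_n_orthogonal",
    "two_way_manova",
]

_TOL = 1e-10
_MAX_ITER = 500


# ---------------------------------------------------------------------------
# PCA

@dataclass(frozen=True)
class PCAModel:
    loadings: np.ndarray                     # components x variables
    scores: np.ndarray                       # samples x components
    explained_variance_fraction: np.ndarray  # per component

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.loadings


def fit_pca(X: np.ndarray, n_components: Optional[int] = None) -> PCAModel:
    """PCA by SVD of the (already centered/scaled) matrix.

    Deterministic sign convention: the largest-|loading| element of each
    component is positive.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    max_comp = min(n - 1, p) if n > 1 else 1
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise ValueError(f"n_components={n_components} exceeds min(samples-1, variables)")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    total = float((s**2).sum())
    k = n_components
    loadings = vt[:k]
    scores = u[:, :k] * s[:k]
    for j in range(k):
        i_max = np.argmax(np.abs(loadings[j]))
        if loadings[j, i_max] < 0:
            loadings[j] *= -1.0
            scores[:, j] *= -1.0
    frac = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PCAModel(loadings=loadings, scores=scores, explained_variance_fraction=frac)


# ---------------------------------------------------------------------------
# NIPALS PLS / OPLS

def _nipals_component(X: np.ndarray, Y: np.ndarray):
    """One NIPALS PLS component; deterministic init from the first Y column."""
    u = Y[:, 0].astype(float).copy()
    if np.allclose(u, 0):
        u = Y.sum(axis=1)
    t_old = None
    for _ in range(_MAX_ITER):
        w = X.T @ u
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("degenerate component: zero weight vector")
        w /= nw
        t = X @ w
        c = Y.T @ t / float(t @ t)
        u = Y @ c / float(c @ c)
        if t_old is not None and np.linalg.norm(t - t_old) <= _TOL * max(
            np.linalg.norm(t), 1e-300
        ):
            break
        t_old = t
    p_load = X.T @ t / float(t @ t)
    return w, t, p_load, c


def _pls_fit(X: np.ndarray, Y: np.ndarray, n_components: int):
    """NIPALS PLS2 with X and Y deflation; returns W, P, C, T."""
    Xd, Yd = X.copy(), Y.copy()
    n, p = X.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros((Y.shape[1], n_components))
    T = np.zeros((n, n_components))
    for a in range(n_components):
        w, t, p_load, c = _nipals_component(Xd, Yd)
        W[:, a], T[:, a], P[:, a], C[:, a] = w, t, p_load, c
        Xd = Xd - np.outer(t, p_load)
        Yd = Yd - np.outer(t, c)
    return W, P, C, T


@dataclass
class OPLSModel:
    """Fitted OPLS / OPLS-DA model with training preprocessing constants."""

    response_kind: str                 # "class" | "age"
    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray                # p x a predictive weights W
    loadings: np.ndarray               # p x a predictive loadings P
    c_loadings: np.ndarray             # m x a response loadings C
    rotation: np.ndarray               # p x a, X_filtered @ rotation = scores
    w_orth: np.ndarray                 # p x k
    p_orth: np.ndarray                 # p x k
    scores: np.ndarray                 # n x a training predictive scores
    orth_scores: np.ndarray            # n x k
    correlation: np.ndarray            # p x a per-variable R vs predictive scores
    classes_: Optional[list] = None
    cv_scores: Optional[np.ndarray] = None
    centroids: Optional[dict] = None
    training_y: Optional[np.ndarray] = None

    @property
    def n_predictive(self) -> int:
        return self.weights.shape[1]

    @property
    def n_orthogonal(self) -> int:
        return self.w_orth.shape[1]


def _correlation_loadings(Xc: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Pearson R between each centered variable and each predictive score."""
    Tc = T - T.mean(axis=0)
    x_sd = np.sqrt((Xc**2).sum(axis=0))
    t_sd = np.sqrt((Tc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Xc.T @ Tc) / np.outer(x_sd, t_sd)
    R[~np.isfinite(R)] = 0.0
    return R


def _orthogonal_filter(X: np.ndarray, Y: np.ndarray, n_orthogonal: int):
    p = X.shape[1]
    Wy, sv, _ = np.linalg.svd(X.T @ Y, full_matrices=False)
    rank = int((sv > sv[0] * 1e-12).sum()) if sv.size and sv[0] > 0 else 0
    Wy = Wy[:, :rank]
    W_o = np.zeros((p, 0))
    P_o = np.zeros((p, 0))
    T_o = np.zeros((X.shape[0], 0))
    Xf = X.copy()
    for _ in range(n_orthogonal):
        _, _, p_load, _ = _nipals_component(Xf, Y)
        w_o = p_load - Wy @ (Wy.T @ p_load)
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break  # no orthogonal structure left
        w_o /= norm
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / float(t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        W_o = np.column_stack([W_o, w_o])
        P_o = np.column_stack([P_o, p_o])
        T_o = np.column_stack([T_o, t_o])
    return Xf, W_o, P_o, T_o


def fit_opls(
    X: np.ndarray,
    Y: np.ndarray,
    n_predictive: int,
    n_orthogonal: int = 0,
    response_kind: str = "age",
) -> OPLSModel:
    """Core OPLS fit: orthogonal filtering then an n_predictive PLS model."""
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and X.shape[0] != 1:
        Y = Y.T
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    Xf, W_o, P_o, T_o = _orthogonal_filter(Xc, Yc, n_orthogonal)
    W, P, C, T = _pls_fit(Xf, Yc, n_predictive)
    rotation = W @ np.linalg.inv(P.T @ W)
    return OPLSModel(
        response_kind=response_kind,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        loadings=P,
        c_loadings=C,
        rotation=rotation,
        w_orth=W_o,
        p_orth=P_o,
        scores=T,
        orth_scores=T_o,
        correlation=_correlation_loadings(Xc, T),
        training_y=Y,
    )


def transform(model: OPLSModel, X_new: np.ndarray) -> np.ndarray:
    """Orthogonal-filter new samples with training weights and project them
    onto the predictive plane."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != len(model.x_mean):
        raise ValueError("variable count mismatch with training data")
    Xc = X_new - model.x_mean
    for j in range(model.n_orthogonal):
        t_o = Xc @ model.w_orth[:, j]
        Xc = Xc - np.outer(t_o, model.p_orth[:, j])
    return Xc @ model.rotation


def predict_response(model: OPLSModel, X_new: np.ndarray) -> np.ndarray:
    T = transform(model, X_new)
    return T @ model.c_loadings.T + model.y_mean


# ---------------------------------------------------------------------------
# Discriminant analysis

def _dummy_matrix(classes: Sequence, levels: list) -> np.ndarray:
    Y = np.zeros((len(classes), len(levels)))
    for i, c in enumerate(classes):
        Y[i, levels.index(c)] = 1.0
    return Y


def _stratified_folds(labels: np.ndarray, n_folds: int) -> np.ndarray:
    """Deterministic round-robin fold assignment within each class."""
    folds = np.zeros(len(labels), dtype=int)
    for lv in pd.unique(labels):
        idx = np.flatnonzero(labels == lv)
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds


def _cv_scores(
    X: np.ndarray,
    Y: np.ndarray,
    labels: np.ndarray,
    n_predictive: int,
    n_orthogonal: int,
    reference: OPLSModel,
    n_folds: int = 7,
) -> np.ndarray:
    """Cross-validated predictive scores with fold signs aligned to the
    full-data model's weight vectors."""
    n = X.shape[0]
    folds = _stratified_folds(labels, min(n_folds, n))
    cv = np.zeros((n, n_predictive))
    for f in np.unique(folds):
        test = folds == f
        sub = fit_opls(X[~test], Y[~test], n_predictive, n_orthogonal)
        signs = np.sign(np.einsum("pa,pa->a", sub.weights, reference.weights))
        signs[signs == 0] = 1.0
        cv[test] = transform(sub, X[test]) * signs
    return cv


def fit_oplsda(
    X: np.ndarray,
    classes: Sequence,
    n_orthogonal: int = 1,
    n_folds: int = 7,
) -> OPLSModel:
    """OPLS-DA on a class dummy response; n_classes - 1 predictive components.

    Cross-validated training scores (stratified deterministic folds) define
    the class centroids used for nearest-centroid assignment.
    """
    labels = np.asarray(classes)
    levels = sorted(pd.unique(labels).tolist())
    if len(levels) < 2:
        raise ValueError("need at least 2 classes")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValueError("each class needs at least 2 samples")
    Y = _dummy_matrix(labels, levels)
    model = fit_opls(X, Y, n_predictive=len(levels) - 1,
                     n_orthogonal=n_orthogonal, response_kind="class")
    model.classes_ = levels
    model.cv_scores = _cv_scores(
        np.asarray(X, dtype=float), Y, labels,
        model.n_predictive, n_orthogonal, model, n_folds,
    )
    model.centroids = {
        lv: model.cv_scores[labels == lv].mean(axis=0) for lv in levels
    }
    return model


@dataclass(frozen=True)
class ClassPrediction:
    scores: np.ndarray        # samples x predictive components
    assigned: np.ndarray      # class label per sample
    is_training: np.ndarray   # bool per sample


def predict_class(
    model: OPLSModel,
    X_new: np.ndarray,
    is_training: Optional[np.ndarray] = None,
) -> ClassPrediction:
    """Project samples and assign each to the nearest class centroid."""
    if model.centroids is None:
        raise ValueError("model has no class centroids; fit with fit_oplsda")
    T = transform(model, X_new)
    levels = list(model.centroids)
    cents = np.stack([model.centroids[lv] for lv in levels])
    d2 = ((T[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    assigned = np.asarray(levels, dtype=object)[d2.argmin(axis=1)]
    if is_training is None:
        is_training = np.zeros(len(T), dtype=bool)
    return ClassPrediction(scores=T, assigned=assigned,
                           is_training=np.asarray(is_training, dtype=bool))


# ---------------------------------------------------------------------------
# Age regression

def fit_opls_age(X: np.ndarray, ages: Sequence[float], n_orthogonal: int = 0) -> OPLSModel:
    ages = np.asarray(ages, dtype=float)
    if len(np.unique(ages)) < 3:
        raise ValueError("need at least 3 distinct training ages")
    return fit_opls(X, ages[:, None], n_predictive=1,
                    n_orthogonal=n_orthogonal, response_kind="age")


@dataclass(frozen=True)
class AgePrediction:
    predicted_age: np.ndarray
    residual: Optional[np.ndarray] = None  # predicted - calendar


def predict_age(
    model: OPLSModel,
    X_new: np.ndarray,
    calendar_age: Optional[Sequence[float]] = None,
) -> AgePrediction:
    if model.response_kind != "age":
        raise ValueError("model is not an age-regression model")
    yhat = predict_response(model, X_new)[:, 0]
    resid = None
    if calendar_age is not None:
        resid = yhat - np.asarray(calendar_age, dtype=float)
    return AgePrediction(predicted_age=yhat, residual=resid)


def select_n_orthogonal(
    X: np.ndarray,
    Y: np.ndarray,
    labels: Sequence,
    n_predictive: int,
    max_orthogonal: int = 3,
    min_gain: float = 0.01,
    n_folds: int = 7,
) -> int:
    """Pick the orthogonal-component count by cross-validated Q^2.

    Q^2 = 1 - PRESS / TSS over held-out folds; stop adding orthogonal
    components when the Q^2 gain drops below ``min_gain``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and X.shape[0] != 1:
        Y = Y.T
    labels = np.asarray(labels)
    folds = _stratified_folds(labels, min(n_folds, X.shape[0]))
    tss = float(((Y - Y.mean(axis=0)) ** 2).sum())

    def q2(k: int) -> float:
        press = 0.0
        for f in np.unique(folds):
            test = folds == f
            sub = fit_opls(X[~test], Y[~test], n_predictive, k)
            press += float(((predict_response(sub, X[test]) - Y[test]) ** 2).sum())
        return 1.0 - press / tss

    best_k, best_q2 = 0, q2(0)
    for k in range(1, max_orthogonal + 1):
        qk = q2(k)
        if qk - best_q2 < min_gain:
            break
        best_k, best_q2 = k, qk
    return best_k


# ---------------------------------------------------------------------------
# MANOVA on PC scores

def two_way_manova(
    pc_scores: np.ndarray,
    genotype: Sequence,
    age: Sequence,
) -> dict:
    """Two-way MANOVA (Wilks' lambda, F approximation) on PC scores with
    genotype and age as crossed categorical main effects (no interaction)."""
    from statsmodels.multivariate.manova import MANOVA

    scores = np.asarray(pc_scores, dtype=float)
    keep = scores.std(axis=0) > 1e-12
    scores = scores[:, keep]
    if scores.shape[1] == 0:
        raise ValueError("no non-degenerate score columns")
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    df = pd.DataFrame(scores, columns=cols)
    df["genotype"] = np.asarray(genotype)
    df["age"] = np.asarray(age)
    formula = " + ".join(cols) + " ~ C(genotype) + C(age)"
    mv = MANOVA.from_formula(formula, data=df)
    res = mv.mv_test()
    out = {}
    for effect, key in [("genotype", "C(genotype)"), ("age", "C(age)")]:
        stat = res.results[key]["stat"]
        row = stat.loc["Wilks' lambda"]
        out[effect] = {
            "wilks_lambda": float(row["Value"]),
            "F": float(row["F Value"]),
            "p_value": float(row["Pr > F"]),
        }
    return out
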