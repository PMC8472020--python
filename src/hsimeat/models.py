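"""PLS-DA and RBF-SVM classifiers with venetian-blinds model selection.

PLS-DA regresses mean-centred spectra onto a one-hot class-indicator matrix
using NIPALS partial least squares and decodes predictions by argmax over
the indicator scores. The latent-variable (LV) count is chosen by
venetian-blinds cross-validation on the calibration set: rows are ordered
class-stratified and row *i* goes to fold ``i mod n_splits``, so every
calibration row is validated exactly once. The LV count with the lowest CV
misclassification wins; ties go to the smaller model.

The RBF-SVM autoscales the calibration spectra and grid-searches the
regularization and kernel-width exponents c = 2^i, g = 2^j over integer
i, j in [-8, 8] (17 x 17 = 289 pairs) by the same CV scheme; ties prefer
the smaller c exponent, then the smaller g exponent. Multi-class handling
is one-vs-one voting.

Model selection only ever sees calibration rows; prediction rows are
ignored by the fitting routines entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .errors import ConfigError, DegenerateClassesError, DimensionError
from .preprocess import PreprocessSpec
from .table import SpectrumTable


@dataclass
class CVScheme:
    kind: str = "venetian_blinds"
    n_splits: int = 10

    def __post_init__(self):
        if self.kind != "venetian_blinds":
            raise ConfigError(f"unknown CV scheme {self.kind!r}")
        if self.n_splits < 2:
            raise ConfigError("n_splits must be >= 2")


def venetian_folds(labels: np.ndarray, n_splits: int) -> np.ndarray:
    """Fold id per row: class-stratified ordering, then interleaved assignment."""
    labels = np.asarray(labels)
    if n_splits > labels.size:
        raise ConfigError("more folds than samples")
    order = np.argsort(labels, kind="stable")
    folds = np.empty(labels.size, dtype=int)
    folds[order] = np.arange(labels.size) % n_splits
    return folds


def one_hot(labels: np.ndarray, classes) -> np.ndarray:
    classes = list(classes)
    Y = np.zeros((len(labels), len(classes)))
    for j, c in enumerate(classes):
        Y[np.asarray(labels) == c, j] = 1.0
    return Y


# ---------------------------------------------------------------------------
# NIPALS PLS2 core


def _nipals_pls2(Xc: np.ndarray, Yc: np.ndarray, n_comp: int,
                 tol: float = 1e-12, max_iter: int = 500):
    """NIPALS on centred X (n x p) and Y (n x m); returns W, P, Q.

    Stops early if a score collapses (rank exhausted). Coefficients for any
    leading number of components a follow as B_a = W_a (P_a' W_a)^-1 Q_a'.
    """
    X = Xc.copy()
    Y = Yc.copy()
    n, p = X.shape
    m = Y.shape[1]
    W = np.zeros((p, n_comp))
    P = np.zeros((p, n_comp))
    Q = np.zeros((m, n_comp))
    a = 0
    for a in range(n_comp):
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
        if u @ u < tol:
            break
        t_old = None
        for _ in range(max_iter):
            w = X.T @ u
            nw = np.linalg.norm(w)
            if nw < tol:
                break
            w /= nw
            t = X @ w
            tt = t @ t
            if tt < tol:
                break
            q = Y.T @ t / tt
            u = Y @ q / (q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) < tol * np.sqrt(tt):
                break
            t_old = t
        t = X @ w
        tt = t @ t
        if tt < tol or np.linalg.norm(w) < tol:
            break
        p_vec = X.T @ t / tt
        q = Y.T @ t / tt
        X -= np.outer(t, p_vec)
        Y -= np.outer(t, q)
        W[:, a], P[:, a], Q[:, a] = w, p_vec, q
        a += 1
    return W[:, :a], P[:, :a], Q[:, :a]


def _pls_coefficients(W, P, Q, n_comp: int) -> np.ndarray:
    Wa, Pa, Qa = W[:, :n_comp], P[:, :n_comp], Q[:, :n_comp]
    return Wa @ np.linalg.solve(Pa.T @ Wa, Qa.T)


@dataclass
class PLSDAModel:
    """Fitted PLS-DA: centring vectors, NIPALS factors and the codebook."""

    n_lvs: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    coef: np.ndarray  # (bands, n_classes) on centred data
    classes: list
    weights: np.ndarray = field(repr=False, default=None)  # W
    x_loadings: np.ndarray = field(repr=False, default=None)  # P
    y_loadings: np.ndarray = field(repr=False, default=None)  # Q
    wavelengths: np.ndarray = None  # bands the model was trained on
    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)
    cv_error: float = None

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean.size:
            raise DimensionError(
                f"spectra have {X.shape[1]} bands; model expects {self.x_mean.size}"
            )
        return (X - self.x_mean) @ self.coef + self.y_mean


def _fit_pls_core(X, y, classes, n_comp):
    x_mean = X.mean(axis=0)
    Y = one_hot(y, classes)
    y_mean = Y.mean(axis=0)
    W, P, Q = _nipals_pls2(X - x_mean, Y - y_mean, n_comp)
    return x_mean, y_mean, W, P, Q


def _cv_misclassification_per_lv(X, y, classes, max_lvs, folds):
    """CV misclassification for each LV count 1..max_lvs (one fit per fold)."""
    errors = np.zeros(max_lvs)
    n = len(y)
    for f in np.unique(folds):
        val = folds == f
        x_mean, y_mean, W, P, Q = _fit_pls_core(X[~val], y[~val], classes, max_lvs)
        fitted = W.shape[1]
        for a in range(1, max_lvs + 1):
            B = _pls_coefficients(W, P, Q, min(a, fitted))
            scores = (X[val] - x_mean) @ B + y_mean
            pred = np.asarray(classes)[np.argmax(scores, axis=1)]
            errors[a - 1] += int((pred != np.asarray(y)[val]).sum())
    return errors / n


def plsda_fit(
    table: SpectrumTable,
    max_lvs: int = 10,
    cv: CVScheme | None = None,
    preprocess: PreprocessSpec | None = None,
) -> PLSDAModel:
    """Fit PLS-DA on the table's calibration rows, selecting LVs by CV."""
    cv = cv or CVScheme()
    cal = table.calibration()
    classes = cal.class_order
    if len(classes) < 2:
        raise DegenerateClassesError("PLS-DA requires at least two classes")
    if max_lvs < 1:
        raise ConfigError("max_lvs must be >= 1")
    X, y = cal.spectra, cal.species
    max_lvs = min(max_lvs, X.shape[1], X.shape[0] - 1)
    folds = venetian_folds(y, min(cv.n_splits, len(y)))
    errors = _cv_misclassification_per_lv(X, y, classes, max_lvs, folds)
    n_lvs = int(np.argmin(errors)) + 1  # argmin takes the first (fewest LVs) on ties
    x_mean, y_mean, W, P, Q = _fit_pls_core(X, y, classes, n_lvs)
    coef = _pls_coefficients(W, P, Q, W.shape[1])
    return PLSDAModel(
        n_lvs=n_lvs, x_mean=x_mean, y_mean=y_mean, coef=coef, classes=classes,
        weights=W, x_loadings=P, y_loadings=Q,
        wavelengths=cal.wavelengths.copy(),
        preprocess=preprocess or PreprocessSpec(),
        cv_error=float(errors[n_lvs - 1]),
    )


def plsda_predict(model: PLSDAModel, spectra: np.ndarray):
    """Predict labels and continuous per-class indicator scores (for ROC)."""
    scores = model.scores(spectra)
    labels = np.asarray(model.classes)[np.argmax(scores, axis=1)]
    return labels, scores


def plsda_cv_error(
    X: np.ndarray, y: np.ndarray, n_lvs: int, n_splits: int = 10
) -> float:
    """Venetian-blinds CV misclassification of a fixed-LV PLS-DA.

    The shared evaluation criterion used by the wavelength selectors.
    """
    classes = []
    for s in y:
        if s not in classes:
            classes.append(s)
    n_lvs = min(n_lvs, X.shape[1])
    folds = venetian_folds(y, min(n_splits, len(y)))
    errors = _cv_misclassification_per_lv(X, y, classes, n_lvs, folds)
    return float(errors[-1])


# ---------------------------------------------------------------------------
# RBF-SVM


@dataclass
class SVMModel:
    c_exponent: int
    g_exponent: int
    svc: SVC = field(repr=False, default=None)
    scale_mean: np.ndarray = None
    scale_sd: np.ndarray = None
    classes: list = None
    wavelengths: np.ndarray = None
    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)
    cv_ccr: float = None


def _autoscale(X, mean, sd):
    return (X - mean) / sd


def svm_fit(
    table: SpectrumTable,
    exponent_range=range(-8, 9),
    cv: CVScheme | None = None,
    preprocess: PreprocessSpec | None = None,
) -> SVMModel:
    """Grid-search an RBF-SVM over c = 2^i, g = 2^j by venetian-blinds CV."""
    cv = cv or CVScheme()
    cal = table.calibration()
    classes = cal.class_order
    if len(classes) < 2:
        raise DegenerateClassesError("SVM requires at least two classes")
    X, y = cal.spectra, cal.species
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = _autoscale(X, mean, sd)
    folds = venetian_folds(y, min(cv.n_splits, len(y)))
    best = None  # (ccr, c_exp, g_exp); iteration order makes ties deterministic
    for c_exp in exponent_range:
        for g_exp in exponent_range:
            correct = 0
            for f in np.unique(folds):
                val = folds == f
                clf = SVC(C=2.0**c_exp, gamma=2.0**g_exp, kernel="rbf")
                clf.fit(Xs[~val], y[~val])
                correct += int((clf.predict(Xs[val]) == y[val]).sum())
            ccr = correct / len(y)
            if best is None or ccr > best[0]:
                best = (ccr, c_exp, g_exp)
    _, c_exp, g_exp = best
    svc = SVC(
        C=2.0**c_exp, gamma=2.0**g_exp, kernel="rbf",
        decision_function_shape="ovr",
    )
    svc.fit(Xs, y)
    return SVMModel(
        c_exponent=c_exp, g_exponent=g_exp, svc=svc,
        scale_mean=mean, scale_sd=sd, classes=classes,
        wavelengths=cal.wavelengths.copy(),
        preprocess=preprocess or PreprocessSpec(), cv_ccr=best[0],
    )


def svm_predict(model: SVMModel, spectra: np.ndarray):
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    if X.shape[1] != model.scale_mean.size:
        raise DimensionError(
            f"spectra have {X.shape[1]} bands; model expects {model.scale_mean.size}"
        )
    Xs = _autoscale(X, model.scale_mean, model.scale_sd)
    labels = model.svc.predict(Xs)
    scores = model.svc.decision_function(Xs)
    if scores.ndim == 2:  # reorder columns to the model's codebook order
        col = {c: j for j, c in enumerate(model.svc.classes_)}
        scores = scores[:, [col[c] for c in model.classes]]
    return labels, scores
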