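"""LASSO-PCR single-trial choice decoding and classifier uncertainty.

The decoder regresses a binary left/right choice on principal-component
scores of the trial x feature matrix (firing-rate features of the simulated
circuit, or single-trial hemodynamic response estimates), with a sparsity
penalty on the component coefficients:

1. center X on the training fold and decompose X = U S V^T; Z = U S are the
   component scores;
2. fit a penalized logistic regression of y in {-1, +1} on Z (the penalty is
   ``lasso`` — the method's namesake — or ``quadratic``; both are exposed and
   the choice is recorded in the model);
3. back-project the coefficients to feature space, w = V beta, so the model
   can score held-out trials and be read as a feature weight map;
4. graded predictions yhat = (1 - e^(-x.w)) / (1 + e^(-x.w)) in (-1, 1), with
   phat = (1 + yhat)/2 on the probability scale;
5. classifier uncertainty U = |phat - opt_choice|: the distance of the graded
   prediction from the objectively optimal choice (1 = left optimal,
   0 = right optimal). High U marks trials where the two action
   representations are co-active and hard to separate.

Cross-validation is leave-one-run-out: centering, SVD, and coefficients are
re-estimated on the training runs of every fold, so no statistic of the
held-out run ever enters the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score


@dataclass
class DecodeModel:
    """A fitted fold: centering vector, SVD basis, and coefficients."""

    mean_: np.ndarray
    V: np.ndarray                 # features x components, orthonormal columns
    S: np.ndarray
    beta: np.ndarray              # component-space coefficients
    intercept: float
    w: np.ndarray                 # feature-space weight map V @ beta
    C: float
    penalty: str

    def linear_score(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mean_) @ self.w + self.intercept

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Graded prediction ``yhat`` in (-1, 1) and probability ``phat``."""
        s = self.linear_score(X)
        return np.tanh(s / 2.0), expit(s)


def decompose(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Center X and return (mean, U, S, V, Z) with X_centered = U S V^T, Z = U S."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two trials")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    if not np.any(S > 0):
        raise ValueError("rank-0 input")
    keep = S > S[0] * 1e-12
    U, S, Vt = U[:, keep], S[keep], Vt[keep]
    return mean, U, S, Vt.T, U * S


def fit_penalized_logistic(
    Z: np.ndarray, y: np.ndarray, C: float = 1.0, penalty_mode: str = "lasso"
) -> tuple[np.ndarray, float]:
    """Penalized logistic regression of y in {-1,+1} on component scores.

    Minimizes ``pen(beta) + C * sum_i log(1 + exp(-y_i z_i.beta))`` where the
    penalty is ``|beta|_1`` (``"lasso"``) or ``(1/2) beta.beta``
    (``"quadratic"``); the intercept is part of beta and is penalized like
    any other coefficient. Returns (coefficients, intercept).
    """
    y = np.asarray(y)
    if set(np.unique(y)) - {-1, 1}:
        raise ValueError("labels must be coded -1/+1")
    if len(np.unique(y)) < 2:
        raise ValueError("single-class labels")
    if C <= 0:
        raise ValueError("C must be positive")
    l1_ratio = {"lasso": 1.0, "quadratic": 0.0}[penalty_mode]
    clf = LogisticRegression(
        l1_ratio=l1_ratio,
        C=C,
        solver="liblinear",
        fit_intercept=True,
        intercept_scaling=1.0,
        tol=1e-9,
        max_iter=20000,
    )
    clf.fit(Z, y)
    return clf.coef_.ravel().copy(), float(clf.intercept_[0])


def project_weights(V: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Back-project component coefficients to the feature space: w = V beta."""
    return V @ beta


def encode_pattern(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Forward-model (encoding) pattern of a linear decoder.

    A = cov(X) w / var(X w): the activation pattern whose presence the
    decoder's weight map detects. Unlike raw weights, A is interpretable as
    the features' signed tuning toward the decoded class.
    """
    Xc = X - X.mean(axis=0)
    s = Xc @ w
    denom = s.var(ddof=1)
    if denom == 0:
        return np.zeros_like(w)
    return (Xc.T @ (s - s.mean())) / ((len(s) - 1) * denom)


def fit_decoder(
    X: np.ndarray, y: np.ndarray, C: float = 1.0, penalty: str = "lasso",
    n_components: int | None = None,
) -> DecodeModel:
    """Fit one LASSO-PCR model on a training fold."""
    mean, U, S, V, Z = decompose(X)
    if n_components is not None:
        V, S, Z = V[:, :n_components], S[:n_components], Z[:, :n_components]
    beta, intercept = fit_penalized_logistic(Z, y, C=C, penalty_mode=penalty)
    w = project_weights(V, beta)
    return DecodeModel(mean, V, S, beta, intercept, w, C, penalty)


def uncertainty(phat: np.ndarray | float, opt_choice: np.ndarray | int) -> np.ndarray | float:
    """Classifier uncertainty U = |phat - opt_choice| in [0, 1].

    ``phat`` is the predicted probability of a left response; ``opt_choice``
    codes the optimal side on the same scale (left = 1, right = 0). U is the
    one-dimensional Euclidean distance between them: 0 when the decoder is
    certain of the optimal action, 1 at maximal miscoding.
    """
    phat = np.asarray(phat, dtype=float)
    opt = np.asarray(opt_choice, dtype=float)
    if np.any((opt != 0) & (opt != 1)):
        raise ValueError("opt_choice must be coded 0/1")
    out = np.abs(phat - opt)
    return float(out) if out.ndim == 0 else out


def _auc_concordance(y: np.ndarray, score: np.ndarray) -> float:
    """Brute-force pairwise concordance AUC (test oracle; O(n^2))."""
    pos = score[y > 0]
    neg = score[y < 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


@dataclass
class CVResult:
    fold_metrics: pd.DataFrame
    yhat: np.ndarray
    phat: np.ndarray
    accuracy: float
    auc: float
    models: list = field(repr=False, default_factory=list)


def _inner_select_c(X, y, runs, c_grid, penalty, n_components):
    """Pick C by nested leave-one-run-out accuracy on the training runs."""
    best_c, best_acc = c_grid[0], -1.0
    for c in c_grid:
        inner = cross_validate(X, y, runs, C=c, penalty=penalty,
                               n_components=n_components)
        if inner.accuracy > best_acc:
            best_c, best_acc = c, inner.accuracy
    return best_c


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    runs: np.ndarray,
    C: float = 1.0,
    penalty: str = "lasso",
    n_components: int | None = None,
    keep_models: bool = False,
    c_grid: tuple | None = None,
) -> CVResult:
    """Leave-one-run-out cross-validation of the LASSO-PCR decoder.

    Every fold holds out one run; the centering vector, SVD basis and
    coefficients are estimated on the remaining runs only. Returns per-fold
    accuracy, pooled held-out predictions, overall accuracy and ROC AUC.
    Folds whose training data contain a single class are flagged and skipped.
    ``c_grid`` switches on nested per-fold selection of the penalty constant
    (off by default: C stays fixed).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    runs = np.asarray(runs)
    uniq = np.unique(runs)
    if len(uniq) < 2:
        raise ValueError("need at least two runs")
    yhat = np.full(len(y), np.nan)
    phat = np.full(len(y), np.nan)
    rows, models = [], []
    for r in uniq:
        test = runs == r
        train = ~test
        if test.sum() == 0:
            continue
        if np.intersect1d(np.where(test)[0], np.where(train)[0]).size:
            raise RuntimeError("train/test overlap")  # leakage guard
        if len(np.unique(y[train])) < 2:
            rows.append(dict(run=r, n_test=int(test.sum()), accuracy=np.nan, skipped=True))
            continue
        c_fold = C
        if c_grid is not None:
            c_fold = _inner_select_c(X[train], y[train], runs[train],
                                     c_grid, penalty, n_components)
        model = fit_decoder(X[train], y[train], C=c_fold, penalty=penalty,
                            n_components=n_components)
        yh, ph = model.predict(X[test])
        yhat[test], phat[test] = yh, ph
        acc = float(np.mean(np.sign(yh) == y[test]))
        rows.append(dict(run=r, n_test=int(test.sum()), accuracy=acc, skipped=False))
        if keep_models:
            models.append(model)
    scored = ~np.isnan(yhat)
    accuracy = float(np.mean(np.sign(yhat[scored]) == y[scored]))
    auc = float(roc_auc_score((y[scored] > 0).astype(int), yhat[scored]))
    return CVResult(pd.DataFrame(rows), yhat, phat, accuracy, auc, models)
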