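"""Elastic-net solver engine with glmnet-style conventions.

The penalized least-squares objective at mixing parameter ``l1_ratio`` (the
glmnet alpha) and penalty strength ``lam`` (the glmnet lambda) is

    (1/(2n)) * sum_i (y_i - b0 - x_i.b)^2
        + lam * ( l1_ratio * ||b||_1 + (1 - l1_ratio)/2 * ||b||_2^2 )

with an unpenalized intercept.  Predictors are centered and scaled to unit
(population) standard deviation during optimization and the coefficients are
back-transformed to the original scale, so fitted clocks apply directly to
raw beta values.  The penalty path is geometric from lambda_max — the
smallest penalty at which every coefficient is zero — down by
``lambda_min_ratio``; lambda is selected by K-fold cross-validated mean
squared error (``"min"``) or the one-standard-error rule (``"1se"``).

Coordinate descent for 0 < l1_ratio <= 1 is delegated to scikit-learn's
``enet_path``; pure ridge (l1_ratio = 0) is solved in closed form via SVD.
The binomial-likelihood analogue used for confounder screening follows the
same path and CV conventions with deviance loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, enet_path
from sklearn.model_selection import KFold, StratifiedKFold

from .data import InsufficientDataError

__all__ = [
    "EnetFit",
    "standardize",
    "make_lambda_path",
    "coef_path",
    "fit_enet_cv",
    "fit_logistic_enet_cv",
    "enet_objective",
]

_ALPHA_FLOOR = 1e-3  # lambda_max divisor floor so ridge paths stay finite


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale columns to unit population SD.

    Constant columns get scale 1 (they carry no signal and end with zero
    coefficients).  Returns (X_std, mean, scale).
    """
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def make_lambda_path(
    X_std: np.ndarray,
    y: np.ndarray,
    l1_ratio: float,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-4,
) -> np.ndarray:
    """Geometric penalty path from lambda_max down, strictly decreasing."""
    n = X_std.shape[0]
    resid = y - y.mean()
    lam_max = np.max(np.abs(X_std.T @ resid)) / (n * max(l1_ratio, _ALPHA_FLOOR))
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)


def coef_path(
    X_std: np.ndarray,
    y_centered: np.ndarray,
    l1_ratio: float,
    lambdas: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 3000,
) -> np.ndarray:
    """Coefficients along a decreasing penalty path; shape (p, len(lambdas))."""
    if l1_ratio == 0.0:
        # ridge closed form b = (X'X + n*lam*I)^-1 X'y via SVD, exact per lambda
        n = X_std.shape[0]
        U, s, Vt = np.linalg.svd(X_std, full_matrices=False)
        uty = U.T @ y_centered
        coefs = np.empty((X_std.shape[1], len(lambdas)))
        for k, lam in enumerate(lambdas):
            d = s / (s**2 + n * lam)
            coefs[:, k] = Vt.T @ (d * uty)
        return coefs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = enet_path(
            np.asfortranarray(X_std),
            y_centered,
            l1_ratio=l1_ratio,
            alphas=lambdas,
            tol=tol,
            max_iter=max_iter,
        )
    return coefs


@dataclass
class EnetFit:
    """Result of a cross-validated elastic-net fit, on the original x scale."""

    intercept: float
    coef: np.ndarray
    lambda_: float
    lambda_index: int
    lambda_path: np.ndarray
    cv_score: np.ndarray        # mean CV loss per lambda (MSE or deviance)
    cv_se: np.ndarray           # SE of the fold losses per lambda
    l1_ratio: float

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coef))


def _select_lambda(cv_mean: np.ndarray, cv_se: np.ndarray, rule: str) -> int:
    """Index into a decreasing lambda path; ties resolve to the largest lambda."""
    best = int(np.argmin(cv_mean))
    # prefer the largest lambda whose loss matches the minimum (to fp noise)
    tol = 1e-10 * max(1.0, abs(cv_mean[best]))
    candidates = np.flatnonzero(cv_mean <= cv_mean[best] + tol)
    best = int(candidates[0])
    if rule == "min":
        return best
    if rule == "1se":
        cutoff = cv_mean[best] + cv_se[best]
        ok = np.flatnonzero(cv_mean <= cutoff)
        return int(ok[0])
    raise ValueError(f"unknown lambda selection rule {rule!r}")


def fit_enet_cv(
    X: np.ndarray,
    y: np.ndarray,
    l1_ratio: float,
    n_folds: int = 10,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-4,
    seed: int = 0,
    lambdas: np.ndarray | None = None,
    lambda_selection: str = "min",
    tol: float = 1e-4,
) -> EnetFit:
    """Gaussian elastic net with internal K-fold CV for the penalty.

    Per-fold standardization statistics are recomputed on each training fold
    (no leakage of the held-out fold into the scaling).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional (samples x predictors)")
    n, p = X.shape
    if not (0.0 <= l1_ratio <= 1.0):
        raise ValueError(f"l1_ratio (mixing alpha) must be in [0, 1], got {l1_ratio}")
    if np.isnan(X).any():
        raise ValueError("X contains missing values; drop incomplete probes first")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    if y.size != n:
        raise ValueError("X and y have incompatible shapes")
    if np.ptp(y) == 0:
        raise InsufficientDataError("degenerate fit: y is constant")
    if n < n_folds:
        raise InsufficientDataError(
            f"need at least n_folds={n_folds} samples, got {n}"
        )

    Xs_full, mu, sd = standardize(X)
    if lambdas is None:
        lam_path = make_lambda_path(Xs_full, y, l1_ratio, n_lambdas, lambda_min_ratio)
    else:
        lam_path = np.sort(np.atleast_1d(np.asarray(lambdas, dtype=float)))[::-1]
    L = lam_path.size

    if L > 1:
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        fold_mse = np.empty((n_folds, L))
        for f, (tr, va) in enumerate(kf.split(X)):
            Xt, mt, st = standardize(X[tr])
            yt = y[tr]
            coefs = coef_path(Xt, yt - yt.mean(), l1_ratio, lam_path, tol=tol)
            Xv = (X[va] - mt) / st
            pred = Xv @ coefs + yt.mean()
            fold_mse[f] = np.mean((y[va][:, None] - pred) ** 2, axis=0)
        cv_mean = fold_mse.mean(axis=0)
        cv_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(n_folds)
        idx = _select_lambda(cv_mean, cv_se, lambda_selection)
    else:  # a single fixed penalty: nothing to cross-validate
        cv_mean = np.zeros(L)
        cv_se = np.zeros(L)
        idx = 0

    coefs_full = coef_path(Xs_full, y - y.mean(), l1_ratio, lam_path, tol=tol)
    b_std = coefs_full[:, idx]
    coef = b_std / sd
    intercept = float(y.mean() - coef @ mu)
    return EnetFit(
        intercept=intercept,
        coef=coef,
        lambda_=float(lam_path[idx]),
        lambda_index=idx,
        lambda_path=lam_path,
        cv_score=cv_mean,
        cv_se=cv_se,
        l1_ratio=l1_ratio,
    )


def enet_objective(
    X: np.ndarray, y: np.ndarray, intercept: float, coef: np.ndarray,
    lam: float, l1_ratio: float,
) -> float:
    """Value of the penalized least-squares objective (documented above)."""
    n = X.shape[0]
    resid = y - intercept - X @ coef
    return float(
        resid @ resid / (2 * n)
        + lam * (l1_ratio * np.abs(coef).sum() + (1 - l1_ratio) / 2 * coef @ coef)
    )


# ---------------------------------------------------------------------------
# Binomial (logistic) elastic net for confounder screening
# ---------------------------------------------------------------------------


def _logit_path(
    X_std: np.ndarray,
    y01: np.ndarray,
    l1_ratio: float,
    lambdas: np.ndarray,
    seed: int = 0,
    max_iter: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started logistic elastic-net path; returns (coefs p x L, intercepts L)."""
    n = X_std.shape[0]
    clf = LogisticRegression(
        solver="saga",
        l1_ratio=l1_ratio,
        warm_start=True,
        fit_intercept=True,
        max_iter=max_iter,
        tol=1e-6,
        random_state=seed,  # saga samples coordinates stochastically
    )
    coefs = np.empty((X_std.shape[1], lambdas.size))
    icepts = np.empty(lambdas.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for k, lam in enumerate(lambdas):
            clf.C = 1.0 / (n * lam)
            clf.fit(X_std, y01)
            coefs[:, k] = clf.coef_[0]
            icepts[k] = clf.intercept_[0]
    return coefs, icepts


def _binomial_deviance(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Mean binomial deviance per column of linear predictors ``eta``."""
    p = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    ll = y[:, None] * np.log(p) + (1 - y)[:, None] * np.log(1 - p)
    return -2.0 * ll.mean(axis=0)


def fit_logistic_enet_cv(
    X: np.ndarray,
    y01: np.ndarray,
    l1_ratio: float = 0.5,
    n_folds: int = 10,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-2,
    seed: int = 0,
    lambda_selection: str = "min",
) -> EnetFit:
    """Binomial elastic net: penalty path + stratified K-fold CV on deviance.

    ``y01`` is the binary label vector ({0, 1}); both classes must occur.
    """
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(y01, dtype=float)
    n = X.shape[0]
    classes = np.unique(y01)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("labels must be encoded 0/1")
    if classes.size < 2:
        raise InsufficientDataError("confounder screen requires both classes present")

    Xs, mu, sd = standardize(X)
    # lambda_max at the null model (fitted probability = class mean)
    resid = y01 - y01.mean()
    lam_max = np.max(np.abs(Xs.T @ resid)) / (n * max(l1_ratio, _ALPHA_FLOOR))
    lam_path = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)

    n_folds_eff = min(n_folds, int(np.min(np.bincount(y01.astype(int)))))
    if n_folds_eff < 2:
        raise InsufficientDataError("need at least 2 samples per class for CV")
    skf = StratifiedKFold(n_splits=n_folds_eff, shuffle=True, random_state=seed)
    fold_dev = np.empty((n_folds_eff, lam_path.size))
    for f, (tr, va) in enumerate(skf.split(X, y01)):
        Xt, mt, st = standardize(X[tr])
        coefs, icepts = _logit_path(Xt, y01[tr], l1_ratio, lam_path, seed=seed)
        eta = ((X[va] - mt) / st) @ coefs + icepts
        fold_dev[f] = _binomial_deviance(y01[va], eta)
    cv_mean = fold_dev.mean(axis=0)
    cv_se = fold_dev.std(axis=0, ddof=1) / np.sqrt(n_folds_eff)
    idx = _select_lambda(cv_mean, cv_se, lambda_selection)

    coefs_full, icepts_full = _logit_path(Xs, y01, l1_ratio, lam_path, seed=seed)
    b_std = coefs_full[:, idx]
    coef = b_std / sd
    intercept = float(icepts_full[idx] - coef @ mu)
    return EnetFit(
        intercept=intercept,
        coef=coef,
        lambda_=float(lam_path[idx]),
        lambda_index=idx,
        lambda_path=lam_path,
        cv_score=cv_mean,
        cv_se=cv_se,
        l1_ratio=l1_ratio,
    )
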