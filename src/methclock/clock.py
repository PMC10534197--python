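"""Elastic-net epigenetic clock training, selection and application.

:class:`ElasticNetClockCV` is a scikit-learn style regressor implementing the
glmnet-convention elastic net with an internally cross-validated penalty (see
:mod:`methclock.enet` for the objective and conventions).  Around it sit the
pipeline steps used to build a clock from a beta matrix: filtering probes by
detection p-value, sweeping a grid over the mixing parameter alpha and the
filter threshold, selecting a parsimonious candidate, predicting ages, merging
multi-species training sets, and comparing clocks by CpG overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import enet
from .data import (
    BetaMatrix,
    ClockModel,
    MergeError,
    Metrics,
    SampleMetadata,
    ValidationError,
)
from .preprocess import filter_probes_by_detection

__all__ = [
    "ElasticNetSpec",
    "ElasticNetClockCV",
    "CandidateGrid",
    "fit_elastic_net",
    "alpha_grid_search",
    "select_model",
    "predict_age",
    "merge_training_sets",
    "clock_overlap",
    "training_frame",
]

DEFAULT_ALPHAS = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))
DEFAULT_THRESHOLDS = (0, 10, 20, 30)


@dataclass
class ElasticNetSpec:
    """Hyper-parameters of a cross-validated elastic-net fit.

    alpha is the lasso/ridge mixing parameter in [0, 1]; the penalty path has
    ``n_penalties`` geometric values down to ``penalty_min_ratio`` of the
    maximal penalty; ``penalty_selection`` is ``"min"`` (CV-MSE minimiser,
    default) or ``"1se"``.
    """

    alpha: float = 0.9
    n_folds: int = 10
    n_penalties: int = 100
    penalty_min_ratio: float = 1e-4
    seed: int = 0
    penalty_selection: str = "min"

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


class ElasticNetClockCV(BaseEstimator, RegressorMixin):
    """Elastic-net age regression with internally cross-validated penalty.

    Parameters follow the glmnet conventions: ``l1_ratio`` is the mixing
    parameter alpha (1 = lasso, 0 = ridge); the penalty strength lambda is
    chosen on a geometric path by K-fold cross-validated mean squared error.
    Predictors are standardized internally and coefficients returned on the
    original scale, so a fitted clock applies directly to raw beta values.

    Attributes (after ``fit``)
    --------------------------
    coef_ : ndarray (n_features,)
        Coefficients in years per unit beta (dense; mostly zero).
    intercept_ : float
    lambda_ : float
        Selected penalty strength.
    lambda_path_, cv_mse_, cv_se_ : ndarray
        The penalty path and its cross-validation profile.
    feature_names_in_ : ndarray of str, when fitted from a DataFrame.
    """

    def __init__(
        self,
        l1_ratio: float = 0.9,
        n_folds: int = 10,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 1e-4,
        lambdas=None,
        lambda_selection: str = "min",
        random_state: int = 0,
        tol: float = 1e-4,
    ):
        self.l1_ratio = l1_ratio
        self.n_folds = n_folds
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.lambdas = lambdas
        self.lambda_selection = lambda_selection
        self.random_state = random_state
        self.tol = tol

    def fit(self, X, y):
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray([str(c) for c in X.columns])
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        res = enet.fit_enet_cv(
            X,
            y,
            l1_ratio=self.l1_ratio,
            n_folds=self.n_folds,
            n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            seed=self.random_state,
            lambdas=self.lambdas,
            lambda_selection=self.lambda_selection,
            tol=self.tol,
        )
        self.n_features_in_ = X.shape[1]
        self.coef_ = res.coef
        self.intercept_ = res.intercept
        self.lambda_ = res.lambda_
        self.lambda_path_ = res.lambda_path
        self.cv_mse_ = res.cv_score
        self.cv_se_ = res.cv_se
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        if hasattr(X, "columns"):
            X = X.to_numpy(dtype=float)
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    @property
    def n_nonzero_(self) -> int:
        check_is_fitted(self, "coef_")
        return int(np.count_nonzero(self.coef_))

    def to_clock_model(
        self,
        probe_ids: Sequence[str] | None = None,
        cpg_filter_threshold: int = 0,
        training_set_label: str = "",
        n_training: int | None = None,
    ) -> ClockModel:
        """Export the fitted model as a sparse :class:`ClockModel`."""
        check_is_fitted(self, "coef_")
        if probe_ids is None:
            probe_ids = getattr(self, "feature_names_in_", None)
            if probe_ids is None:
                raise ValueError("probe_ids required when fitted from a bare array")
        coefs = {
            str(pid): float(c)
            for pid, c in zip(probe_ids, self.coef_)
            if c != 0.0
        }
        return ClockModel(
            intercept=self.intercept_,
            coefficients=coefs,
            training_meta={
                "alpha": self.l1_ratio,
                "penalty": self.lambda_,
                "cpg_filter_threshold": int(cpg_filter_threshold),
                "training_set_label": training_set_label,
                "n_training": int(n_training if n_training is not None else -1),
                "seed": int(self.random_state),
            },
        )


def training_frame(
    m: BetaMatrix,
    meta: Sequence[SampleMetadata],
    tier: str = "strict",
) -> tuple[pd.DataFrame, pd.Series]:
    """Build the samples x probes design frame and age vector for training.

    ``tier`` selects samples: ``"strict"`` (high-confidence ages only),
    ``"relaxed"`` (strict plus relaxed_only), or ``"any"`` (any sample with a
    known age).  Samples are ordered lexicographically by id so results do not
    depend on input order; probes with any missing beta among the selected
    samples are dropped.  Fails loudly if a selected sample is absent from the
    matrix.
    """
    if tier == "strict":
        chosen = [r for r in meta if r.in_strict]
    elif tier == "relaxed":
        chosen = [r for r in meta if r.in_relaxed and r.age_years is not None]
    elif tier == "any":
        chosen = [r for r in meta if r.age_years is not None]
    else:
        raise ValueError(f"unknown tier {tier!r}")
    chosen = sorted(chosen, key=lambda r: r.sample_id)
    if not chosen:
        raise ValidationError(f"no samples with known age in tier {tier!r}")
    missing = [r.sample_id for r in chosen if r.sample_id not in m.betas.columns]
    if missing:
        raise ValidationError(f"metadata samples absent from beta matrix: {missing[:5]}")
    X = m.betas[[r.sample_id for r in chosen]].T  # samples x probes
    X = X.dropna(axis=1)
    y = pd.Series([r.age_years for r in chosen], index=X.index, name="age_years")
    return X, y


def fit_elastic_net(
    x: pd.DataFrame,
    y: Sequence[float],
    spec: ElasticNetSpec,
    cpg_filter_threshold: int = 0,
    training_set_label: str = "",
) -> ClockModel:
    """Fit one cross-validated elastic net and return the sparse clock."""
    est = ElasticNetClockCV(
        l1_ratio=spec.alpha,
        n_folds=spec.n_folds,
        n_lambdas=spec.n_penalties,
        lambda_min_ratio=spec.penalty_min_ratio,
        lambda_selection=spec.penalty_selection,
        random_state=spec.seed,
    ).fit(x, np.asarray(y, dtype=float))
    return est.to_clock_model(
        probe_ids=list(x.columns),
        cpg_filter_threshold=cpg_filter_threshold,
        training_set_label=training_set_label,
        n_training=x.shape[0],
    )


@dataclass
class CandidateGrid:
    """All candidate clocks from an (alpha x filter-threshold) sweep."""

    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            rec = {
                "alpha": row["alpha"],
                "cpg_filter_threshold": row["cpg_filter_threshold"],
                "n_coefficients": row["n_coefficients"],
            }
            rec.update(row["metrics"].as_dict())
            recs.append(rec)
        return pd.DataFrame(recs)


def alpha_grid_search(
    m: BetaMatrix,
    meta: Sequence[SampleMetadata],
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    spec: ElasticNetSpec | None = None,
    tier: str = "strict",
) -> CandidateGrid:
    """Sweep candidate clocks over filter thresholds and mixing alphas.

    For each threshold the probe set is filtered by detection p-value
    (threshold 0 = no filtering), then one cross-validated elastic net is fit
    per alpha; rows carry in-sample metrics, the coefficient count and the
    fitted :class:`ClockModel`.
    """
    from .validation import compute_metrics  # local import avoids a cycle

    spec = spec or ElasticNetSpec()
    X_all, y = training_frame(m, meta, tier=tier)
    grid = CandidateGrid()
    for thr in thresholds:
        if thr == 0:
            cols = list(X_all.columns)
        else:
            sub = m.select_samples(list(X_all.index))
            fr = filter_probes_by_detection(sub, thr)
            cols = [p for p in X_all.columns if p in fr.retained_probes]
        if not cols:
            raise ValidationError(
                f"no probes survive detection filtering at threshold {thr}"
            )
        X = X_all[cols]
        for a in alphas:
            sp = ElasticNetSpec(
                alpha=float(a),
                n_folds=spec.n_folds,
                n_penalties=spec.n_penalties,
                penalty_min_ratio=spec.penalty_min_ratio,
                seed=spec.seed,
                penalty_selection=spec.penalty_selection,
            )
            model = fit_elastic_net(
                X, y, sp, cpg_filter_threshold=thr, training_set_label=tier
            )
            pred = predict_age(model, m.select_samples(list(X.index)))
            pred_v = np.array([pred[s] for s in X.index])
            metrics = compute_metrics(y.to_numpy(), pred_v)
            grid.rows.append(
                {
                    "alpha": float(a),
                    "cpg_filter_threshold": int(thr),
                    "n_coefficients": model.n_terms,
                    "metrics": metrics,
                    "model": model,
                }
            )
    return grid


def select_model(grid: CandidateGrid, medae_tolerance: float = 0.05) -> ClockModel:
    """Pick the most parsimonious near-optimal candidate.

    Among rows whose median absolute error is within ``medae_tolerance``
    years of the grid minimum, returns the one with the fewest CpG terms;
    ties break toward larger alpha, then larger filter threshold.
    """
    if not grid.rows:
        raise ValueError("empty candidate grid")
    best_medae = min(r["metrics"].medae for r in grid.rows)
    eligible = [r for r in grid.rows if r["metrics"].medae <= best_medae + medae_tolerance]
    chosen = min(
        eligible,
        key=lambda r: (r["n_coefficients"], -r["alpha"], -r["cpg_filter_threshold"]),
    )
    return chosen["model"]


def predict_age(
    model: ClockModel,
    m: BetaMatrix,
    missing_policy: str = "error",
) -> dict[str, float]:
    """Apply a clock to a beta matrix: age = intercept + sum(coef * beta).

    ``missing_policy`` governs samples lacking a clock probe (absent row or
    NaN beta): ``"error"`` raises naming the probe and sample;
    ``"skip_sample"`` omits those samples from the result.  Negative
    predictions are legitimate (fetal/neonatal samples).
    """
    if missing_policy not in ("error", "skip_sample"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    probes = model.probe_ids
    absent = [p for p in probes if p not in m.betas.index]
    if absent and missing_policy == "error":
        raise ValidationError(f"clock probes absent from matrix: {absent}")
    present = [p for p in probes if p not in absent]
    sub = m.betas.loc[present]
    coef = np.array([model.coefficients[p] for p in present])
    out: dict[str, float] = {}
    for s in m.sample_ids:
        v = sub[s].to_numpy(dtype=float)
        nan_at = np.isnan(v)
        if absent or nan_at.any():
            if missing_policy == "error":
                bad = [present[i] for i in np.flatnonzero(nan_at)]
                raise ValidationError(
                    f"sample {s!r} missing beta for clock probe(s) {bad}"
                )
            continue
        out[s] = float(model.intercept + coef @ v)
    return out


def merge_training_sets(
    a: tuple[BetaMatrix, Sequence[SampleMetadata]],
    b: tuple[BetaMatrix, Sequence[SampleMetadata]],
) -> tuple[BetaMatrix, list[SampleMetadata]]:
    """Concatenate two training sets on their shared probe universe.

    Used to pool species for a joint clock: probes are intersected (in the
    first set's order), samples concatenated with group labels preserved, and
    no species covariate is introduced.  Detection p-values are kept only if
    both sets carry them.
    """
    ma, meta_a = a
    mb, meta_b = b
    shared = [p for p in ma.probe_ids if p in set(mb.probe_ids)]
    if not shared:
        raise MergeError("no probes shared between the two training sets")
    dup = set(ma.sample_ids) & set(mb.sample_ids)
    if dup:
        raise MergeError(f"duplicate sample ids across sets: {sorted(dup)[:5]}")
    betas = pd.concat([ma.betas.loc[shared], mb.betas.loc[shared]], axis=1)
    dp = None
    if ma.detection_p is not None and mb.detection_p is not None:
        dp = pd.concat([ma.detection_p.loc[shared], mb.detection_p.loc[shared]], axis=1)
    merged = BetaMatrix(betas, dp)
    return merged, list(meta_a) + list(meta_b)


def clock_overlap(a: ClockModel, b: ClockModel) -> set[str]:
    """CpG probes shared by two clocks (intersection of coefficient keys)."""
    return set(a.coefficients) & set(b.coefficients)
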