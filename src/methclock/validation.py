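"""Clock validation: accuracy metrics, leave-one-out CV, confounder screens.

Metrics summarize predicted-vs-true ages (mean and median absolute error in
years, Pearson r, and the regression of predicted on true).  LOOCV refits the
whole pipeline — probe filtering included — with each training sample held
out in turn.  Confounder screening fits a binomial elastic net on a binary
nuisance label (subspecies, tissue source) and checks that no diagnostic CpG
leaked into a clock.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import enet
from .clock import ElasticNetSpec, fit_elastic_net, predict_age, training_frame
from .data import (
    BetaMatrix,
    ClockModel,
    InsufficientDataError,
    Metrics,
    SampleMetadata,
)
from .preprocess import filter_probes_by_detection

__all__ = [
    "ValidationReport",
    "DiagnosticScreen",
    "ConfoundingReport",
    "LogisticScreenCV",
    "compute_metrics",
    "in_sample_report",
    "loocv",
    "confounder_screen",
    "check_clock_confounding",
]


def compute_metrics(true_ages, predicted_ages) -> Metrics:
    """Accuracy metrics for paired true/predicted ages (n >= 3).

    mae/medae are the mean and median of |predicted - true| in years;
    the slope/intercept/p come from the simple regression of predicted on
    true age, and r_squared is the squared Pearson correlation.
    """
    t = np.asarray(true_ages, dtype=float)
    p = np.asarray(predicted_ages, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("true and predicted ages must be equal-length vectors")
    if t.size < 3:
        raise InsufficientDataError("metrics need at least 3 paired ages")
    err = np.abs(p - t)
    reg = stats.linregress(t, p)
    return Metrics(
        mae=float(err.mean()),
        medae=float(np.median(err)),
        pearson_r=float(reg.rvalue),
        r_squared=float(reg.rvalue**2),
        reg_slope=float(reg.slope),
        reg_intercept=float(reg.intercept),
        reg_p=float(reg.pvalue),
    )


@dataclass
class ValidationReport:
    """Predicted-vs-true ages plus summary metrics.

    ``per_sample`` is indexed by sample id with columns ``true_age`` and
    ``predicted_age``; ``mode`` is ``"in_sample"`` or ``"loocv"``.
    """

    per_sample: pd.DataFrame
    metrics: Metrics
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return self.per_sample.copy()


def in_sample_report(
    model: ClockModel, m: BetaMatrix, meta: Sequence[SampleMetadata], tier: str = "strict"
) -> ValidationReport:
    """Apply a fitted clock back to its training tier and summarize."""
    X, y = training_frame(m, meta, tier=tier)
    pred = predict_age(model, m.select_samples(list(X.index)))
    pv = np.array([pred[s] for s in X.index])
    df = pd.DataFrame(
        {"true_age": y.to_numpy(), "predicted_age": pv},
        index=pd.Index(X.index, name="sample_id"),
    )
    return ValidationReport(per_sample=df, metrics=compute_metrics(df.true_age, df.predicted_age), mode="in_sample")


def loocv(
    m: BetaMatrix,
    meta: Sequence[SampleMetadata],
    alpha: float,
    threshold: int = 0,
    spec: ElasticNetSpec | None = None,
    tier: str = "strict",
    refilter: bool = True,
) -> ValidationReport:
    """Leave-one-out cross-validation of the full training pipeline.

    For each aged sample, probes are re-filtered on the remaining n - 1
    samples (unless ``refilter=False``, which reuses the whole-set filter and
    reproduces the optimistic variant), the elastic net is refit, and the
    held-out sample predicted.  Per-sample predictions depend only on the
    sample ids and the seed, not on input order.
    """
    spec = spec or ElasticNetSpec()
    X_all, y = training_frame(m, meta, tier=tier)
    sample_ids = list(X_all.index)
    if len(sample_ids) < spec.n_folds + 1:
        raise InsufficientDataError(
            f"LOOCV needs at least n_folds + 1 = {spec.n_folds + 1} samples"
        )
    sp = ElasticNetSpec(
        alpha=alpha,
        n_folds=spec.n_folds,
        n_penalties=spec.n_penalties,
        penalty_min_ratio=spec.penalty_min_ratio,
        seed=spec.seed,
        penalty_selection=spec.penalty_selection,
    )

    global_cols = None
    if threshold > 0 and not refilter:
        fr = filter_probes_by_detection(m.select_samples(sample_ids), threshold)
        global_cols = [p for p in X_all.columns if p in fr.retained_probes]

    preds: dict[str, float] = {}
    for held in sample_ids:
        rest = [s for s in sample_ids if s != held]
        if threshold > 0 and refilter:
            fr = filter_probes_by_detection(m.select_samples(rest), threshold)
            cols = [p for p in X_all.columns if p in fr.retained_probes]
        elif global_cols is not None:
            cols = global_cols
        else:
            cols = list(X_all.columns)
        Xtr = X_all.loc[rest, cols]
        try:
            model = fit_elastic_net(Xtr, y.loc[rest], sp, cpg_filter_threshold=threshold)
        except Exception as exc:
            raise RuntimeError(f"LOOCV fold holding out {held!r} failed: {exc}") from exc
        x_held = X_all.loc[held, cols]
        used = model.probe_ids
        vals = x_held[used].to_numpy(dtype=float)
        if np.isnan(vals).any():
            warnings.warn(f"held-out sample {held} missing a clock probe; skipped")
            continue
        preds[held] = float(
            model.intercept + np.array([model.coefficients[p] for p in used]) @ vals
        )

    df = pd.DataFrame(
        {
            "true_age": [y.loc[s] for s in preds],
            "predicted_age": list(preds.values()),
        },
        index=pd.Index(list(preds), name="sample_id"),
    ).sort_index()
    return ValidationReport(
        per_sample=df,
        metrics=compute_metrics(df.true_age, df.predicted_age),
        mode="loocv",
    )


# ---------------------------------------------------------------------------
# Confounder screening
# ---------------------------------------------------------------------------


@dataclass
class DiagnosticScreen:
    """CpGs diagnostic of a binary nuisance label (nonzero logistic-enet
    coefficients at the CV-selected penalty)."""

    label_name: str
    diagnostic_probes: set[str]
    alpha_used: float = 0.5


class LogisticScreenCV(BaseEstimator, ClassifierMixin):
    """Binomial elastic net with cross-validated penalty (screening model).

    Mirrors :class:`methclock.clock.ElasticNetClockCV` with a logistic link
    and binomial-deviance CV loss; ``l1_ratio`` defaults to 0.5.  After
    ``fit``: ``coef_``, ``intercept_``, ``lambda_``, ``selected_features_``
    (indices of nonzero coefficients).
    """

    def __init__(
        self,
        l1_ratio: float = 0.5,
        n_folds: int = 10,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 1e-2,
        lambda_selection: str = "1se",
        random_state: int = 0,
    ):
        self.l1_ratio = l1_ratio
        self.n_folds = n_folds
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.lambda_selection = lambda_selection
        self.random_state = random_state

    def fit(self, X, y):
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray([str(c) for c in X.columns])
            X = X.to_numpy(dtype=float)
        y = np.asarray(y, dtype=float)
        res = enet.fit_logistic_enet_cv(
            np.asarray(X, dtype=float),
            y,
            l1_ratio=self.l1_ratio,
            n_folds=self.n_folds,
            n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            seed=self.random_state,
            lambda_selection=self.lambda_selection,
        )
        self.classes_ = np.array([0.0, 1.0])
        self.n_features_in_ = np.asarray(X).shape[1]
        self.coef_ = res.coef
        self.intercept_ = res.intercept
        self.lambda_ = res.lambda_
        self.selected_features_ = np.flatnonzero(res.coef)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        if hasattr(X, "columns"):
            X = X.to_numpy(dtype=float)
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        eta = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(float)


def confounder_screen(
    m: BetaMatrix,
    labels: Mapping[str, int],
    label_name: str = "label",
    spec: ElasticNetSpec | None = None,
) -> DiagnosticScreen:
    """Screen for CpGs diagnostic of a binary sample label.

    ``labels`` maps sample id to {0, 1} ("1" being the group of concern, e.g.
    biopsy tissue).  A binomial elastic net at mixing alpha 0.5 (unless the
    spec overrides it) is fit on the labelled samples; probes with nonzero
    coefficients at the CV-selected penalty are returned.  By default the
    screen uses the one-standard-error penalty rule: on permuted (null)
    labels the CV-deviance-minimizing penalty frequently admits a handful of
    noise CpGs, while the 1-SE rule keeps the null screen mostly empty
    without losing genuinely separating probes.
    """
    spec = spec or ElasticNetSpec(alpha=0.5, penalty_selection="1se")
    ids = sorted(s for s in labels if s in m.betas.columns)
    if len(ids) < len(labels):
        missing = sorted(set(labels) - set(ids))
        raise ValueError(f"labelled samples absent from matrix: {missing[:5]}")
    y = np.array([float(labels[s]) for s in ids])
    X = m.betas[ids].T.dropna(axis=1)
    scr = LogisticScreenCV(
        l1_ratio=spec.alpha,
        n_folds=spec.n_folds,
        n_lambdas=spec.n_penalties,
        lambda_selection=spec.penalty_selection,
        random_state=spec.seed,
    ).fit(X, y)
    probes = {str(X.columns[i]) for i in scr.selected_features_}
    return DiagnosticScreen(
        label_name=label_name, diagnostic_probes=probes, alpha_used=spec.alpha
    )


@dataclass
class ConfoundingReport:
    """Per-screen overlap between a clock's CpGs and diagnostic CpGs."""

    entries: list[dict] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(e["passed"] for e in self.entries)


def check_clock_confounding(
    model: ClockModel, screens: Sequence[DiagnosticScreen]
) -> ConfoundingReport:
    """Intersect clock CpGs with each diagnostic set; empty = pass."""
    report = ConfoundingReport()
    clock_probes = set(model.coefficients)
    for scr in screens:
        shared = clock_probes & scr.diagnostic_probes
        report.entries.append(
            {
                "label_name": scr.label_name,
                "shared_probes": shared,
                "passed": not shared,
            }
        )
    return report
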