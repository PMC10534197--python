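"""Population age-structure analysis from clock predictions.

Nonparametric two-sample and paired comparisons of age distributions
(rank-sum and signed-rank with exact small-sample null distributions),
per-survey-period summaries with bootstrap confidence intervals, and
consistency checks for serially sampled individuals.

Statistic conventions match the ones commonly reported alongside these
tests: the rank-sum statistic W is the Mann–Whitney U for the first sample
(rank sum of x minus n_x(n_x+1)/2 on midranks) and the signed-rank statistic
V is the sum of ranks of positive differences, zero differences dropped.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import SampleMetadata, ValidationError

__all__ = [
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "AgeStructureReport",
    "age_structure",
    "serial_consistency",
]

_EXACT_PRODUCT_LIMIT = 400     # n_x * n_y bound for the tie-free exact null
_ENUM_COMB_LIMIT = 200_000     # assignments enumerated when ties force it
_EXACT_SIGNED_N = 20           # signed-rank exact bound (tie-free)


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _two_sided_from_enum(null: np.ndarray, observed: float) -> float:
    """Two-sided p as 2 * min(tail) over an enumerated null, capped at 1."""
    lo = np.mean(null <= observed + 1e-9)
    hi = np.mean(null >= observed - 1e-9)
    return float(min(1.0, 2.0 * min(lo, hi)))


def _rank_sum_enumerate(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Full enumeration of the rank-sum null over all group assignments."""
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    nx, n = len(x), len(pooled)
    if math.comb(n, nx) > _ENUM_COMB_LIMIT:
        raise ValueError(
            f"exact enumeration infeasible for C({n},{nx}) assignments; "
            "use mode='normal_approx'"
        )
    offset = nx * (nx + 1) / 2.0
    w_obs = ranks[:nx].sum() - offset
    null = np.array(
        [sum(ranks[list(c)]) - offset for c in itertools.combinations(range(n), nx)]
    )
    return w_obs, _two_sided_from_enum(null, w_obs)


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> dict:
    """Two-sample rank-sum test; returns {"W": ..., "p": ...}.

    ``mode``: ``"exact"`` (full null enumeration; the tie-free distribution
    when there are no ties), ``"normal_approx"`` (normal approximation with
    midrank tie correction and continuity correction), or ``"auto"`` (exact
    when tie-free and n_x * n_y <= 400, else the approximation — the usual
    convention of the R function these W values are reported from).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    small = x.size * y.size <= _EXACT_PRODUCT_LIMIT

    if mode not in ("auto", "exact", "normal_approx"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and small and not has_ties)

    if use_exact:
        if has_ties:
            return dict(zip(("W", "p"), _rank_sum_enumerate(x, y)))
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return {"W": float(res.statistic), "p": float(res.pvalue)}
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return {"W": float(res.statistic), "p": float(res.pvalue)}


def _signed_rank_enumerate(d: np.ndarray) -> tuple[float, float]:
    """Enumerate all 2^n sign patterns on the midranks of |d|."""
    n = d.size
    if n > _EXACT_SIGNED_N:
        raise ValueError("exact enumeration infeasible beyond n = 20 differences")
    ranks = _midranks(np.abs(d))
    v_obs = ranks[d > 0].sum()
    # null: each |d| signs +/- independently; V = sum of ranks with + sign
    signs = np.array(list(itertools.product([0, 1], repeat=n)), dtype=float)
    null = signs @ ranks
    return float(v_obs), _two_sided_from_enum(null, v_obs)


def wilcoxon_signed_rank(paired_x, paired_y, mode: str = "auto") -> dict:
    """Paired signed-rank test; returns {"V": ..., "p": ...}.

    Zero differences are dropped before ranking; all-zero differences give
    the degenerate result V = 0, p = 1.  ``mode`` as in
    :func:`wilcoxon_rank_sum`, with the exact null enumerated for up to 20
    nonzero differences.
    """
    x = np.asarray(paired_x, dtype=float)
    y = np.asarray(paired_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return {"V": 0.0, "p": 1.0}
    ranks = _midranks(np.abs(d))
    v_obs = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < d.size

    if mode not in ("auto", "exact", "normal_approx"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (
        mode == "auto" and d.size <= _EXACT_SIGNED_N and not has_ties
    )
    if use_exact:
        if has_ties:
            return dict(zip(("V", "p"), _signed_rank_enumerate(d)))
        res = stats.wilcoxon(d, zero_method="wilcox", method="exact",
                             alternative="two-sided")
        return {"V": v_obs, "p": float(res.pvalue)}
    res = stats.wilcoxon(
        d, zero_method="wilcox", method="approx", correction=True,
        alternative="two-sided",
    )
    return {"V": v_obs, "p": float(res.pvalue)}


@dataclass
class AgeStructureReport:
    """Per-period age summaries, pairwise comparisons and histograms.

    ``per_period`` maps period label to {ages, mean, median, ci95_mean};
    ``comparisons`` holds rank-sum results for every period pair;
    ``histograms`` maps period to a DataFrame of counts per age bin by sex.
    """

    per_period: dict = field(default_factory=dict)
    comparisons: list[dict] = field(default_factory=list)
    histogram_bins: float = 1.0
    histograms: dict = field(default_factory=dict)


def age_structure(
    predictions: Mapping[str, float],
    meta: Sequence[SampleMetadata],
    periods: Sequence[str],
    bin_width: float = 1.0,
    n_bootstrap: int = 10_000,
    seed: int = 0,
    one_per_individual: bool = True,
) -> AgeStructureReport:
    """Summarize predicted age structure by survey period.

    One age per individual per period enters the summaries (the sample with
    the latest collection date wins) unless ``one_per_individual=False``.
    95% CIs on the mean are seeded bootstrap percentile intervals; pairwise
    period comparisons use :func:`wilcoxon_rank_sum` in auto mode.
    """
    by_id = {r.sample_id: r for r in meta}
    known_periods = {r.survey_period for r in meta if r.survey_period}
    unknown = [p for p in periods if p not in known_periods]
    if unknown:
        raise ValidationError(f"unknown survey period label(s): {unknown}")

    rng = np.random.default_rng(seed)
    report = AgeStructureReport(histogram_bins=bin_width)
    period_entries: dict[str, list] = {p: [] for p in periods}
    for sid, age in predictions.items():
        r = by_id.get(sid)
        if r is None or not r.survey_period or r.survey_period not in period_entries:
            continue
        period_entries[r.survey_period].append(r)

    for period in periods:
        recs = period_entries[period]
        if one_per_individual:
            best: dict[str, SampleMetadata] = {}
            for r in recs:
                cur = best.get(r.individual_id)
                if cur is None or _date_key(r) >= _date_key(cur):
                    best[r.individual_id] = r
            recs = list(best.values())
        recs = sorted(recs, key=lambda r: r.sample_id)
        ages = np.array([predictions[r.sample_id] for r in recs])
        if ages.size == 0:
            raise ValidationError(f"no predicted samples in period {period!r}")
        boots = rng.choice(ages, size=(n_bootstrap, ages.size), replace=True).mean(axis=1)
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
        sexes = [r.sex for r in recs]
        report.per_period[period] = {
            "ages": ages.tolist(),
            "mean": float(ages.mean()),
            "median": float(np.median(ages)),
            "ci95_mean": ci,
            "n": int(ages.size),
        }
        report.histograms[period] = _sex_histogram(ages, sexes, bin_width)

    for pa, pb in itertools.combinations(periods, 2):
        res = wilcoxon_rank_sum(
            report.per_period[pa]["ages"], report.per_period[pb]["ages"], mode="auto"
        )
        report.comparisons.append(
            {"period_a": pa, "period_b": pb, "statistic_W": res["W"], "p_value": res["p"]}
        )
    return report


def _date_key(r: SampleMetadata):
    return (r.collection_date or pd.Timestamp.min.date(), r.sample_id)


def _sex_histogram(ages: np.ndarray, sexes: list[str], bin_width: float) -> pd.DataFrame:
    lo = math.floor(min(ages.min(), 0) / bin_width) * bin_width
    hi = math.floor(ages.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    rows = []
    sexes = np.array(sexes)
    for a, b in zip(edges[:-1], edges[1:]):
        in_bin = (ages >= a) & (ages < b)
        rows.append(
            {
                "bin_start": float(a),
                "bin_end": float(b),
                "F": int(np.sum(in_bin & (sexes == "F"))),
                "M": int(np.sum(in_bin & (sexes == "M"))),
                "unknown": int(np.sum(in_bin & (sexes == "unknown"))),
                "total": int(in_bin.sum()),
            }
        )
    return pd.DataFrame(rows)


def serial_consistency(
    predictions: Mapping[str, float], meta: Sequence[SampleMetadata]
) -> pd.DataFrame:
    """Check age predictions of individuals sampled repeatedly over time.

    For each individual with >= 2 dated, predicted samples, every
    consecutive pair contributes a row: the predicted age interval, the
    calendar interval in years, and whether the direction agrees (later
    sample predicted older).  Individuals lacking collection dates are
    skipped with a warning.
    """
    groups: dict[str, list[SampleMetadata]] = {}
    for r in meta:
        if r.sample_id in predictions:
            groups.setdefault(r.individual_id, []).append(r)
    rows = []
    for ind, recs in sorted(groups.items()):
        if len(recs) < 2:
            continue
        undated = [r for r in recs if r.collection_date is None]
        if undated:
            warnings.warn(
                f"individual {ind}: {len(undated)} sample(s) lack collection "
                "dates; individual skipped"
            )
            continue
        recs = sorted(recs, key=lambda r: (r.collection_date, r.sample_id))
        for a, b in zip(recs[:-1], recs[1:]):
            actual = (b.collection_date - a.collection_date).days / 365.25
            pred_iv = predictions[b.sample_id] - predictions[a.sample_id]
            rows.append(
                {
                    "individual_id": ind,
                    "sample_a": a.sample_id,
                    "sample_b": b.sample_id,
                    "predicted_interval": float(pred_iv),
                    "actual_interval": float(actual),
                    "direction_correct": bool(np.sign(pred_iv) == np.sign(actual)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "individual_id",
            "sample_a",
            "sample_b",
            "predicted_interval",
            "actual_interval",
            "direction_correct",
        ],
    )
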