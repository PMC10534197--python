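"""Sample QC and probe screening ahead of clock training.

Three stages: flagging technical outlier arrays by inter-array correlation,
detection-p filtering of unreliably measured CpG probes, and per-probe
Pearson screening of methylation against age with Table-style binned
summaries of |r|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .data import (
    BetaMatrix,
    FilterResult,
    InsufficientDataError,
    SampleMetadata,
    ValidationError,
)

__all__ = [
    "OutlierReport",
    "detect_outlier_samples",
    "filter_probes_by_detection",
    "probe_age_correlations",
    "bin_correlations",
]


@dataclass
class OutlierReport:
    """Technical-outlier flagging result.

    ``mean_interarray_r`` maps each sample to its mean Pearson correlation
    with every other sample's beta vector; samples falling more than
    ``z_cut`` SD below the across-sample mean are flagged.  The average-link
    hierarchy on distance 1 - r is kept for manual review.
    """

    flagged_samples: set[str]
    mean_interarray_r: dict[str, float]
    method_params: dict = field(default_factory=dict)
    linkage_matrix: np.ndarray | None = None


def detect_outlier_samples(m: BetaMatrix, z_cut: float = 2.0) -> OutlierReport:
    """Flag samples whose mean inter-array correlation is anomalously low.

    Pairwise Pearson correlations are computed between sample beta vectors on
    complete-case probes.  A reproducible z-score rule replaces a visual
    dendrogram call: flag samples with mean r below (mean - z_cut * SD).
    """
    if m.n_samples < 3:
        raise InsufficientDataError("outlier detection needs at least 3 samples")
    B = m.values()
    complete = ~np.isnan(B).any(axis=1)
    if complete.sum() < 2:
        raise InsufficientDataError("fewer than 2 complete-case probes")
    V = B[complete]  # probes x samples
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(V.T)
    C = np.nan_to_num(C, nan=1.0)  # zero-variance samples: treat as perfectly flat
    n = m.n_samples
    off = C.copy()
    np.fill_diagonal(off, np.nan)
    mean_r = np.nanmean(off, axis=1)
    mu, sd = mean_r.mean(), mean_r.std()
    if sd > 0:
        flagged = {s for s, r in zip(m.sample_ids, mean_r) if r < mu - z_cut * sd}
    else:
        flagged = set()
    D = np.clip(1.0 - C, 0.0, None)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    return OutlierReport(
        flagged_samples=flagged,
        mean_interarray_r=dict(zip(m.sample_ids, mean_r.tolist())),
        method_params={
            "linkage": "average",
            "cut_rule": f"mean_r < mean - {z_cut} * sd",
            "n_complete_probes": int(complete.sum()),
        },
        linkage_matrix=Z,
    )


def filter_probes_by_detection(
    m: BetaMatrix,
    threshold_individuals: int,
    significance_level: float = 0.05,
) -> FilterResult:
    """Retain probes detected (p < significance_level) in enough samples.

    The comparison is strict (<).  Missing detection p-values count as failed
    detections.
    """
    if m.detection_p is None:
        raise ValidationError("matrix has no detection p-value layer")
    if not (1 <= threshold_individuals <= m.n_samples):
        raise ValueError(
            f"threshold_individuals must be in [1, {m.n_samples}], "
            f"got {threshold_individuals}"
        )
    P = m.detection_p.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        counts = np.sum(P < significance_level, axis=1)
    sig = dict(zip(m.probe_ids, (int(c) for c in counts)))
    retained = {p for p, c in sig.items() if c >= threshold_individuals}
    return FilterResult(
        retained_probes=retained,
        significant_counts=sig,
        threshold_individuals=threshold_individuals,
        significance_level=significance_level,
    )


def probe_age_correlations(
    m: BetaMatrix, meta: Sequence[SampleMetadata]
) -> pd.DataFrame:
    """Per-probe Pearson correlation of methylation with age.

    Uses pairwise-complete observations per probe; probes with fewer than 3
    observations or zero variance are excluded (r undefined, not 0).  Returns
    a DataFrame indexed by probe id with columns ``r``, ``p_value``, ``n``;
    p-values are two-sided from the t distribution on n - 2 df.
    """
    by_id = {r.sample_id: r for r in meta}
    aged = [s for s in m.sample_ids if by_id.get(s) and by_id[s].age_years is not None]
    if len(aged) < 3:
        raise InsufficientDataError("need at least 3 samples with known age")
    sub = m.betas[aged]
    age = np.array([by_id[s].age_years for s in aged], dtype=float)
    B = sub.to_numpy(dtype=float)  # probes x samples
    mask = ~np.isnan(B)
    n_obs = mask.sum(axis=1)

    Bz = np.where(mask, B, 0.0)
    A = np.where(mask, age[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_b = Bz.sum(axis=1) / n_obs
        mean_a = A.sum(axis=1) / n_obs
        cov = (Bz * A).sum(axis=1) / n_obs - mean_b * mean_a
        var_b = (Bz**2).sum(axis=1) / n_obs - mean_b**2
        var_a = (A**2).sum(axis=1) / n_obs - mean_a**2
        r = cov / np.sqrt(var_b * var_a)
    ok = (n_obs >= 3) & (var_b > 0) & (var_a > 0) & np.isfinite(r)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n_obs - 2) / np.maximum(1.0 - r**2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(n_obs - 2, 1))
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    out = pd.DataFrame(
        {"r": r[ok], "p_value": p[ok], "n": n_obs[ok].astype(int)},
        index=pd.Index(np.array(m.probe_ids)[ok], name="probe_id"),
    )
    return out


_BIN_EDGES = np.round(np.arange(0.0, 1.01, 0.1), 10)


def bin_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Summarize a correlation table into |r| bins of width 0.1.

    Bins are half-open [a, b) with the final bin closed at 1.0; a boundary
    value belongs to the upper bin.  Columns: ``bin``, ``n_cpgs``,
    ``pct_positive`` (percent of probes in the bin with r > 0, NaN for empty
    bins), plus a ``total`` row.  Bin counts always sum to the number of
    probes with a defined correlation.
    """
    r = table["r"].to_numpy(dtype=float)
    idx = np.minimum(np.floor(np.abs(r) * 10 + 1e-12).astype(int), 9)
    rows = []
    for b in range(10):
        in_bin = idx == b
        cnt = int(in_bin.sum())
        pct = 100.0 * np.mean(r[in_bin] > 0) if cnt else np.nan
        rows.append(
            {
                "bin": f"{_BIN_EDGES[b]:.1f}-{_BIN_EDGES[b + 1]:.1f}",
                "n_cpgs": cnt,
                "pct_positive": pct,
            }
        )
    total_pct = 100.0 * np.mean(r > 0) if r.size else np.nan
    rows.append({"bin": "total", "n_cpgs": int(r.size), "pct_positive": total_pct})
    return pd.DataFrame(rows, columns=["bin", "n_cpgs", "pct_positive"])
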