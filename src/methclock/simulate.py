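"""Synthetic methylation fixtures with the structure the pipeline assumes.

Emulates normalized array beta values: a small set of informative CpGs whose
methylation follows a logistic (inverse-logit) trend in age — positive for a
configurable share of sites, negative for the rest — plus age-independent
background probes, per-measurement detection-p failures, and an optional
binary batch shift mimicking a species or tissue confounder.  A truth record
(informative probes, slopes, batch probes) accompanies every draw so
recovery can be tested.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import BetaMatrix, SampleMetadata

__all__ = ["SyntheticConfig", "generate", "generate_serial"]


@dataclass
class SyntheticConfig:
    """Generative parameters for synthetic beta matrices.

    ``slope_scale`` is the typical age trend of an informative CpG in logit
    units per year (drawn per probe in [0.75, 1.25] x slope_scale, signed);
    ``noise_sd`` is measurement noise on the beta scale; a
    ``detection_fail_rate`` share of measurements receive detection p >= .05.
    ``batch_effect``, when set, is a dict with keys ``label_name`` ("species"
    or "tissue"), ``n_batch_probes`` and ``shift`` (beta-scale offset applied
    to label-1 samples at the batch probes).
    """

    n_samples: int = 60
    n_probes: int = 2000
    n_informative: int = 8
    age_range: tuple[float, float] = (0.25, 20.0)
    slope_scale: float = 0.1
    noise_sd: float = 0.02
    frac_positive: float = 0.5
    detection_fail_rate: float = 0.05
    batch_effect: dict | None = None
    n_species: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.n_informative <= self.n_probes):
            raise ValueError("need 0 < n_informative <= n_probes")
        for name in ("frac_positive", "detection_fail_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0 or self.slope_scale < 0:
            raise ValueError("noise_sd and slope_scale must be non-negative")
        lo, hi = self.age_range
        if not (0 <= lo < hi):
            raise ValueError(f"invalid age_range {self.age_range}")
        if self.batch_effect is not None:
            required = {"label_name", "n_batch_probes", "shift"}
            if not required <= set(self.batch_effect):
                raise ValueError(f"batch_effect needs keys {sorted(required)}")


@dataclass
class _ProbeParams:
    probe_ids: list[str]
    informative_idx: np.ndarray
    slopes: np.ndarray          # logit/year, informative probes only
    intercepts: np.ndarray      # logit units, informative probes only
    baselines: np.ndarray       # beta units, background probes
    batch_idx: np.ndarray


def _draw_probe_params(cfg: SyntheticConfig, rng: np.random.Generator) -> _ProbeParams:
    probe_ids = [f"cg{i:08d}" for i in range(cfg.n_probes)]
    informative = np.sort(rng.choice(cfg.n_probes, cfg.n_informative, replace=False))
    n_pos = int(round(cfg.frac_positive * cfg.n_informative))
    signs = np.array([1.0] * n_pos + [-1.0] * (cfg.n_informative - n_pos))
    rng.shuffle(signs)
    mags = cfg.slope_scale * rng.uniform(0.75, 1.25, cfg.n_informative)
    slopes = signs * mags
    mid_age = 0.5 * (cfg.age_range[0] + cfg.age_range[1])
    intercepts = -slopes * mid_age + rng.normal(0.0, 0.5, cfg.n_informative)
    baselines = rng.uniform(0.05, 0.95, cfg.n_probes)
    batch_idx = np.array([], dtype=int)
    if cfg.batch_effect is not None:
        pool = np.setdiff1d(np.arange(cfg.n_probes), informative)
        batch_idx = np.sort(
            rng.choice(pool, int(cfg.batch_effect["n_batch_probes"]), replace=False)
        )
        # keep headroom so the shift is not flattened by [0, 1] clipping
        shift = float(cfg.batch_effect["shift"])
        lo = 0.05 + max(0.0, -shift)
        hi = 0.95 - max(0.0, shift)
        baselines[batch_idx] = rng.uniform(lo, max(hi, lo + 0.05), batch_idx.size)
    return _ProbeParams(probe_ids, informative, slopes, intercepts, baselines, batch_idx)


def _betas_for_ages(
    ages: np.ndarray,
    params: _ProbeParams,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    batch_labels: np.ndarray | None,
) -> np.ndarray:
    n = ages.size
    B = np.empty((cfg.n_probes, n))
    B[:] = params.baselines[:, None]
    inf = params.informative_idx
    B[inf, :] = expit(params.intercepts[:, None] + params.slopes[:, None] * ages[None, :])
    if cfg.batch_effect is not None and batch_labels is not None and params.batch_idx.size:
        shift = float(cfg.batch_effect["shift"])
        B[np.ix_(params.batch_idx, np.flatnonzero(batch_labels == 1))] += shift
    if cfg.noise_sd > 0:
        B += rng.normal(0.0, cfg.noise_sd, B.shape)
    return np.clip(B, 0.0, 1.0)


def _detection_p(shape: tuple[int, int], rate: float, rng: np.random.Generator) -> np.ndarray:
    fail = rng.random(shape) < rate
    return np.where(fail, rng.uniform(0.05, 1.0, shape), rng.uniform(0.0, 0.05, shape))


def _truth(params: _ProbeParams) -> dict:
    ids = params.probe_ids
    return {
        "informative_probes": [ids[i] for i in params.informative_idx],
        "slopes": {
            ids[i]: float(s) for i, s in zip(params.informative_idx, params.slopes)
        },
        "batch_probes": [ids[i] for i in params.batch_idx],
    }


def generate(
    config: SyntheticConfig,
) -> tuple[BetaMatrix, list[SampleMetadata], dict]:
    """Draw a cross-sectional synthetic cohort.

    Ages are uniform over ``age_range``; every sample is an independent
    individual with a high-confidence (strict-tier) age label.  Returns the
    beta matrix (with detection p-values), metadata and the truth record.
    """
    rng = np.random.default_rng(config.seed)
    params = _draw_probe_params(config, rng)
    ages = rng.uniform(*config.age_range, config.n_samples)

    batch_labels = None
    group = ["groupA"] * config.n_samples
    tissue = ["beachcast"] * config.n_samples
    if config.batch_effect is not None or config.n_species > 1:
        batch_labels = (rng.random(config.n_samples) < 0.5).astype(int)
        name = (config.batch_effect or {}).get("label_name", "species")
        if name == "species" or config.n_species > 1:
            group = ["groupB" if b else "groupA" for b in batch_labels]
        if name == "tissue":
            tissue = ["biopsy" if b else "beachcast" for b in batch_labels]

    B = _betas_for_ages(ages, params, config, rng, batch_labels)
    P = _detection_p(B.shape, config.detection_fail_rate, rng)
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    betas = pd.DataFrame(B, index=params.probe_ids, columns=sample_ids)
    pvals = pd.DataFrame(P, index=params.probe_ids, columns=sample_ids)

    sexes = np.where(rng.random(config.n_samples) < 0.5, "F", "M")
    meta = [
        SampleMetadata(
            sample_id=s,
            individual_id=f"I{i:04d}",
            age_years=float(ages[i]),
            confidence_tier="strict",
            sex=str(sexes[i]),
            group_label=group[i],
            tissue_source=tissue[i],
        )
        for i, s in enumerate(sample_ids)
    ]
    truth = _truth(params)
    if batch_labels is not None:
        truth["batch_labels"] = {s: int(b) for s, b in zip(sample_ids, batch_labels)}
    return BetaMatrix(betas, pvals), meta, truth


def generate_serial(
    config: SyntheticConfig,
    n_individuals: int,
    samples_per_individual: int = 2,
    gap_years: float = 5.0,
) -> tuple[BetaMatrix, list[SampleMetadata], dict]:
    """Draw repeated samples from the same individuals spaced ``gap_years``.

    Each individual is first sampled at a uniform age, then again after each
    gap; collection dates are spaced consistently with the gaps so the serial
    consistency check can recover the true intervals.
    """
    if samples_per_individual < 2:
        raise ValueError("samples_per_individual must be >= 2")
    rng = np.random.default_rng(config.seed)
    params = _draw_probe_params(config, rng)
    lo, hi = config.age_range
    span = gap_years * (samples_per_individual - 1)
    base_ages = rng.uniform(lo, max(hi - span, lo + 0.1), n_individuals)
    base_days = rng.integers(0, 3650, n_individuals)

    ages, sample_ids, meta = [], [], []
    epoch = _dt.date(2005, 1, 1)
    for i in range(n_individuals):
        for t in range(samples_per_individual):
            age = base_ages[i] + t * gap_years
            sid = f"S{i:04d}T{t}"
            date = epoch + _dt.timedelta(
                days=int(base_days[i]) + int(round(t * gap_years * 365.25))
            )
            ages.append(age)
            sample_ids.append(sid)
            meta.append(
                SampleMetadata(
                    sample_id=sid,
                    individual_id=f"I{i:04d}",
                    age_years=float(age),
                    confidence_tier="strict",
                    sex="F" if rng.random() < 0.5 else "M",
                    group_label="groupA",
                    tissue_source="biopsy",
                    collection_date=date,
                )
            )
    ages = np.asarray(ages)
    B = _betas_for_ages(ages, params, config, rng, None)
    P = _detection_p(B.shape, config.detection_fail_rate, rng)
    betas = pd.DataFrame(B, index=params.probe_ids, columns=sample_ids)
    pvals = pd.DataFrame(P, index=params.probe_ids, columns=sample_ids)
    return BetaMatrix(betas, pvals), meta, _truth(params)
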