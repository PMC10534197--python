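"""Core containers and text I/O for methylation clock data.

The central objects are :class:`BetaMatrix` (probes x samples methylation
fractions with optional per-measurement detection p-values),
:class:`SampleMetadata` (per-sample annotations: age, confidence tier, sex,
group, tissue, survey period) and :class:`ClockModel` (a sparse linear model
mapping beta values to age in years).

All file formats are plain delimited text: TSV by default, CSV when the file
extension is ``.csv``.  Clock models serialize to a diff-able text format that
round-trips every coefficient bit-exactly (``repr`` of a float64).
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "InsufficientDataError",
    "MergeError",
    "BetaMatrix",
    "SampleMetadata",
    "ClockModel",
    "FilterResult",
    "Metrics",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_metadata",
    "write_metadata",
    "metadata_to_frame",
    "load_published_clock",
    "canonical_probe_id",
]


class FormatError(ValueError):
    """Malformed input file (duplicate identifiers, unknown tokens...)."""


class ValidationError(ValueError):
    """Input violates a data invariant (out-of-range beta, strict tier
    without an age...)."""


class InsufficientDataError(ValueError):
    """Too few samples/observations for the requested computation."""


class MergeError(ValueError):
    """Training sets cannot be merged (disjoint probes, duplicate ids)."""


_CG_RE = re.compile(r"^cg\d+$", re.IGNORECASE)


def canonical_probe_id(probe_id: str) -> str:
    """Canonicalize an array probe identifier.

    Identifiers of the ``cg<digits>`` form are matched case-insensitively
    (published tables mix ``Cg...`` and ``cg...``) and lowercased; anything
    else is returned unchanged.
    """
    pid = str(probe_id).strip()
    if _CG_RE.match(pid):
        return pid.lower()
    return pid


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


class BetaMatrix:
    """Probes x samples matrix of methylation fractions in [0, 1].

    Parameters
    ----------
    betas
        DataFrame indexed by probe id with sample ids as columns.  Missing
        measurements are NaN; all finite values must lie in [0, 1].
    detection_p
        Optional matrix of per-measurement detection p-values, aligned
        element-wise with ``betas`` (same index and columns).
    """

    def __init__(self, betas: pd.DataFrame, detection_p: pd.DataFrame | None = None):
        betas = betas.copy()
        betas.index = [canonical_probe_id(p) for p in betas.index]
        betas.columns = [str(c) for c in betas.columns]
        if betas.index.has_duplicates:
            dups = betas.index[betas.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe identifiers: {dups[:5]}")
        if pd.Index(betas.columns).has_duplicates:
            raise FormatError("duplicate sample identifiers")
        vals = betas.to_numpy(dtype=float)
        bad = np.where(np.isfinite(vals) & ((vals < 0) | (vals > 1)))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"beta value {vals[i, j]} outside [0, 1] at probe "
                f"{betas.index[i]!r}, sample {betas.columns[j]!r}"
            )
        inf = np.where(np.isinf(vals))
        if inf[0].size:
            raise ValidationError("non-finite beta value (inf) in matrix")
        self.betas = betas.astype(float)
        if detection_p is not None:
            detection_p = detection_p.copy()
            detection_p.index = [canonical_probe_id(p) for p in detection_p.index]
            detection_p.columns = [str(c) for c in detection_p.columns]
            if set(detection_p.index) != set(self.betas.index) or set(
                detection_p.columns
            ) != set(self.betas.columns):
                raise ValidationError("detection_p matrix is not aligned with betas")
            # allow same content in different order
            detection_p = detection_p.loc[self.betas.index, self.betas.columns]
            pv = detection_p.to_numpy(dtype=float)
            if np.any(np.isfinite(pv) & ((pv < 0) | (pv > 1))):
                raise ValidationError("detection p-value outside [0, 1]")
            detection_p = detection_p.astype(float)
        self.detection_p = detection_p

    # -- basic accessors -------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.betas.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.betas.columns)

    @property
    def n_probes(self) -> int:
        return self.betas.shape[0]

    @property
    def n_samples(self) -> int:
        return self.betas.shape[1]

    def values(self) -> np.ndarray:
        """Betas as a float ndarray (probes x samples)."""
        return self.betas.to_numpy(dtype=float)

    def select_samples(self, sample_ids: Iterable[str]) -> "BetaMatrix":
        ids = [str(s) for s in sample_ids]
        missing = [s for s in ids if s not in self.betas.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        dp = self.detection_p[ids] if self.detection_p is not None else None
        return BetaMatrix(self.betas[ids], dp)

    def select_probes(self, probe_ids: Iterable[str]) -> "BetaMatrix":
        ids = [canonical_probe_id(p) for p in probe_ids]
        missing = [p for p in ids if p not in self.betas.index]
        if missing:
            raise KeyError(f"unknown probe ids: {missing[:5]}")
        dp = self.detection_p.loc[ids] if self.detection_p is not None else None
        return BetaMatrix(self.betas.loc[ids], dp)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        dp = "with" if self.detection_p is not None else "without"
        return (
            f"BetaMatrix({self.n_probes} probes x {self.n_samples} samples, "
            f"{dp} detection p-values)"
        )


def read_beta_matrix(
    path: str | Path,
    dialect: str = "probes_in_rows",
    detection_path: str | Path | None = None,
) -> BetaMatrix:
    """Read a delimited beta-value matrix (and optional detection p-values).

    ``dialect`` declares the file orientation; the returned matrix is always
    probes x samples.  Empty cells are missing measurements.
    """
    if dialect not in ("probes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown dialect {dialect!r}")
    betas = _read_numeric_table(path, dialect)
    dp = None
    if detection_path is not None:
        dp = _read_numeric_table(detection_path, dialect)
    return BetaMatrix(betas, dp)


def _read_numeric_table(path: str | Path, dialect: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
    if dialect == "samples_in_rows":
        df = df.T
    return df


def _write_full_precision(df: pd.DataFrame, path: str | Path) -> None:
    # repr() round-trips float64 exactly; NaN cells become empty
    df.to_csv(
        path,
        sep=_sep_for(path),
        index_label="probe_id",
        float_format=lambda v: repr(float(v)),
        na_rep="",
    )


def write_beta_matrix(m: BetaMatrix, path: str | Path, detection_path: str | Path | None = None) -> None:
    """Write a BetaMatrix (probes in rows) with full float precision."""
    _write_full_precision(m.betas, path)
    if detection_path is not None:
        if m.detection_p is None:
            raise ValueError("matrix has no detection p-values to write")
        _write_full_precision(m.detection_p, detection_path)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

_TIERS = {"strict", "relaxed_only", "unknown"}
_SEXES = {"f": "F", "m": "M", "female": "F", "male": "M", "unknown": "unknown", "": "unknown"}
_TISSUES = {"beachcast", "biopsy", "unknown"}


@dataclass
class SampleMetadata:
    """Annotations for one array sample.

    ``confidence_tier`` encodes age-label quality: ``strict`` samples have
    high-confidence (e.g. tooth-layer) ages, ``relaxed_only`` samples carry at
    least a minimum age estimate, ``unknown`` samples have no training age.
    The relaxed training set is the union of strict and relaxed_only samples.
    """

    sample_id: str
    individual_id: str = ""
    age_years: float | None = None
    confidence_tier: str = "unknown"
    sex: str = "unknown"
    group_label: str = ""
    tissue_source: str = "unknown"
    survey_period: str | None = None
    collection_date: _dt.date | None = None

    def __post_init__(self):
        self.sample_id = str(self.sample_id)
        if not self.individual_id:
            self.individual_id = self.sample_id
        tier = str(self.confidence_tier).strip().lower() or "unknown"
        if tier not in _TIERS:
            raise FormatError(f"unknown confidence tier {self.confidence_tier!r}")
        self.confidence_tier = tier
        sex = str(self.sex).strip().lower()
        if sex not in _SEXES:
            raise FormatError(f"unknown sex token {self.sex!r}")
        self.sex = _SEXES[sex]
        tissue = str(self.tissue_source).strip().lower() or "unknown"
        if tissue not in _TISSUES:
            raise FormatError(f"unknown tissue source {self.tissue_source!r}")
        self.tissue_source = tissue
        if self.age_years is not None:
            self.age_years = float(self.age_years)
            if not np.isfinite(self.age_years) or self.age_years < 0:
                raise ValidationError(
                    f"sample {self.sample_id}: age must be a non-negative number"
                )
        if self.confidence_tier == "strict" and self.age_years is None:
            raise ValidationError(
                f"sample {self.sample_id}: strict confidence tier requires an age"
            )
        if isinstance(self.collection_date, str):
            self.collection_date = _dt.date.fromisoformat(self.collection_date)

    @property
    def in_strict(self) -> bool:
        return self.confidence_tier == "strict"

    @property
    def in_relaxed(self) -> bool:
        return self.confidence_tier in ("strict", "relaxed_only")


_META_COLUMNS = [
    "sample_id",
    "individual_id",
    "age_years",
    "confidence_tier",
    "sex",
    "group_label",
    "tissue_source",
    "survey_period",
    "collection_date",
]


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read a sample metadata table; unknowns are encoded as empty cells."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    if "sample_id" not in df.columns:
        raise FormatError("metadata table must have a sample_id column")
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                individual_id=row.get("individual_id", "") or row["sample_id"],
                age_years=float(row["age_years"]) if row.get("age_years", "") != "" else None,
                confidence_tier=row.get("confidence_tier", "") or "unknown",
                sex=row.get("sex", "") or "unknown",
                group_label=row.get("group_label", ""),
                tissue_source=row.get("tissue_source", "") or "unknown",
                survey_period=row.get("survey_period", "") or None,
                collection_date=row.get("collection_date", "") or None,
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sample_id in metadata")
    return records


def metadata_to_frame(meta: Iterable[SampleMetadata]) -> pd.DataFrame:
    rows = []
    for r in meta:
        rows.append(
            {
                "sample_id": r.sample_id,
                "individual_id": r.individual_id,
                "age_years": r.age_years,
                "confidence_tier": r.confidence_tier,
                "sex": r.sex,
                "group_label": r.group_label,
                "tissue_source": r.tissue_source,
                "survey_period": r.survey_period or "",
                "collection_date": r.collection_date.isoformat() if r.collection_date else "",
            }
        )
    return pd.DataFrame(rows, columns=_META_COLUMNS)


def write_metadata(meta: Iterable[SampleMetadata], path: str | Path) -> None:
    metadata_to_frame(meta).to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Clock models
# ---------------------------------------------------------------------------


@dataclass
class ClockModel:
    """A sparse linear epigenetic clock: age = intercept + sum(coef_j * beta_j).

    ``coefficients`` holds only nonzero terms, keyed by canonical probe id,
    in years per unit beta.  ``training_meta`` records provenance (mixing
    parameter alpha, selected penalty lambda, CpG filter threshold, training
    set label, n, seed).
    """

    intercept: float
    coefficients: dict[str, float]
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intercept = float(self.intercept)
        canon: dict[str, float] = {}
        for pid, c in self.coefficients.items():
            cid = canonical_probe_id(pid)
            if cid in canon:
                raise ValidationError(f"duplicate probe in clock: {cid}")
            c = float(c)
            if c == 0.0:
                raise ValidationError(f"zero coefficient stored for probe {cid}")
            canon[cid] = c
        self.coefficients = canon

    @property
    def probe_ids(self) -> list[str]:
        return list(self.coefficients)

    @property
    def n_terms(self) -> int:
        """Number of CpG terms (excluding the intercept)."""
        return len(self.coefficients)

    # -- text serialization (bit-exact round trip) -----------------------
    def to_file(self, path: str | Path) -> None:
        lines = ["#methclock-model\tv1"]
        for k in sorted(self.training_meta):
            lines.append(f"meta\t{k}\t{self.training_meta[k]}")
        lines.append(f"intercept\t{self.intercept!r}")
        for pid, c in self.coefficients.items():
            lines.append(f"coef\t{pid}\t{c!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ClockModel":
        return cls.from_text(Path(path).read_text())

    @classmethod
    def from_text(cls, text: str) -> "ClockModel":
        intercept = None
        coefs: dict[str, float] = {}
        meta: dict = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "meta" and len(parts) == 3:
                meta[parts[1]] = _parse_meta_value(parts[2])
            elif parts[0] == "intercept" and len(parts) == 2:
                intercept = float(parts[1])
            elif parts[0] == "coef" and len(parts) == 3:
                coefs[parts[1]] = float(parts[2])
            else:
                raise FormatError(f"unrecognized clock-file line: {line!r}")
        if intercept is None:
            raise FormatError("clock file has no intercept line")
        return cls(intercept=intercept, coefficients=coefs, training_meta=meta)


def _parse_meta_value(tok: str):
    for cast in (int, float):
        try:
            return cast(tok)
        except ValueError:
            continue
    return tok


@dataclass
class FilterResult:
    """Outcome of detection-p probe filtering.

    ``retained_probes`` are the probes whose detection p-value was below the
    significance level in at least ``threshold_individuals`` samples.
    """

    retained_probes: set[str]
    significant_counts: dict[str, int]
    threshold_individuals: int
    significance_level: float = 0.05


@dataclass
class Metrics:
    """Clock accuracy summary: mean/median absolute error (years), Pearson r,
    and the simple regression of predicted on true age."""

    mae: float
    medae: float
    pearson_r: float
    r_squared: float
    reg_slope: float
    reg_intercept: float
    reg_p: float

    def as_dict(self) -> dict:
        return {
            "mae": self.mae,
            "medae": self.medae,
            "pearson_r": self.pearson_r,
            "r_squared": self.r_squared,
            "reg_slope": self.reg_slope,
            "reg_intercept": self.reg_intercept,
            "reg_p": self.reg_p,
        }


_PUBLISHED = {"maui_hectors_8cpg": "maui_hectors_8cpg.clock"}


def load_published_clock(name: str = "maui_hectors_8cpg") -> ClockModel:
    """Load a packaged published clock by name.

    ``maui_hectors_8cpg`` is the eight-CpG Maui/Hector's dolphin skin clock
    (intercept and coefficients as published, applicable directly to
    normalized beta values).
    """
    if name not in _PUBLISHED:
        raise KeyError(
            f"unknown published clock {name!r}; available: {sorted(_PUBLISHED)}"
        )
    text = resources.files("methclock.clocks").joinpath(_PUBLISHED[name]).read_text()
    return ClockModel.from_text(text)
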