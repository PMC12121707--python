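"""Shared domain types, tabular I/O, and validation for the pipeline.

All tables are UTF-8 CSV/TSV with a mandatory header row. Missing numeric
cells are encoded as empty strings on disk and as NaN in memory — they are
never silently coerced to zero, because downstream steps interpolate
missingness explicitly. Condition labels are opaque categories, so the same
machinery serves opener/nonopener and opener/nonopener/baseline designs.

Latency units follow the assays that produce them: minutes for the helping
behavior test (capped at 40), seconds for the boldness test (capped at 300)
and social-interaction scoring. No hidden unit conversion is performed.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

HBT_MAX_LATENCY_MIN = 40.0
BOLDNESS_MAX_LATENCY_S = 300.0
DENSITY_REFERENCE_AREA_UM2 = 250.0


class SchemaError(ValueError):
    """A required column is missing or a table is structurally malformed."""


class ValidationError(ValueError):
    """A value violates a domain invariant (negative count, zero area, ...)."""


class DegenerateInputError(ValueError):
    """Input is technically well-formed but statistically degenerate."""


def cfos_density(count: float, sampled_area: float) -> float:
    """c-Fos density as positive cells per 250 um^2 of sampled area."""
    if sampled_area <= 0:
        raise ValidationError(f"sampled_area must be positive, got {sampled_area}")
    return count * DENSITY_REFERENCE_AREA_UM2 / sampled_area


# ---------------------------------------------------------------------------
# Record types


@dataclass(frozen=True)
class RegionActivityRecord:
    """One subject x region c-Fos count with the area it was sampled over."""

    subject_id: str
    region_id: str
    cfos_count: int
    sampled_area: float
    n_slices: Optional[int] = None

    def __post_init__(self) -> None:
        if self.cfos_count < 0:
            raise ValidationError(
                f"cfos_count must be >= 0, got {self.cfos_count} "
                f"({self.subject_id}, {self.region_id})"
            )
        if self.sampled_area <= 0:
            raise ValidationError(
                f"sampled_area must be > 0, got {self.sampled_area} "
                f"({self.subject_id}, {self.region_id})"
            )
        if self.n_slices is not None and self.n_slices <= 0:
            raise ValidationError(f"n_slices must be positive, got {self.n_slices}")

    @property
    def density(self) -> float:
        return cfos_density(self.cfos_count, self.sampled_area)


@dataclass(frozen=True)
class SessionRecord:
    """One helping-behavior-test day for one pair.

    ``latency`` (minutes) is present iff the free rat opened the door;
    openings by the trapped rat after the halfway point are logged with
    ``opened_by_free=False`` and never count toward opener status.
    """

    pair_id: str
    day: int
    opened_by_free: bool
    latency: Optional[float] = None
    blocker_used: bool = False

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValidationError(f"day must be >= 1, got {self.day}")
        if self.opened_by_free:
            if self.latency is None:
                raise ValidationError(
                    f"latency required when opened_by_free ({self.pair_id} day {self.day})"
                )
            if not 0 <= self.latency <= HBT_MAX_LATENCY_MIN:
                raise ValidationError(
                    f"latency must be in [0, {HBT_MAX_LATENCY_MIN}] min, "
                    f"got {self.latency} ({self.pair_id} day {self.day})"
                )
        elif self.latency is not None:
            raise ValidationError(
                f"latency must be absent when the free rat did not open "
                f"({self.pair_id} day {self.day})"
            )


@dataclass(frozen=True)
class BoldnessRecord:
    """One cage-top peek trial; latency is censored at 300 s if no peek."""

    pair_id: str
    rat_id: str
    day: int
    peek_latency: float
    peeked: bool

    def __post_init__(self) -> None:
        if not 1 <= self.day <= 5:
            raise ValidationError(f"boldness day must be in 1..5, got {self.day}")
        if not 0 <= self.peek_latency <= BOLDNESS_MAX_LATENCY_S:
            raise ValidationError(
                f"peek_latency must be in [0, {BOLDNESS_MAX_LATENCY_S}] s, "
                f"got {self.peek_latency}"
            )
        if not self.peeked and self.peek_latency != BOLDNESS_MAX_LATENCY_S:
            raise ValidationError(
                f"latency must equal {BOLDNESS_MAX_LATENCY_S} when the rat never "
                f"peeked ({self.rat_id} day {self.day})"
            )


@dataclass(frozen=True)
class SocialInteractionSummary:
    """Frequency/duration of affiliative behaviors in a scoring window."""

    pair_id: str
    session: str  # pre_HBT | first_HBT | post_HBT
    si_count: int
    si_duration: float
    window: float = 300.0

    def __post_init__(self) -> None:
        if self.si_count < 0 or self.si_duration < 0:
            raise ValidationError("si_count and si_duration must be non-negative")
        if self.si_count == 0 and self.si_duration != 0:
            raise ValidationError("si_duration must be 0 when si_count is 0")
        if self.window <= 0:
            raise ValidationError("window must be positive")


@dataclass(frozen=True)
class CtRecord:
    """Raw qPCR cycle thresholds for one sample (target and reference gene)."""

    sample_id: str
    group: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ct_target) and np.isfinite(self.ct_reference)):
            raise ValidationError(f"non-finite Ct for sample {self.sample_id}")


@dataclass(frozen=True)
class RoleAssignment:
    """Free/trapped role call for one pair from the 5-day boldness test."""

    pair_id: str
    free_rat: str
    trapped_rat: str
    days_first: Mapping[str, int]
    mean_latency: Mapping[str, float]
    delta_latency: float


@dataclass(frozen=True)
class OpenerCall:
    """Opener/nonopener classification for one pair's free rat."""

    pair_id: str
    is_opener: bool
    total_openings: int
    openings_last3: int
    mean_latency: float

    def __post_init__(self) -> None:
        if not 0 <= self.openings_last3 <= 3:
            raise ValidationError("openings_last3 must be in 0..3")
        if not 0 <= self.mean_latency <= HBT_MAX_LATENCY_MIN:
            raise ValidationError("mean_latency must lie in [0, 40] minutes")


# ---------------------------------------------------------------------------
# Matrix containers


@dataclass
class ActivityMatrix:
    """Subjects x regions c-Fos density matrix with condition labels.

    ``values`` holds densities in cells per 250 um^2; NaN marks a missing
    (subject, region) observation prior to interpolation.
    """

    values: np.ndarray
    subject_ids: list[str]
    region_ids: list[str]
    condition: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.condition = np.asarray(self.condition, dtype=object)
        n, p = self.values.shape
        if len(self.subject_ids) != n:
            raise ValidationError("subject_ids length does not match matrix rows")
        if len(self.region_ids) != p:
            raise ValidationError("region_ids length does not match matrix columns")
        if self.condition.shape != (n,):
            raise ValidationError("condition length does not match matrix rows")
        if len(set(self.region_ids)) != p:
            raise ValidationError("region_ids must be unique")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValidationError("densities must be non-negative where present")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def conditions(self) -> list[str]:
        """Condition levels in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.condition:
            seen.setdefault(c, None)
        return list(seen)

    def condition_mask(self, level: str) -> np.ndarray:
        return self.condition == level

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.subject_ids, columns=self.region_ids)
        df.insert(0, "condition", self.condition)
        df.index.name = "subject_id"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ActivityMatrix":
        if "condition" not in df.columns:
            raise SchemaError("missing required column: condition")
        cond = df["condition"].to_numpy(dtype=object)
        vals = df.drop(columns="condition")
        return cls(
            values=vals.to_numpy(dtype=float),
            subject_ids=[str(s) for s in df.index],
            region_ids=[str(c) for c in vals.columns],
            condition=cond,
        )

    def copy(self) -> "ActivityMatrix":
        return ActivityMatrix(
            values=self.values.copy(),
            subject_ids=list(self.subject_ids),
            region_ids=list(self.region_ids),
            condition=self.condition.copy(),
        )


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM abundance with group and sex metadata."""

    abundance: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    group: np.ndarray
    sex: np.ndarray
    log_offset: float = 1.0

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        self.group = np.asarray(self.group, dtype=object)
        self.sex = np.asarray(self.sex, dtype=object)
        g, m = self.abundance.shape
        if len(self.gene_ids) != g:
            raise ValidationError("gene_ids length does not match rows")
        if len(self.sample_ids) != m:
            raise ValidationError("sample_ids length does not match columns")
        if self.group.shape != (m,) or self.sex.shape != (m,):
            raise ValidationError("group/sex length does not match samples")
        if np.any(self.abundance < 0):
            raise ValidationError("TPM abundance must be non-negative")
        if self.log_offset <= 0:
            raise ValidationError("log_offset must be positive")
        if len(set(self.group)) < 2:
            raise ValidationError("both groups must be represented")
        if len(set(self.sex)) < 2:
            raise ValidationError("both sexes must be represented")

    @property
    def n_genes(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[1]

    def log2_abundance(self) -> np.ndarray:
        return np.log2(self.abundance + self.log_offset)


@dataclass
class TFBMMatrix:
    """Genes x motifs occurrence counts in core promoter sequences."""

    counts: np.ndarray
    gene_ids: list[str]
    motif_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        g, t = self.counts.shape
        if len(self.gene_ids) != g or len(self.motif_ids) != t:
            raise ValidationError("gene_ids/motif_ids length mismatch")
        if np.any(self.counts < 0):
            raise ValidationError("motif counts must be non-negative")

    def subset(self, genes: Sequence[str]) -> np.ndarray:
        index = {gid: i for i, gid in enumerate(self.gene_ids)}
        missing = [gid for gid in genes if gid not in index]
        if missing:
            raise ValidationError(f"genes absent from TFBM matrix: {missing[:5]}")
        return self.counts[[index[gid] for gid in genes]]


# ---------------------------------------------------------------------------
# Readers

_REGION_COLUMNS = ("subject_id", "region_id", "cfos_count", "sampled_area")


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: object) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_region_activity(
    path: str | Path, schema: Optional[Mapping[str, str]] = None
) -> list[RegionActivityRecord]:
    """Read a c-Fos count table into validated records.

    ``schema`` optionally maps canonical column names (subject_id, region_id,
    cfos_count, sampled_area, n_slices) to the file's actual column names.
    Duplicate (subject, region) rows are rejected.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    _require_columns(df, _REGION_COLUMNS, path)
    dup = df.duplicated(subset=["subject_id", "region_id"], keep=False)
    if dup.any():
        first = df.loc[dup, ["subject_id", "region_id"]].iloc[0]
        raise ValidationError(
            f"{path}: duplicate (subject, region) rows, e.g. "
            f"({first['subject_id']}, {first['region_id']})"
        )
    records = []
    for idx, row in df.iterrows():
        count = row["cfos_count"]
        if not float(count).is_integer():
            raise ValidationError(f"{path} row {idx}: cfos_count must be an integer")
        if count < 0:
            raise ValidationError(f"{path} row {idx}: negative cfos_count {count}")
        n_slices = row.get("n_slices")
        if n_slices is not None and pd.isna(n_slices):
            n_slices = None
        try:
            records.append(
                RegionActivityRecord(
                    subject_id=str(row["subject_id"]),
                    region_id=str(row["region_id"]),
                    cfos_count=int(count),
                    sampled_area=float(row["sampled_area"]),
                    n_slices=None if n_slices is None else int(n_slices),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {idx}: {exc}") from exc
    return records


def read_sessions(path: str | Path) -> dict[str, list[SessionRecord]]:
    """Read HBT door-opening logs, keyed by pair."""
    df = pd.read_csv(path)
    _require_columns(df, ("pair_id", "day", "opened_by_free"), path)
    logs: dict[str, list[SessionRecord]] = {}
    for idx, row in df.iterrows():
        latency = row.get("latency")
        if latency is not None and pd.isna(latency):
            latency = None
        opened = _as_bool(row["opened_by_free"], path, idx)
        blocker = row.get("blocker_used", False)
        blocker = False if pd.isna(blocker) else _as_bool(blocker, path, idx)
        rec = SessionRecord(
            pair_id=str(row["pair_id"]),
            day=int(row["day"]),
            opened_by_free=opened,
            latency=None if latency is None else float(latency),
            blocker_used=blocker,
        )
        logs.setdefault(rec.pair_id, []).append(rec)
    return logs


def read_boldness(path: str | Path) -> dict[str, list[BoldnessRecord]]:
    df = pd.read_csv(path)
    _require_columns(df, ("pair_id", "rat_id", "day", "peek_latency", "peeked"), path)
    logs: dict[str, list[BoldnessRecord]] = {}
    for idx, row in df.iterrows():
        rec = BoldnessRecord(
            pair_id=str(row["pair_id"]),
            rat_id=str(row["rat_id"]),
            day=int(row["day"]),
            peek_latency=float(row["peek_latency"]),
            peeked=_as_bool(row["peeked"], path, idx),
        )
        logs.setdefault(rec.pair_id, []).append(rec)
    return logs


def read_social_interactions(path: str | Path) -> list[SocialInteractionSummary]:
    df = pd.read_csv(path)
    _require_columns(df, ("pair_id", "session", "si_count", "si_duration"), path)
    out = []
    for _, row in df.iterrows():
        out.append(
            SocialInteractionSummary(
                pair_id=str(row["pair_id"]),
                session=str(row["session"]),
                si_count=int(row["si_count"]),
                si_duration=float(row["si_duration"]),
                window=float(row.get("window", 300.0) or 300.0),
            )
        )
    return out


def read_ct_table(path: str | Path) -> list[CtRecord]:
    df = pd.read_csv(path)
    _require_columns(df, ("sample_id", "group", "ct_target", "ct_reference"), path)
    return [
        CtRecord(
            sample_id=str(row["sample_id"]),
            group=str(row["group"]),
            ct_target=float(row["ct_target"]),
            ct_reference=float(row["ct_reference"]),
        )
        for _, row in df.iterrows()
    ]


def read_expression(
    tpm_path: str | Path, meta_path: str | Path, log_offset: float = 1.0
) -> ExpressionMatrix:
    """Read a genes x samples TPM TSV plus a sample metadata CSV.

    The TSV has gene ids in the first column and one column per sample; the
    metadata CSV needs sample_id, group, sex.
    """
    tpm = pd.read_csv(tpm_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path)
    _require_columns(meta, ("sample_id", "group", "sex"), meta_path)
    meta = meta.set_index("sample_id")
    missing = [s for s in tpm.columns if s not in meta.index]
    if missing:
        raise SchemaError(f"{meta_path}: no metadata for sample(s) {missing[:5]}")
    meta = meta.loc[tpm.columns]
    return ExpressionMatrix(
        abundance=tpm.to_numpy(dtype=float),
        gene_ids=[str(g) for g in tpm.index],
        sample_ids=[str(s) for s in tpm.columns],
        group=meta["group"].to_numpy(dtype=object),
        sex=meta["sex"].to_numpy(dtype=object),
        log_offset=log_offset,
    )


def read_tfbm(path: str | Path) -> TFBMMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return TFBMMatrix(
        counts=df.to_numpy(dtype=float),
        gene_ids=[str(g) for g in df.index],
        motif_ids=[str(m) for m in df.columns],
    )


def _as_bool(value: object, path: object, idx: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer)) and value in (0, 1):
        return bool(value)
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("true", "1", "yes"):
            return True
        if v in ("false", "0", "no"):
            return False
    raise ValidationError(f"{path} row {idx}: cannot interpret {value!r} as boolean")


# ---------------------------------------------------------------------------
# Pivot and writers


def pivot_to_matrix(
    records: Sequence[RegionActivityRecord],
    conditions: Mapping[str, str],
) -> ActivityMatrix:
    """Arrange per-record densities into a subjects x regions matrix.

    Cells with no record stay NaN (missing); they are filled later by
    condition-mean interpolation. Every subject must have a condition label.
    """
    subjects: dict[str, None] = {}
    regions: dict[str, None] = {}
    for rec in records:
        subjects.setdefault(rec.subject_id, None)
        regions.setdefault(rec.region_id, None)
    unlabeled = [s for s in subjects if s not in conditions]
    if unlabeled:
        raise ValidationError(f"subjects without a condition label: {unlabeled[:5]}")
    subject_ids = list(subjects)
    region_ids = list(regions)
    srow = {s: i for i, s in enumerate(subject_ids)}
    rcol = {r: j for j, r in enumerate(region_ids)}
    values = np.full((len(subject_ids), len(region_ids)), np.nan)
    for rec in records:
        i, j = srow[rec.subject_id], rcol[rec.region_id]
        if not np.isnan(values[i, j]):
            raise ValidationError(
                f"duplicate record for ({rec.subject_id}, {rec.region_id})"
            )
        values[i, j] = rec.density
    condition = np.array([conditions[s] for s in subject_ids], dtype=object)
    return ActivityMatrix(values, subject_ids, region_ids, condition)


_SUPPORTED_FORMATS = ("csv", "json")


def write_results(result: object, path: str | Path, format: str = "json") -> None:
    """Serialize a result object (dataclass or DataFrame) to CSV or JSON.

    Writers are round-trip safe: numeric fields survive to 1e-12, labels
    exactly. NaNs are emitted as JSON null / empty CSV cells.
    """
    if format not in _SUPPORTED_FORMATS:
        raise ValueError(
            f"unknown format {format!r}; supported: {', '.join(_SUPPORTED_FORMATS)}"
        )
    path = Path(path)
    if isinstance(result, pd.DataFrame):
        if format == "csv":
            result.to_csv(path, index=False)
        else:
            path.write_text(result.to_json(orient="records", double_precision=15))
        return
    if dataclasses.is_dataclass(result) and not isinstance(result, type):
        payload = _dataclass_to_jsonable(result)
        if format == "json":
            path.write_text(json.dumps(payload, indent=2))
        else:
            pd.DataFrame(payload).to_csv(path, index=False)
        return
    raise TypeError(f"cannot serialize object of type {type(result).__name__}")


def _dataclass_to_jsonable(obj: object) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, np.ndarray):
            v = np.where(np.isnan(v.astype(float)), None, v.astype(object)).tolist() \
                if v.dtype.kind == "f" else v.tolist()
        elif isinstance(v, (np.integer, np.floating)):
            v = v.item()
        out[f.name] = v
    return out


def load_json_result(cls: type, path: str | Path):
    """Rehydrate a dataclass previously written by :func:`write_results`."""
    payload = json.loads(Path(path).read_text())
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in payload:
            continue
        v = payload[f.name]
        if isinstance(v, list):
            arr = np.array(
                [[np.nan if x is None else x for x in row] for row in v]
                if v and isinstance(v[0], list)
                else [np.nan if x is None else x for x in v]
            )
            v = arr
        kwargs[f.name] = v
    return cls(**kwargs)


def write_edge_list(
    adjacency: np.ndarray,
    r_matrix: np.ndarray,
    region_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Write network edges as a (source, target, r) CSV."""
    rows = []
    p = len(region_ids)
    for i in range(p):
        for j in range(i + 1, p):
            if adjacency[i, j]:
                rows.append((region_ids[i], region_ids[j], r_matrix[i, j]))
    pd.DataFrame(rows, columns=["source", "target", "r"]).to_csv(path, index=False)
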