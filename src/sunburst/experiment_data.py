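"""Data model and readers/writers for per-experiment path-choice datasets.

A Sunburst-style experiment presents each subject with K radial paths and
records a single committed choice.  The digitized summary of such an
experiment is a vector of per-path counts plus boolean *role* flags that
carry all of the geometric meaning used downstream: which path is the
shortcut, which two flank the blocked training route (adjacent), which are
the outermost arms, which heads toward a salient cue, and which arms are
excluded from scoring altogether (e.g., the six shortened left arms of the
original apparatus).  Angles and coordinates are deliberately not modeled.

Two interchangeable on-disk layouts are supported:

* ``experiments.csv`` — one row per (experiment, path), flags as 0/1, with a
  companion ``<stem>_meta.csv`` holding experiment-level fields
  (``n_no_choice``, ``provenance``).
* a JSON mirror — one object per experiment with a nested ``paths`` array.

Unknown columns are preserved as opaque per-record metadata rather than
rejected, leaving an adapter point for externally digitized datasets whose
exact column sets may differ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "PathSpec",
    "ExperimentRecord",
    "Dataset",
    "read_dataset",
    "write_dataset",
    "to_percentages",
]

SPECIES_LABELS = frozenset({"rat", "monkey", "human"})
SCORING_LABELS = frozenset({"first_choice", "mixed_order"})

#: Boolean role columns, in canonical file order.
FLAG_FIELDS = (
    "is_shortcut",
    "is_adjacent",
    "is_outer",
    "is_cued",
    "is_training",
    "is_excluded",
    "intersects_training",
    "matches_first_turn",
    "reward_side",
)

_PATH_COLUMNS = ("study_id", "experiment_id", "species", "group_label",
                 "scoring", "path_index", "count") + FLAG_FIELDS
_META_COLUMNS = ("study_id", "experiment_id", "n_no_choice", "provenance")


@dataclass(frozen=True)
class PathSpec:
    """One radial path with its 1-based printed index and role flags.

    ``intersects_training`` is meaningful only for adjacent paths,
    ``matches_first_turn`` for adjacent/outer paths and ``reward_side`` for
    outer paths; the flags are carried verbatim otherwise.
    """

    index: int
    is_shortcut: bool = False
    is_adjacent: bool = False
    is_outer: bool = False
    is_cued: bool = False
    is_training: bool = False
    is_excluded: bool = False
    intersects_training: bool = False
    matches_first_turn: bool = False
    reward_side: bool = False


@dataclass(frozen=True)
class ExperimentRecord:
    """One experiment's per-path choice counts plus metadata.

    ``counts[i]`` is the number of subjects whose scored choice was
    ``paths[i]``.  ``n_no_choice`` counts subjects that never committed to a
    path; it is metadata only and never enters the scored total N, because
    preference percentages are computed over choices actually made.
    """

    study_id: str
    experiment_id: str
    species: str
    group_label: str
    scoring: str
    paths: tuple[PathSpec, ...]
    counts: tuple[int, ...]
    n_no_choice: int = 0
    provenance: str = ""
    extra: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "paths", tuple(self.paths))
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        _validate_record(self)

    # -- derived quantities -------------------------------------------------

    @property
    def scorable_paths(self) -> tuple[PathSpec, ...]:
        """Paths that enter scoring and the chance computation."""
        return tuple(p for p in self.paths if not p.is_excluded)

    @property
    def k_scorable(self) -> int:
        return len(self.scorable_paths)

    @property
    def n_scored(self) -> int:
        """N: total scored choices over non-excluded paths."""
        return sum(c for p, c in zip(self.paths, self.counts)
                   if not p.is_excluded)

    def count_of(self, index: int) -> int:
        for p, c in zip(self.paths, self.counts):
            if p.index == index:
                return c
        raise KeyError(f"no path with index {index} in "
                       f"{self.study_id}/{self.experiment_id}")

    def with_counts(self, counts: Iterable[int]) -> "ExperimentRecord":
        return replace(self, counts=tuple(int(c) for c in counts))


@dataclass(frozen=True)
class Dataset:
    """A collection of experiments with unique (study_id, experiment_id)."""

    records: tuple[ExperimentRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.study_id, rec.experiment_id)
            if key in seen:
                raise ValidationError(f"duplicate experiment id {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, study_id: str, experiment_id: str) -> ExperimentRecord:
        for rec in self.records:
            if (rec.study_id, rec.experiment_id) == (study_id, experiment_id):
                return rec
        raise KeyError((study_id, experiment_id))


def _validate_record(rec: ExperimentRecord) -> None:
    rid = f"{rec.study_id}/{rec.experiment_id}"
    if not rec.paths:
        raise ValidationError(f"{rid}: record has no paths")
    if len(rec.counts) != len(rec.paths):
        raise ValidationError(
            f"{rid}: counts length {len(rec.counts)} != paths length "
            f"{len(rec.paths)}")
    if rec.species not in SPECIES_LABELS:
        raise ValidationError(f"{rid}: unknown species {rec.species!r}")
    if rec.scoring not in SCORING_LABELS:
        raise ValidationError(f"{rid}: unknown scoring {rec.scoring!r}")
    if rec.n_no_choice < 0:
        raise ValidationError(f"{rid}: negative n_no_choice")
    indices = [p.index for p in rec.paths]
    if len(set(indices)) != len(indices):
        raise ValidationError(f"{rid}: duplicate path index within record")
    for p, c in zip(rec.paths, rec.counts):
        if c < 0:
            raise ValidationError(f"{rid}: negative count on path {p.index}")
    scorable = rec.scorable_paths
    if sum(p.is_shortcut for p in scorable) > 1:
        raise ValidationError(f"{rid}: more than one shortcut path")
    if sum(p.is_adjacent for p in scorable) > 2:
        raise ValidationError(f"{rid}: more than two adjacent paths")
    if sum(p.is_outer for p in scorable) > 2:
        raise ValidationError(f"{rid}: more than two outer paths")
    # The blocked training route may be absent from the choosable array
    # (layouts with a separate, physically blocked stub), hence 0 or 1.
    if sum(p.is_training for p in rec.paths) > 1:
        raise ValidationError(f"{rid}: more than one training path")


def to_percentages(record: ExperimentRecord) -> dict[int, float]:
    """Per-path percentages of scored choices over non-excluded paths.

    Excluded paths are absent from the result (not reported as zero); the
    returned values sum to 100.  Raises :class:`ValidationError` when the
    record holds no scored choices (N = 0), for which percentages are
    undefined.
    """
    n = record.n_scored
    if n < 1:
        raise ValidationError(
            f"{record.study_id}/{record.experiment_id}: percentages "
            "undefined for N = 0")
    return {p.index: 100.0 * c / n
            for p, c in zip(record.paths, record.counts)
            if not p.is_excluded}


# ---------------------------------------------------------------------------
# Readers / writers


def _meta_path(path: Path) -> Path:
    return path.with_name(path.stem + "_meta" + path.suffix)


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "json"):
        return suffix
    raise SchemaError(f"cannot infer format from suffix of {path}")


def read_dataset(path: str | Path, format: str | None = None) -> Dataset:
    """Read and validate a dataset from ``experiments.csv`` or its JSON mirror.

    Malformed rows are reported with their file row numbers; validation
    failures name the offending record.  No partially constructed dataset is
    ever returned.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise SchemaError(f"dataset file not found: {path}")
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "json":
        return _read_json(path)
    raise SchemaError(f"unknown format {fmt!r}")


def _read_csv(path: Path) -> Dataset:
    try:
        df = pd.read_csv(path, dtype={"study_id": str, "experiment_id": str})
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    missing = [c for c in _PATH_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    meta: dict[tuple[str, str], dict] = {}
    mpath = _meta_path(path)
    if mpath.exists():
        mdf = pd.read_csv(mpath, dtype={"study_id": str, "experiment_id": str})
        mmissing = [c for c in _META_COLUMNS if c not in mdf.columns]
        if mmissing:
            raise SchemaError(f"{mpath}: missing required columns {mmissing}")
        for _, row in mdf.iterrows():
            key = (row["study_id"], row["experiment_id"])
            extra = {c: row[c] for c in mdf.columns if c not in _META_COLUMNS}
            meta[key] = {
                "n_no_choice": int(row["n_no_choice"]),
                "provenance": "" if pd.isna(row["provenance"])
                else str(row["provenance"]),
                "extra": extra,
            }

    extra_cols = [c for c in df.columns if c not in _PATH_COLUMNS]
    records = []
    for key, group in df.groupby(["study_id", "experiment_id"], sort=False):
        paths, counts = [], []
        for idx, row in group.iterrows():
            rowno = idx + 2  # header line + 1-based
            count = row["count"]
            if pd.isna(count) or int(count) != count:
                raise SchemaError(f"{path} row {rowno}: non-integer count")
            try:
                spec = PathSpec(
                    index=int(row["path_index"]),
                    **{f: bool(int(row[f])) for f in FLAG_FIELDS})
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"{path} row {rowno}: {exc}") from exc
            paths.append(spec)
            counts.append(int(count))
        first = group.iloc[0]
        m = meta.get(key, {})
        extra = dict(m.get("extra", {}))
        for c in extra_cols:
            extra[c] = first[c]
        records.append(ExperimentRecord(
            study_id=key[0], experiment_id=key[1],
            species=str(first.species), group_label=str(first.group_label),
            scoring=str(first.scoring),
            paths=tuple(paths), counts=tuple(counts),
            n_no_choice=m.get("n_no_choice", 0),
            provenance=m.get("provenance", ""),
            extra=extra))
    if not records:
        raise SchemaError(f"{path}: no experiment rows found")
    return Dataset(records=tuple(records))


def _record_to_obj(rec: ExperimentRecord) -> dict:
    return {
        "study_id": rec.study_id,
        "experiment_id": rec.experiment_id,
        "species": rec.species,
        "group_label": rec.group_label,
        "scoring": rec.scoring,
        "n_no_choice": rec.n_no_choice,
        "provenance": rec.provenance,
        "extra": dict(rec.extra),
        "paths": [
            {"index": p.index, "count": c,
             **{f: getattr(p, f) for f in FLAG_FIELDS}}
            for p, c in zip(rec.paths, rec.counts)
        ],
    }


def _read_json(path: Path) -> Dataset:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(payload, list) or not payload:
        raise SchemaError(f"{path}: expected a non-empty list of experiments")
    records = []
    for i, obj in enumerate(payload):
        try:
            paths = tuple(
                PathSpec(index=int(p["index"]),
                         **{f: bool(p.get(f, False)) for f in FLAG_FIELDS})
                for p in obj["paths"])
            counts = tuple(int(p["count"]) for p in obj["paths"])
            records.append(ExperimentRecord(
                study_id=str(obj["study_id"]),
                experiment_id=str(obj["experiment_id"]),
                species=str(obj["species"]),
                group_label=str(obj.get("group_label", "")),
                scoring=str(obj["scoring"]),
                paths=paths, counts=counts,
                n_no_choice=int(obj.get("n_no_choice", 0)),
                provenance=str(obj.get("provenance", "")),
                extra=dict(obj.get("extra", {}))))
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: experiment #{i}: {exc}") from exc
    return Dataset(records=tuple(records))


def write_dataset(dataset: Dataset, path: str | Path,
                  format: str | None = None) -> None:
    """Write a dataset as CSV (+ companion meta CSV) or JSON.

    ``read_dataset(write_dataset(...))`` round-trips counts, flags and
    metadata losslessly.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        path.write_text(json.dumps(
            [_record_to_obj(r) for r in dataset.records], indent=2))
        return
    if fmt != "csv":
        raise SchemaError(f"unknown format {fmt!r}")
    rows, meta_rows = [], []
    for rec in dataset.records:
        for p, c in zip(rec.paths, rec.counts):
            row = {
                "study_id": rec.study_id, "experiment_id": rec.experiment_id,
                "species": rec.species, "group_label": rec.group_label,
                "scoring": rec.scoring, "path_index": p.index, "count": c,
                **{f: int(getattr(p, f)) for f in FLAG_FIELDS},
            }
            rows.append(row)
        meta_rows.append({
            "study_id": rec.study_id, "experiment_id": rec.experiment_id,
            "n_no_choice": rec.n_no_choice, "provenance": rec.provenance,
            **{k: v for k, v in rec.extra.items()},
        })
    pd.DataFrame(rows).to_csv(path, index=False)
    pd.DataFrame(meta_rows).to_csv(_meta_path(path), index=False)
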