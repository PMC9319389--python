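"""Reading, validating and writing counting datasets and presence profiles.

A *counting dataset* is the tabular input of the scoring model: one row per
binary diagnostic variable (a patient symptom or a medical-image finding),
carrying the number of patients in the cohort who exhibit it and/or a
pre-tabulated weight expressed as a percent.  A *presence profile* assigns
present/absent to every variable of a dataset and is the unit that gets
scored.

File formats
------------
Datasets travel as CSV/TSV with the column schema

    variable,group,count,weight_pct,weight_min_pct,weight_max_pct

(blank cell = absent value), preceded by optional front-matter comment lines
``# key: value`` carrying dataset-level metadata (``name``,
``total_patients``, ``source_kind``), or as a single JSON document.  Profiles
are plain text: one present-variable name per line.  Variable names are
matched exactly and case-sensitively — clinical labels such as
``Low-grade fever (37.3–38.0)`` must never be normalised.
"""

from __future__ import annotations

import csv
import difflib
import io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "VariableRecord",
    "CountingDataset",
    "PresenceProfile",
    "DatasetFormatError",
    "DatasetValidationError",
    "read_counting_dataset",
    "write_dataset",
    "read_profile",
    "write_profile",
]

#: column order of the delimited-text schema
COLUMNS = (
    "variable",
    "group",
    "count",
    "weight_pct",
    "weight_min_pct",
    "weight_max_pct",
)

SOURCE_KINDS = ("symptoms", "image_features")


class DatasetFormatError(ValueError):
    """Raised when a file cannot be parsed under its declared dialect."""


class DatasetValidationError(ValueError):
    """Raised when parsed content violates a dataset or profile invariant."""


@dataclass(frozen=True)
class VariableRecord:
    """One binary diagnostic variable.

    Parameters
    ----------
    name:
        Non-empty display label, unique within a dataset.
    group:
        Optional label tying together a mutually related categorical family,
        e.g. the fever grades or the lesion-distribution categories.  Groups
        are descriptive metadata unless strict group mode is requested.
    count:
        Number of patients exhibiting the variable (non-negative), if known.
    weight_pct:
        Pre-tabulated weight on the printed 0–100 percent scale, if supplied.
    weight_min_pct, weight_max_pct:
        Optional percent bounds for datasets that report a weight range per
        variable instead of a single count.
    """

    name: str
    group: str | None = None
    count: int | None = None
    weight_pct: float | None = None
    weight_min_pct: float | None = None
    weight_max_pct: float | None = None

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise DatasetValidationError("variable name must be non-empty")
        if self.count is not None:
            if self.count != int(self.count) or self.count < 0:
                raise DatasetValidationError(
                    f"{self.name!r}: count must be a non-negative integer, "
                    f"got {self.count!r}"
                )
        for attr in ("weight_pct", "weight_min_pct", "weight_max_pct"):
            value = getattr(self, attr)
            if value is not None and not 0.0 <= value <= 100.0:
                raise DatasetValidationError(
                    f"{self.name!r}: {attr} must lie in [0, 100], got {value!r}"
                )
        if (self.weight_min_pct is None) != (self.weight_max_pct is None):
            raise DatasetValidationError(
                f"{self.name!r}: weight_min_pct and weight_max_pct must be "
                "given together"
            )
        if (
            self.weight_min_pct is not None
            and self.weight_max_pct is not None
            and self.weight_min_pct > self.weight_max_pct
        ):
            raise DatasetValidationError(
                f"{self.name!r}: weight_min_pct ({self.weight_min_pct}) "
                f"exceeds weight_max_pct ({self.weight_max_pct})"
            )
        if (
            self.count is None
            and self.weight_pct is None
            and self.weight_min_pct is None
        ):
            raise DatasetValidationError(
                f"{self.name!r}: needs a count, a weight_pct, or a "
                "weight_min_pct/weight_max_pct pair"
            )


@dataclass(frozen=True)
class CountingDataset:
    """An ordered, validated collection of :class:`VariableRecord`.

    Row order is significant: every downstream output (weight tables, score
    contributions, enumeration columns) preserves it.
    """

    variables: tuple[VariableRecord, ...]
    total_patients: int | None = None
    source_kind: str = "symptoms"
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        if not self.variables:
            raise DatasetValidationError("dataset has no variables")
        seen: set[str] = set()
        for rec in self.variables:
            if rec.name in seen:
                raise DatasetValidationError(
                    f"duplicate variable name {rec.name!r}"
                )
            seen.add(rec.name)
        if self.total_patients is not None and self.total_patients <= 0:
            raise DatasetValidationError(
                f"total_patients must be positive, got {self.total_patients}"
            )
        if self.source_kind not in SOURCE_KINDS:
            raise DatasetValidationError(
                f"source_kind must be one of {SOURCE_KINDS}, "
                f"got {self.source_kind!r}"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(rec.name for rec in self.variables)

    def __len__(self) -> int:
        return len(self.variables)

    def __getitem__(self, name: str) -> VariableRecord:
        for rec in self.variables:
            if rec.name == name:
                return rec
        raise KeyError(name)

    def has_counts(self) -> bool:
        """True when every variable carries a patient count."""
        return all(rec.count is not None for rec in self.variables)

    def check_groups_exclusive(self) -> None:
        """Strict group mode helper: no constraint here (datasets list
        categorical families exhaustively); see PresenceProfile.check_groups.
        """


@dataclass(frozen=True)
class PresenceProfile:
    """A complete present/absent assignment over a dataset's variables."""

    dataset: CountingDataset
    presence: Mapping[str, bool]

    def __post_init__(self) -> None:
        names = set(self.dataset.names)
        given = set(self.presence)
        extra = given - names
        if extra:
            raise DatasetValidationError(
                f"profile names not in dataset: {sorted(extra)}"
            )
        missing = names - given
        if missing:
            raise DatasetValidationError(
                f"profile missing variables: {sorted(missing)}"
            )
        object.__setattr__(self, "presence", dict(self.presence))

    @property
    def present(self) -> tuple[str, ...]:
        """Present variables, in dataset order."""
        return tuple(n for n in self.dataset.names if self.presence[n])

    @property
    def absent(self) -> tuple[str, ...]:
        return tuple(n for n in self.dataset.names if not self.presence[n])

    def statuses(self) -> tuple[bool, ...]:
        """Presence flags aligned to dataset variable order."""
        return tuple(self.presence[n] for n in self.dataset.names)

    def check_groups_exclusive(self) -> None:
        """Raise if more than one member of any variable group is present.

        Opt-in guard: a patient has exactly one fever grade, so profiles with
        two grades present are clinically contradictory even though the
        profile lattice contains them.
        """
        by_group: dict[str, list[str]] = {}
        for rec in self.dataset.variables:
            if rec.group and self.presence[rec.name]:
                by_group.setdefault(rec.group, []).append(rec.name)
        bad = {g: ns for g, ns in by_group.items() if len(ns) > 1}
        if bad:
            detail = "; ".join(
                f"group {g!r}: {', '.join(ns)}" for g, ns in sorted(bad.items())
            )
            raise DatasetValidationError(
                f"multiple present variables in exclusive group(s): {detail}"
            )


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_optional_int(cell: str, *, where: str) -> int | None:
    cell = cell.strip()
    if not cell:
        return None
    try:
        return int(cell)
    except ValueError as exc:
        raise DatasetFormatError(f"{where}: expected integer, got {cell!r}") from exc


def _parse_optional_float(cell: str, *, where: str) -> float | None:
    cell = cell.strip()
    if not cell:
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise DatasetFormatError(f"{where}: expected number, got {cell!r}") from exc


def _split_front_matter(text: str) -> tuple[dict[str, str], str, int]:
    """Extract leading ``# key: value`` lines; return (meta, body, offset)."""
    meta: dict[str, str] = {}
    lines = text.splitlines(keepends=True)
    idx = 0
    for line in lines:
        stripped = line.strip()
        if not stripped.startswith("#"):
            break
        idx += 1
        payload = stripped.lstrip("#").strip()
        if ":" in payload:
            key, _, value = payload.partition(":")
            meta[key.strip()] = value.strip()
    return meta, "".join(lines[idx:]), idx


def _records_from_rows(
    rows: Iterable[Mapping[str, str]], *, first_line: int
) -> list[VariableRecord]:
    records = []
    for i, row in enumerate(rows):
        where = f"line {first_line + i}"
        name = (row.get("variable") or "").strip()
        if not name:
            raise DatasetFormatError(f"{where}: empty variable name")
        try:
            records.append(
                VariableRecord(
                    name=name,
                    group=(row.get("group") or "").strip() or None,
                    count=_parse_optional_int(row.get("count") or "", where=where),
                    weight_pct=_parse_optional_float(
                        row.get("weight_pct") or "", where=where
                    ),
                    weight_min_pct=_parse_optional_float(
                        row.get("weight_min_pct") or "", where=where
                    ),
                    weight_max_pct=_parse_optional_float(
                        row.get("weight_max_pct") or "", where=where
                    ),
                )
            )
        except DatasetValidationError as exc:
            raise DatasetValidationError(f"{where}: {exc}") from exc
    return records


def read_counting_dataset(
    path: str | Path, dialect: str | None = None
) -> CountingDataset:
    """Read and validate a counting dataset.

    Parameters
    ----------
    path:
        File to read.
    dialect:
        ``"csv"``, ``"tsv"`` or ``"json"``; inferred from the file suffix
        when omitted.
    """
    path = Path(path)
    if dialect is None:
        dialect = {".csv": "csv", ".tsv": "tsv", ".json": "json"}.get(
            path.suffix.lower(), "csv"
        )
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise DatasetFormatError(f"{path}: empty file")
    if dialect == "json":
        return _dataset_from_json(text, source=str(path))
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    return _dataset_from_delimited(
        text, delimiter="\t" if dialect == "tsv" else ",", source=str(path)
    )


def _dataset_from_delimited(
    text: str, *, delimiter: str, source: str
) -> CountingDataset:
    meta, body, offset = _split_front_matter(text)
    if not body.strip():
        raise DatasetFormatError(f"{source}: no table after front matter")
    reader = csv.DictReader(io.StringIO(body), delimiter=delimiter)
    if reader.fieldnames is None or "variable" not in reader.fieldnames:
        raise DatasetFormatError(
            f"{source}: header must include a 'variable' column, "
            f"got {reader.fieldnames!r}"
        )
    records = _records_from_rows(reader, first_line=offset + 2)
    total = meta.get("total_patients")
    return CountingDataset(
        variables=tuple(records),
        total_patients=int(total) if total else None,
        source_kind=meta.get("source_kind", "symptoms"),
        name=meta.get("name", ""),
    )


def _dataset_from_json(text: str, *, source: str) -> CountingDataset:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DatasetFormatError(f"{source}: line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(doc, dict) or "variables" not in doc:
        raise DatasetFormatError(f"{source}: expected an object with 'variables'")
    records = []
    for entry in doc["variables"]:
        records.append(
            VariableRecord(
                name=entry["variable"],
                group=entry.get("group"),
                count=entry.get("count"),
                weight_pct=entry.get("weight_pct"),
                weight_min_pct=entry.get("weight_min_pct"),
                weight_max_pct=entry.get("weight_max_pct"),
            )
        )
    return CountingDataset(
        variables=tuple(records),
        total_patients=doc.get("total_patients"),
        source_kind=doc.get("source_kind", "symptoms"),
        name=doc.get("name", ""),
    )


# ---------------------------------------------------------------------------
# writing


def write_dataset(
    dataset: CountingDataset, path: str | Path, dialect: str | None = None
) -> Path:
    """Write a dataset; ``read_counting_dataset(write_dataset(d)) == d``."""
    path = Path(path)
    if dialect is None:
        dialect = {".csv": "csv", ".tsv": "tsv", ".json": "json"}.get(
            path.suffix.lower(), "csv"
        )
    if dialect == "json":
        doc: dict = {"name": dataset.name, "source_kind": dataset.source_kind}
        if dataset.total_patients is not None:
            doc["total_patients"] = dataset.total_patients
        doc["variables"] = [
            {
                k: v
                for k, v in {
                    "variable": rec.name,
                    "group": rec.group,
                    "count": rec.count,
                    "weight_pct": rec.weight_pct,
                    "weight_min_pct": rec.weight_min_pct,
                    "weight_max_pct": rec.weight_max_pct,
                }.items()
                if v is not None
            }
            for rec in dataset.variables
        ]
        path.write_text(
            json.dumps(doc, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
        )
        return path
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    delimiter = "\t" if dialect == "tsv" else ","
    buf = io.StringIO()
    if dataset.name:
        buf.write(f"# name: {dataset.name}\n")
    buf.write(f"# source_kind: {dataset.source_kind}\n")
    if dataset.total_patients is not None:
        buf.write(f"# total_patients: {dataset.total_patients}\n")
    writer = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    writer.writerow(COLUMNS)
    for rec in dataset.variables:
        writer.writerow(
            [
                rec.name,
                rec.group or "",
                "" if rec.count is None else rec.count,
                "" if rec.weight_pct is None else _num(rec.weight_pct),
                "" if rec.weight_min_pct is None else _num(rec.weight_min_pct),
                "" if rec.weight_max_pct is None else _num(rec.weight_max_pct),
            ]
        )
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def _num(x: float) -> str:
    # render 5.0 as "5" so round-trips are textually tidy; float() reads both
    return str(int(x)) if float(x) == int(x) else repr(float(x))


# ---------------------------------------------------------------------------
# profiles


def read_profile(
    path_or_tokens: str | Path | Sequence[str],
    dataset: CountingDataset,
) -> PresenceProfile:
    """Build a profile from present-variable names.

    ``path_or_tokens`` is either a file (one present-variable name per line,
    ``#`` comments ignored) or an in-memory sequence of names.  Named
    variables are marked present; every other dataset variable is absent.
    Unknown names raise a validation error listing near-matches.
    """
    if isinstance(path_or_tokens, (str, Path)):
        lines = Path(path_or_tokens).read_text(encoding="utf-8").splitlines()
        tokens = [ln.strip() for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    else:
        tokens = [str(t) for t in path_or_tokens]
    known = set(dataset.names)
    unknown = [t for t in tokens if t not in known]
    if unknown:
        hints = []
        for t in unknown:
            close = difflib.get_close_matches(t, dataset.names, n=3, cutoff=0.4)
            hints.append(f"{t!r}" + (f" (did you mean: {', '.join(close)}?)" if close else ""))
        raise DatasetValidationError(
            "unknown variable name(s): " + "; ".join(hints)
        )
    present = set(tokens)
    return PresenceProfile(
        dataset=dataset,
        presence={n: (n in present) for n in dataset.names},
    )


def write_profile(profile: PresenceProfile, path: str | Path) -> Path:
    """Write the present-variable names of a profile, one per line."""
    path = Path(path)
    path.write_text(
        "".join(f"{n}\n" for n in profile.present), encoding="utf-8"
    )
    return path
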