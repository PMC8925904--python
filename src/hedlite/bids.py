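"""BIDS event tables and sidecars: reading, inheritance, assembly, validation.

Event files are tab-separated UTF-8 text with required ``onset`` and
``duration`` columns and ``n/a`` for missing cells.  Sidecars are JSON
dictionaries keyed by column name; a column whose ``HED`` entry is a
mapping is categorical (level name -> annotation), a column whose ``HED``
entry is a single string containing one ``#`` is a value column, and keys
without a ``HED`` entry are unannotated.  Definition groups found anywhere
in sidecar annotations are harvested into the sidecar's definition pool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import definitions as defs_mod
from .errors import FormatError, HedError, Issue
from .schema import HedSchema
from .strings import (
    HedString,
    count_placeholders,
    parse_hed_string,
    substitute_placeholder,
)

NA = "n/a"


# ---------------------------------------------------------------------------
# Event tables


class EventTable:
    """A BIDS events table.  Cells are kept as written (strings, ``n/a``)."""

    def __init__(self, df: pd.DataFrame, path: str | None = None):
        if "onset" not in df.columns:
            raise FormatError(f"{path or 'events table'}: missing 'onset' column")
        if "duration" not in df.columns:
            raise FormatError(f"{path or 'events table'}: missing 'duration' column")
        self.df = df.reset_index(drop=True)
        self.path = path
        self.issues: list[Issue] = []
        onsets = self.onsets
        if (pd.Series(onsets).diff().dropna() < 0).any():
            self.issues.append(
                Issue(
                    code="non-monotone-onsets",
                    message="onset column is not sorted non-decreasing",
                    file=path,
                )
            )

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    @property
    def onsets(self):
        return pd.to_numeric(self.df["onset"], errors="coerce").to_numpy(float)

    def __len__(self) -> int:
        return len(self.df)

    def rows(self):
        """Iterate rows as ordered column->string dicts (``n/a`` preserved)."""
        cols = self.columns
        for values in self.df.itertuples(index=False, name=None):
            yield dict(zip(cols, values))


def read_events_tsv(path) -> EventTable:
    """Read a BIDS ``...events.tsv`` file."""
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
    )
    return EventTable(df, path=str(path))


def write_events_tsv(table: EventTable, path) -> None:
    """Write a table back out (tabs, UTF-8, newline-terminated, ``n/a``)."""
    df = table.df.fillna(NA)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8", lineterminator="\n")


# ---------------------------------------------------------------------------
# Sidecars


@dataclass
class ColumnAnnotation:
    """The parsed HED annotation attached to one event-file column."""

    kind: str  # "categorical" | "value"
    categorical_map: dict[str, HedString] = field(default_factory=dict)
    value_template: HedString | None = None
    levels: dict[str, str] = field(default_factory=dict)
    description: str = ""


@dataclass
class Sidecar:
    """Merged per-column annotations plus harvested definition strings."""

    column_annotations: dict[str, ColumnAnnotation] = field(default_factory=dict)
    definition_strings: list[HedString] = field(default_factory=list)
    unannotated: set[str] = field(default_factory=set)
    raw: dict = field(default_factory=dict)
    issues: list[Issue] = field(default_factory=list)

    def registry(self) -> defs_mod.DefinitionRegistry:
        """Build the definition registry from the harvested definitions."""
        return defs_mod.extract_definitions(self.definition_strings)


def sidecar_from_dict(data: dict, schema: HedSchema, source: str = "") -> Sidecar:
    """Interpret a sidecar dictionary (shape rules in the module docstring)."""
    sidecar = Sidecar(raw=data)
    for key, entry in data.items():
        if not isinstance(entry, dict) or "HED" not in entry:
            sidecar.unannotated.add(key)
            continue
        hed = entry["HED"]
        description = entry.get("Description", "")
        levels = entry.get("Levels", {}) if isinstance(entry.get("Levels"), dict) else {}
        if isinstance(hed, dict):
            cat_map: dict[str, HedString] = {}
            for level, text in hed.items():
                if not isinstance(text, str):
                    sidecar.issues.append(
                        Issue(
                            code="sidecar-format",
                            message=f"{key}/{level}: level annotation must be text",
                            file=source or None,
                        )
                    )
                    continue
                parsed = _parse_annotation(
                    text, schema, sidecar, f"{key}/{level}", source
                )
                if parsed is None:
                    continue
                parsed = _harvest_definitions(parsed, sidecar, f"{source}:{key}")
                cat_map[level] = parsed
            sidecar.column_annotations[key] = ColumnAnnotation(
                kind="categorical",
                categorical_map=cat_map,
                levels=levels,
                description=description,
            )
        elif isinstance(hed, str):
            parsed = _parse_annotation(hed, schema, sidecar, key, source)
            if parsed is None:
                continue
            remainder = _harvest_definitions(parsed, sidecar, f"{source}:{key}")
            if remainder.is_empty():
                # a dedicated definitions key: contributes nothing per-row
                continue
            n = count_placeholders(remainder.items)
            if n != 1:
                sidecar.issues.append(
                    Issue(
                        code="placeholder-arity",
                        message=(
                            f"value column {key!r} template must contain exactly "
                            f"one '#', found {n}"
                        ),
                        file=source or None,
                    )
                )
                continue
            sidecar.column_annotations[key] = ColumnAnnotation(
                kind="value",
                value_template=remainder,
                description=description,
            )
        else:
            sidecar.issues.append(
                Issue(
                    code="sidecar-format",
                    message=f"{key}: HED entry must be a mapping or a string",
                    file=source or None,
                )
            )
    return sidecar


def _parse_annotation(text, schema, sidecar, label, source) -> HedString | None:
    try:
        return parse_hed_string(text, schema)
    except HedError as exc:
        sidecar.issues.append(
            Issue(
                code="annotation-parse",
                message=f"{label}: {exc}",
                file=source or None,
            )
        )
        return None


def _harvest_definitions(hs: HedString, sidecar: Sidecar, provenance: str) -> HedString:
    def_items = [it for it in hs.items if defs_mod.is_definition_group(it)]
    if def_items:
        sidecar.definition_strings.append(HedString(def_items))
    return defs_mod.strip_definitions(hs)


def read_sidecar(path, schema: HedSchema) -> Sidecar:
    """Read a single ``...events.json`` sidecar file."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    return sidecar_from_dict(data, schema, source=str(path))


def write_sidecar(sidecar: Sidecar, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(sidecar.raw, fh, indent=4)
        fh.write("\n")


def gather_sidecars(dataset_root, events_path, schema: HedSchema) -> Sidecar:
    """Merge all ``*events.json`` files on the path from root to the file.

    Deeper sidecars override shallower ones per top-level key (whole-column
    replacement, the BIDS inheritance granularity).
    """
    root = Path(dataset_root).resolve()
    events_path = Path(events_path).resolve()
    directories = [root]
    try:
        rel = events_path.parent.relative_to(root)
        for part in rel.parts:
            directories.append(directories[-1] / part)
    except ValueError:
        pass
    merged: dict = {}
    found = False
    for directory in directories:
        for candidate in sorted(directory.glob("*events.json")):
            with open(candidate, "r", encoding="utf-8") as fh:
                data = json.load(fh)
            merged.update(data)
            found = True
    sidecar = sidecar_from_dict(merged, schema, source=str(events_path))
    if not found:
        sidecar.issues.append(
            Issue(
                code="no-sidecar",
                message=f"no *events.json found between {root} and {events_path}",
                file=str(events_path),
            )
        )
    return sidecar


# ---------------------------------------------------------------------------
# Assembly


@dataclass
class AssembledEvent:
    """One event marker with its fully assembled annotation."""

    onset: float
    hed: HedString
    sample: int | None = None
    contributions: dict[str, HedString] = field(default_factory=dict)
    issues: list[Issue] = field(default_factory=list)
    row_index: int | None = None


def assemble(
    row: dict,
    sidecar: Sidecar,
    registry: defs_mod.DefinitionRegistry | None = None,
    schema: HedSchema | None = None,
    expand: bool = False,
) -> AssembledEvent:
    """Assemble the single HED string for one event row.

    Columns are visited in row order; categorical cells look up their
    level's annotation, value cells substitute the cell text for ``#``, and
    ``n/a`` or unannotated cells contribute nothing.  A categorical cell
    value with no annotation entry is flagged but assembly continues.
    """
    contributions: dict[str, HedString] = {}
    issues: list[Issue] = []
    items = []
    for column, cell in row.items():
        annotation = sidecar.column_annotations.get(column)
        if annotation is None or cell == NA or cell == "" or cell is None:
            continue
        if annotation.kind == "categorical":
            fragment = annotation.categorical_map.get(cell)
            if fragment is None:
                issues.append(
                    Issue(
                        code="missing-level",
                        message=(
                            f"column {column!r}: categorical value {cell!r} "
                            "has no sidecar annotation"
                        ),
                    )
                )
                continue
        else:
            fragment = substitute_placeholder(annotation.value_template, cell)
        contributions[column] = fragment
        items.extend(fragment.items)
    hed = HedString(list(items))
    if expand:
        if registry is None or schema is None:
            raise ValueError("expand=True requires a registry and schema")
        hed = defs_mod.expand_defs(hed, registry, schema)
    onset = float(row["onset"]) if row.get("onset") not in (None, NA, "") else float("nan")
    sample = None
    raw_sample = row.get("sample")
    if raw_sample not in (None, NA, ""):
        try:
            sample = int(float(raw_sample))
        except ValueError:
            pass
    return AssembledEvent(
        onset=onset,
        hed=hed,
        sample=sample,
        contributions=contributions,
        issues=issues,
    )


def assemble_events(
    table: EventTable,
    sidecar: Sidecar,
    registry: defs_mod.DefinitionRegistry | None = None,
    schema: HedSchema | None = None,
    expand: bool = False,
) -> list[AssembledEvent]:
    """Assemble every row of a table (row order preserved)."""
    events = []
    for i, row in enumerate(table.rows()):
        event = assemble(row, sidecar, registry=registry, schema=schema, expand=expand)
        event.row_index = i
        events.append(event)
    return events


# ---------------------------------------------------------------------------
# Dataset-level validation


def find_event_files(root) -> list[Path]:
    return sorted(Path(root).rglob("*_events.tsv"))


def validate_dataset(root, schema: HedSchema | None = None) -> list[Issue]:
    """Validate every events file under *root* against its merged sidecars.

    Aggregates sidecar parse problems, definition conflicts and lint,
    missing categorical levels, and unmatched temporal Offsets.  Returns
    issues as data; an empty list means the dataset is clean.
    """
    from .temporal import resolve_processes  # local import to avoid a cycle

    if schema is None:
        from .resources import load_mini_schema

        schema = load_mini_schema()
    issues: list[Issue] = []
    root = Path(root)
    sidecar_cache: dict[str, tuple[Sidecar, defs_mod.DefinitionRegistry | None]] = {}
    for events_path in find_event_files(root):
        cache_key = str(events_path.parent)
        if cache_key in sidecar_cache:
            sidecar, registry = sidecar_cache[cache_key]
        else:
            sidecar = gather_sidecars(root, events_path, schema)
            issues.extend(sidecar.issues)
            try:
                registry = sidecar.registry()
                issues.extend(defs_mod.validate_definitions(registry, schema))
            except HedError as exc:
                registry = None
                issues.append(
                    Issue(
                        code="definition-conflict",
                        message=str(exc),
                        file=str(events_path),
                    )
                )
            sidecar_cache[cache_key] = (sidecar, registry)
        try:
            table = read_events_tsv(events_path)
        except FormatError as exc:
            issues.append(
                Issue(code="table-format", message=str(exc), file=str(events_path))
            )
            continue
        issues.extend(table.issues)
        events = assemble_events(table, sidecar)
        for event in events:
            for issue in event.issues:
                issues.append(
                    Issue(
                        code=issue.code,
                        message=issue.message,
                        file=str(events_path),
                        line=(event.row_index or 0) + 1,
                    )
                )
        timeline = resolve_processes(events)
        for issue in timeline.issues:
            issues.append(
                Issue(code=issue.code, message=issue.message, file=str(events_path))
            )
    return issues
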