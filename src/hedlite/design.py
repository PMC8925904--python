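"""Experimental-design extraction from definitions and the event stream.

A definition whose body contains ``Condition-variable/F`` declares its own
name as a level of factor ``F``; a bare ``Condition-variable`` makes the
definition a singleton factor of its own.  Levels referenced directly in
an event's assembled string are column-encoded; levels that open temporal
processes (e.g. a setup meta-event at the first sample) are row-encoded
and apply to every event within the process span, boundary events
included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bids import AssembledEvent
from .definitions import DefinitionRegistry, split_def_value
from .errors import Issue
from .strings import HedGroup
from .temporal import Timeline

ENCODING_COLUMN = "column"
ENCODING_ROW = "row"


@dataclass
class ConditionVariable:
    """One factor of the design: a named set of definition levels."""

    factor_name: str
    levels: list[str] = field(default_factory=list)
    encoding: str = ENCODING_COLUMN


@dataclass
class DesignMatrix:
    factors: list[ConditionVariable]
    assignment: list[dict[str, str | None]]
    issues: list[Issue] = field(default_factory=list)

    def factor(self, name: str) -> ConditionVariable:
        key = name.casefold()
        for f in self.factors:
            if f.factor_name.casefold() == key:
                return f
        raise KeyError(name)

    def column(self, factor_name: str) -> list[str | None]:
        key = self.factor(factor_name).factor_name
        return [row.get(key) for row in self.assignment]


def extract_condition_variables(
    registry: DefinitionRegistry,
) -> list[ConditionVariable]:
    """Derive factors and their levels from the definition registry alone."""
    factors: dict[str, ConditionVariable] = {}
    for definition in registry:
        for tag in HedGroup(definition.body).iter_tags():
            if tag.node.name.casefold() != "condition-variable":
                continue
            factor_name = tag.value if tag.value is not None else definition.name
            key = factor_name.casefold()
            if key not in factors:
                factors[key] = ConditionVariable(factor_name=factor_name)
            if definition.name not in factors[key].levels:
                factors[key].levels.append(definition.name)
    return list(factors.values())


def _referenced_definitions(event: AssembledEvent) -> set[str]:
    names = set()
    for tag in event.hed.iter_tags():
        lowered = tag.node.name.casefold()
        if lowered in ("def", "def-expand") and tag.value is not None:
            names.add(split_def_value(tag.value)[0].casefold())
    return names


def design_matrix(
    events: list[AssembledEvent],
    timeline: Timeline,
    factors: list[ConditionVariable],
) -> DesignMatrix:
    """Assign a level of each factor to each event where one applies."""
    level_to_factor: dict[str, ConditionVariable] = {}
    level_display: dict[str, str] = {}
    for factor in factors:
        for level in factor.levels:
            level_to_factor[level.casefold()] = factor
            level_display[level.casefold()] = level

    issues: list[Issue] = []
    assignment: list[dict[str, str | None]] = [
        {f.factor_name: None for f in factors} for _ in events
    ]

    def assign(i: int, factor: ConditionVariable, level_key: str) -> None:
        current = assignment[i][factor.factor_name]
        level = level_display[level_key]
        if current is not None and current.casefold() != level_key:
            issues.append(
                Issue(
                    code="level-conflict",
                    message=(
                        f"event {i}: factor {factor.factor_name!r} assigned both "
                        f"{current!r} and {level!r}"
                    ),
                    line=i + 1,
                )
            )
            return
        assignment[i][factor.factor_name] = level

    # column-encoded: direct references in the assembled string
    for i, event in enumerate(events):
        for name in _referenced_definitions(event):
            factor = level_to_factor.get(name)
            if factor is not None:
                assign(i, factor, name)

    # row-encoded: temporal processes opened by level definitions span events
    row_encoded: set[str] = set()
    for process in timeline.processes:
        key = process.definition_name.casefold()
        factor = level_to_factor.get(key)
        if factor is None:
            continue
        row_encoded.add(factor.factor_name.casefold())
        for i, event in enumerate(events):
            if process.onset_time <= event.onset <= process.offset_time:
                assign(i, factor, key)
    for factor in factors:
        factor.encoding = (
            ENCODING_ROW
            if factor.factor_name.casefold() in row_encoded
            else ENCODING_COLUMN
        )
    return DesignMatrix(factors=factors, assignment=assignment, issues=issues)


def summarize_design(dm: DesignMatrix) -> dict:
    """Per-factor level counts plus pairwise crossed-cell counts."""
    summary: dict = {"factors": {}, "cells": {}}
    for factor in dm.factors:
        counts = {level: 0 for level in factor.levels}
        for row in dm.assignment:
            level = row.get(factor.factor_name)
            if level is not None:
                counts[level] = counts.get(level, 0) + 1
        summary["factors"][factor.factor_name] = {
            "levels": list(factor.levels),
            "encoding": factor.encoding,
            "counts": counts,
            "n_events": sum(counts.values()),
        }
    for a in range(len(dm.factors)):
        for b in range(a + 1, len(dm.factors)):
            fa, fb = dm.factors[a], dm.factors[b]
            cells: dict[tuple[str, str], int] = {}
            for row in dm.assignment:
                la, lb = row.get(fa.factor_name), row.get(fb.factor_name)
                if la is not None and lb is not None:
                    cells[(la, lb)] = cells.get((la, lb), 0) + 1
            summary["cells"][(fa.factor_name, fb.factor_name)] = cells
    return summary
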