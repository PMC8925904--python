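"""Onset/Offset scope resolution and event-context insertion.

A group containing a ``Def/Name`` together with an ``Onset`` tag opens an
event process for ``Name`` at the marker's time; the process stays in
effect until the next marker whose annotation groups the same definition
with ``Onset`` (close-and-reopen) or ``Offset`` (explicit close).
Processes still open at the last marker close there and are flagged as
``end-of-record``.  Intervals are half-open ``[onset, offset)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .bids import AssembledEvent
from .errors import Issue
from .schema import HedSchema
from .strings import HedGroup, HedString, HedTag
from .definitions import split_def_value

CLOSED_BY_OFFSET = "explicit-offset"
CLOSED_BY_REONSET = "next-onset"
CLOSED_BY_END = "end-of-record"


@dataclass
class EventProcess:
    """A resolved (definition, onset-time, offset-time) interval."""

    definition_name: str
    onset_time: float
    offset_time: float
    closed_by: str

    @property
    def duration(self) -> float:
        return self.offset_time - self.onset_time

    def contains(self, t: float) -> bool:
        """Strict interior test (both boundary markers excluded)."""
        return self.onset_time < t < self.offset_time


@dataclass
class Timeline:
    processes: list[EventProcess] = field(default_factory=list)
    instantaneous: list[tuple[float, HedString]] = field(default_factory=list)
    issues: list[Issue] = field(default_factory=list)

    def for_definition(self, name: str) -> list[EventProcess]:
        key = name.casefold()
        return [p for p in self.processes if p.definition_name.casefold() == key]

    def total_duration(self, name: str) -> float:
        return sum(p.duration for p in self.for_definition(name))


def temporal_references(hed: HedString):
    """Yield (definition_name, kind) for each top-level temporal group.

    ``kind`` is ``"onset"`` or ``"offset"``.  A group qualifies when a Def
    (or Def-expand subgroup) and an Onset/Offset tag are siblings in it.
    """
    for group in hed.groups():
        kind = None
        for tag in group.tags():
            lowered = tag.node.name.casefold()
            if lowered == "onset":
                kind = "onset"
            elif lowered == "offset":
                kind = "offset"
        if kind is None:
            continue
        name = _def_name_in_group(group)
        if name is not None:
            yield name, kind


def _def_name_in_group(group: HedGroup) -> str | None:
    for tag in group.tags():
        if tag.node.name.casefold() == "def" and tag.value is not None:
            return split_def_value(tag.value)[0]
    for sub in group.groups():
        for tag in sub.tags():
            if tag.node.name.casefold() == "def-expand" and tag.value is not None:
                return split_def_value(tag.value)[0]
    return None


def resolve_processes(events: list[AssembledEvent]) -> Timeline:
    """Sweep the (time-sorted) markers and resolve all event processes."""
    timeline = Timeline()
    open_processes: dict[str, tuple[str, float]] = {}  # key -> (name, t0)
    last_time = math.nan
    for event in events:
        t = event.onset
        if not math.isnan(t):
            last_time = t
        refs = list(temporal_references(event.hed))
        for name, kind in refs:
            key = name.casefold()
            if kind == "onset":
                if key in open_processes:
                    prev_name, t0 = open_processes.pop(key)
                    timeline.processes.append(
                        EventProcess(prev_name, t0, t, CLOSED_BY_REONSET)
                    )
                open_processes[key] = (name, t)
            else:  # offset
                if key in open_processes:
                    prev_name, t0 = open_processes.pop(key)
                    timeline.processes.append(
                        EventProcess(prev_name, t0, t, CLOSED_BY_OFFSET)
                    )
                else:
                    timeline.issues.append(
                        Issue(
                            code="unmatched-offset",
                            message=(
                                f"Offset for definition {name!r} at t={t} "
                                "has no open process"
                            ),
                        )
                    )
        if not refs and not event.hed.is_empty():
            timeline.instantaneous.append((t, event.hed))
    for name, t0 in open_processes.values():
        timeline.processes.append(EventProcess(name, t0, last_time, CLOSED_BY_END))
    timeline.processes.sort(key=lambda p: (p.onset_time, p.definition_name.casefold()))
    return timeline


def insert_context(
    events: list[AssembledEvent], timeline: Timeline, schema: HedSchema
) -> list[AssembledEvent]:
    """Return new events carrying an ``(Event-context, Def/..., ...)`` group.

    A process is in an event's context when the event time lies in the
    strict interior of the process interval; a process's own boundary
    markers are never part of its context.  Events with no enclosing
    process are returned unchanged.
    """
    context_node = schema.get("Event-context")
    def_node = schema.get("Def")
    out = []
    for event in events:
        names = sorted(
            {p.definition_name for p in timeline.processes if p.contains(event.onset)},
            key=str.casefold,
        )
        if not names:
            out.append(event)
            continue
        group = HedGroup(
            [HedTag(node=context_node)]
            + [HedTag(node=def_node, value=name) for name in names]
        )
        contextualized = AssembledEvent(
            onset=event.onset,
            hed=HedString(list(event.hed.items) + [group]),
            sample=event.sample,
            contributions=event.contributions,
            issues=event.issues,
            row_index=event.row_index,
        )
        out.append(contextualized)
    return out
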