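import numpy as np
import pytest

from hedlite.bids import AssembledEvent
from hedlite.strings import HedString, parse_hed_string, serialize
from hedlite.temporal import (
    CLOSED_BY_END,
    CLOSED_BY_OFFSET,
    CLOSED_BY_REONSET,
    insert_context,
    resolve_processes,
)


def _event(t, text, schema):
    return AssembledEvent(onset=t, hed=parse_hed_string(text, schema))


class TestResolve:
    def test_face_image_duration_from_excerpt(self, excerpt_timeline):
        (first, second) = excerpt_timeline.for_definition("Face-image")
        assert first.onset_time == pytest.approx(23.870)
        assert first.offset_time == pytest.approx(24.750)
        assert first.duration == pytest.approx(0.88)
        assert first.closed_by == CLOSED_BY_OFFSET

    def test_excerpt_has_no_issues(self, excerpt_timeline):
        assert excerpt_timeline.issues == []

    def test_reonset_closes_previous(self, schema):
        events = [
            _event(1.0, "(Def/Cross-only, Onset)", schema),
            _event(2.0, "(Def/Cross-only, Onset)", schema),
            _event(3.0, "(Def/Cross-only, Offset)", schema),
        ]
        timeline = resolve_processes(events)
        procs = timeline.for_definition("Cross-only")
        assert [(p.onset_time, p.offset_time, p.closed_by) for p in procs] == [
            (1.0, 2.0, CLOSED_BY_REONSET),
            (2.0, 3.0, CLOSED_BY_OFFSET),
        ]

    def test_lone_offset_is_unmatched(self, schema):
        events = [_event(1.0, "(Def/Cross-only, Offset)", schema)]
        timeline = resolve_processes(events)
        assert timeline.processes == []
        assert [i.code for i in timeline.issues] == ["unmatched-offset"]

    def test_open_process_closes_at_end_of_record(self, schema):
        events = [
            _event(1.0, "(Def/Cross-only, Onset)", schema),
            _event(5.0, "Sensory-event", schema),
        ]
        (proc,) = resolve_processes(events).processes
        assert proc.offset_time == 5.0
        assert proc.closed_by == CLOSED_BY_END

    def test_def_expand_groups_also_resolve(self, schema, registry):
        from hedlite.definitions import expand_defs

        events = [
            AssembledEvent(
                onset=1.0,
                hed=expand_defs(
                    parse_hed_string("(Def/Cross-only, Onset)", schema),
                    registry,
                    schema,
                ),
            ),
            _event(2.0, "(Def/Cross-only, Offset)", schema),
        ]
        (proc,) = resolve_processes(events).processes
        assert proc.duration == pytest.approx(1.0)

    def test_instantaneous_events_recorded(self, schema):
        events = [
            _event(1.0, "(Def/Cross-only, Onset)", schema),
            _event(1.5, "Agent-action, Def/Press-left-finger", schema),
            _event(2.0, "(Def/Cross-only, Offset)", schema),
        ]
        timeline = resolve_processes(events)
        assert [t for t, _ in timeline.instantaneous] == [1.5]

    def test_instantaneous_events_do_not_change_durations(self, schema):
        base = [
            _event(1.0, "(Def/Cross-only, Onset)", schema),
            _event(4.0, "(Def/Cross-only, Offset)", schema),
        ]
        with_extra = [
            base[0],
            _event(2.0, "Sensory-event", schema),
            _event(3.0, "Agent-action", schema),
            base[1],
        ]
        assert resolve_processes(base).total_duration(
            "Cross-only"
        ) == resolve_processes(with_extra).total_duration("Cross-only")


class TestContext:
    def test_press_inside_face_process(self, excerpt_events, excerpt_timeline, schema):
        contextualized = insert_context(excerpt_events, excerpt_timeline, schema)
        press = contextualized[2]  # left_press at 24.081
        rendered = serialize(press.hed, "short")
        assert "Event-context" in rendered
        assert "Def/Face-image" in rendered
        assert "Def/Left-sym-cond" in rendered

    def test_boundary_markers_excluded(self, excerpt_events, excerpt_timeline, schema):
        contextualized = insert_context(excerpt_events, excerpt_timeline, schema)
        # show_circle at 24.750 carries Face-image's Offset: not "inside"
        closing = serialize(contextualized[3].hed, "short")
        assert "(Event-context" not in closing or "Def/Face-image" not in closing.split(
            "(Event-context"
        )[1]
        # show_face_initial at 23.870 opens Face-image: not inside either
        opening = serialize(contextualized[1].hed, "short")
        assert "Event-context, Def/Face-image" not in opening

    def test_event_outside_any_process_unchanged(self, schema):
        events = [
            _event(1.0, "(Def/Cross-only, Onset)", schema),
            _event(2.0, "(Def/Cross-only, Offset)", schema),
            _event(3.0, "Agent-action", schema),
        ]
        timeline = resolve_processes(events)
        contextualized = insert_context(events, timeline, schema)
        assert contextualized[2] is events[2]

    def test_removal_recovers_original(self, excerpt_events, excerpt_timeline, schema):
        contextualized = insert_context(excerpt_events, excerpt_timeline, schema)
        for before, after in zip(excerpt_events, contextualized):
            stripped = HedString(
                [
                    item
                    for item in after.hed.items
                    if not (
                        hasattr(item, "tags")
                        and any(t.name == "Event-context" for t in item.tags())
                    )
                ]
            )
            assert stripped == before.hed

    def test_process_boundaries_unchanged(self, excerpt_events, excerpt_timeline, schema):
        before = [
            (p.definition_name, p.onset_time, p.offset_time)
            for p in excerpt_timeline.processes
        ]
        insert_context(excerpt_events, excerpt_timeline, schema)
        after = [
            (p.definition_name, p.onset_time, p.offset_time)
            for p in excerpt_timeline.processes
        ]
        assert before == after


def _oracle(events):
    """Per-definition left-to-right pairing sweep, O(n*m)."""
    names = set()
    for event in events:
        for group in event.hed.groups():
            for tag in group.tags():
                if tag.name == "Def" and tag.value:
                    names.add(tag.value.split("/")[0])
    intervals, issues = [], 0
    last_time = events[-1].onset if events else None
    for name in names:
        markers = []
        for event in events:
            for group in event.hed.groups():
                tag_names = [t.name for t in group.tags()]
                values = [t.value for t in group.tags() if t.name == "Def"]
                if name not in [v.split("/")[0] for v in values if v]:
                    continue
                if "Onset" in tag_names:
                    markers.append((event.onset, "on"))
                elif "Offset" in tag_names:
                    markers.append((event.onset, "off"))
        open_t = None
        for t, kind in markers:
            if kind == "on":
                if open_t is not None:
                    intervals.append((name, open_t, t))
                open_t = t
            else:
                if open_t is None:
                    issues += 1
                else:
                    intervals.append((name, open_t, t))
                    open_t = None
        if open_t is not None:
            intervals.append((name, open_t, last_time))
    return sorted(intervals), issues


@pytest.mark.parametrize("seed", range(8))
def test_resolver_matches_interval_sweep_oracle(schema, seed):
    rng = np.random.default_rng(seed)
    n_defs = int(rng.integers(1, 10))
    names = [f"Proc-{i}" for i in range(n_defs)]
    events = []
    t = 0.0
    for _ in range(int(rng.integers(2, 200))):
        t += float(rng.uniform(0.01, 1.0))
        name = names[int(rng.integers(0, n_defs))]
        kind = "Onset" if rng.random() < 0.6 else "Offset"
        events.append(_event(round(t, 3), f"(Def/{name}, {kind})", schema))
    timeline = resolve_processes(events)
    got = sorted(
        (p.definition_name, p.onset_time, p.offset_time) for p in timeline.processes
    )
    expected, expected_issues = _oracle(events)
    assert got == expected
    assert len(timeline.issues) == expected_issues
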