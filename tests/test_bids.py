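import json

import pandas as pd
import pytest

from hedlite.bids import (
    NA,
    EventTable,
    assemble,
    assemble_events,
    gather_sidecars,
    read_events_tsv,
    sidecar_from_dict,
    validate_dataset,
    write_events_tsv,
)
from hedlite.errors import FormatError
from hedlite.resources import wh_sidecar_dict
from hedlite.simulate import SessionSpec, generate_dataset
from hedlite.strings import parse_hed_string

# frozen reconstruction of the assembled annotation for the show_face row
# at onset 26.940 (famous face, immediate repeat, lag 1, file f032.bmp)
EXPECTED_SHOW_FACE = (
    "Sensory-event, (Def/Face-image, Onset), (Def/Blink-inhibition, Onset), "
    "(Def/Cross-only, Offset), Def/Famous-face-cond, Def/Immediate-repeat-cond, "
    "(Item-interval/1), (Image, Pathname/f032.bmp)"
)


class TestReadEvents:
    def test_excerpt_shape(self, excerpt):
        assert len(excerpt) == 8
        assert excerpt.columns == [
            "onset", "duration", "sample", "event_type", "face_type",
            "rep_status", "rep_lag", "value", "stim_file",
        ]
        assert excerpt.onsets[0] == pytest.approx(0.400)
        assert excerpt.issues == []

    def test_na_kept_as_written(self, excerpt):
        first = next(excerpt.rows())
        assert first["duration"] == NA
        assert first["stim_file"] == NA

    def test_missing_onset_column(self, tmp_path):
        path = tmp_path / "bad_events.tsv"
        path.write_text("duration\tevent_type\n1\tx\n")
        with pytest.raises(FormatError):
            read_events_tsv(path)

    def test_missing_duration_column(self, tmp_path):
        path = tmp_path / "bad_events.tsv"
        path.write_text("onset\tevent_type\n1\tx\n")
        with pytest.raises(FormatError):
            read_events_tsv(path)

    def test_non_monotone_onsets_flagged(self, tmp_path):
        path = tmp_path / "odd_events.tsv"
        path.write_text("onset\tduration\n2.0\tn/a\n1.0\tn/a\n")
        table = read_events_tsv(path)
        assert [i.code for i in table.issues] == ["non-monotone-onsets"]


class TestSidecar:
    def test_classification(self, sidecar):
        kinds = {k: v.kind for k, v in sidecar.column_annotations.items()}
        assert kinds == {
            "event_type": "categorical",
            "face_type": "categorical",
            "rep_status": "categorical",
            "rep_lag": "value",
            "stim_file": "value",
        }

    def test_rep_status_levels(self, sidecar):
        levels = set(sidecar.column_annotations["rep_status"].categorical_map)
        assert levels == {"first_show", "immediate_repeat", "delayed_repeat"}

    def test_unannotated_columns_ignored(self, sidecar):
        assert {"onset", "duration", "sample", "value", "trial"} <= sidecar.unannotated
        for key in sidecar.unannotated:
            assert key not in sidecar.column_annotations

    def test_value_template_without_hash_flagged(self, schema):
        sidecar = sidecar_from_dict({"col": {"HED": "Circle"}}, schema)
        assert [i.code for i in sidecar.issues] == ["placeholder-arity"]
        assert "col" not in sidecar.column_annotations

    def test_definitions_harvested_from_dedicated_keys(self, sidecar):
        assert len(sidecar.definition_strings) == 4  # one per hed_defs_* key
        assert "hed_defs_conditions" not in sidecar.column_annotations

    def test_bad_hed_entry_type(self, schema):
        sidecar = sidecar_from_dict({"col": {"HED": 17}}, schema)
        assert [i.code for i in sidecar.issues] == ["sidecar-format"]


class TestInheritance:
    def _write_tree(self, root, override=False):
        (root / "sub-01").mkdir(parents=True)
        with open(root / "task-FacePerception_events.json", "w") as fh:
            json.dump(wh_sidecar_dict(), fh)
        events = root / "sub-01" / "sub-01_task-FacePerception_run-01_events.tsv"
        events.write_text("onset\tduration\trep_status\n1.0\tn/a\tfirst_show\n")
        if override:
            with open(root / "sub-01" / "override_events.json", "w") as fh:
                json.dump(
                    {"rep_status": {"HED": {"first_show": "Def/First-show-cond, Sensory-event"}}},
                    fh,
                )
        return events

    def test_top_level_applies(self, tmp_path, schema):
        events = self._write_tree(tmp_path)
        sidecar = gather_sidecars(tmp_path, events, schema)
        assert "rep_status" in sidecar.column_annotations
        assert sidecar.issues == []

    def test_deeper_sidecar_wins(self, tmp_path, schema):
        events = self._write_tree(tmp_path, override=True)
        sidecar = gather_sidecars(tmp_path, events, schema)
        annotation = sidecar.column_annotations["rep_status"].categorical_map
        assert annotation["first_show"] == parse_hed_string(
            "Def/First-show-cond, Sensory-event", schema
        )

    def test_no_sidecars_flagged(self, tmp_path, schema):
        events = tmp_path / "sub-01" / "run_events.tsv"
        events.parent.mkdir(parents=True)
        events.write_text("onset\tduration\n1.0\tn/a\n")
        sidecar = gather_sidecars(tmp_path, events, schema)
        assert not sidecar.column_annotations
        assert [i.code for i in sidecar.issues] == ["no-sidecar"]


class TestAssemble:
    def test_worked_example_row(self, excerpt, sidecar, schema):
        rows = list(excerpt.rows())
        event = assemble(rows[5], sidecar)
        assert event.onset == pytest.approx(26.940)
        assert event.hed == parse_hed_string(EXPECTED_SHOW_FACE, schema)
        assert set(event.contributions) == {
            "event_type", "face_type", "rep_status", "rep_lag", "stim_file",
        }

    def test_press_row_single_fragment(self, excerpt, sidecar, schema):
        rows = list(excerpt.rows())
        event = assemble(rows[2], sidecar)  # left_press at 24.081
        assert set(event.contributions) == {"event_type"}
        assert event.hed == parse_hed_string(
            "Agent-action, Def/Press-left-finger", schema
        )

    def test_unannotated_table_row(self, schema):
        sidecar = sidecar_from_dict({}, schema)
        event = assemble({"onset": "1.0", "duration": "n/a", "x": "y"}, sidecar)
        assert event.hed.is_empty()

    def test_missing_level_flagged_but_continues(self, excerpt, sidecar):
        row = dict(list(excerpt.rows())[5])
        row["rep_status"] = "totally_new_level"
        event = assemble(row, sidecar)
        assert [i.code for i in event.issues] == ["missing-level"]
        assert "face_type" in event.contributions  # assembly continued

    def test_numeric_substitution_verbatim(self, sidecar):
        row = {
            "onset": "1.0", "duration": "n/a", "rep_lag": "1.0",
        }
        event = assemble(row, sidecar)
        (group,) = event.hed.groups()
        assert group.tags()[0].value == "1.0"  # not reformatted to "1"

    def test_row_permutation_permutes_events(self, excerpt, sidecar):
        events = assemble_events(excerpt, sidecar)
        reversed_df = excerpt.df.iloc[::-1].reset_index(drop=True)
        reversed_events = assemble_events(
            EventTable(reversed_df), sidecar
        )
        assert [e.hed for e in reversed_events] == [e.hed for e in events[::-1]]

    def test_assembled_strings_reparse(self, excerpt_events, schema):
        from hedlite.strings import serialize

        for event in excerpt_events:
            rendered = serialize(event.hed, "short")
            assert parse_hed_string(rendered, schema) == event.hed


class TestWrite:
    def test_round_trip_identity(self, tmp_path, excerpt):
        out = tmp_path / "copy_events.tsv"
        write_events_tsv(excerpt, out)
        again = read_events_tsv(out)
        assert again.df.equals(excerpt.df)
        write_events_tsv(again, tmp_path / "copy2_events.tsv")
        assert (tmp_path / "copy2_events.tsv").read_bytes() == out.read_bytes()

    def test_missing_written_as_na(self, tmp_path):
        df = pd.DataFrame({"onset": ["1.0"], "duration": [NA], "x": [NA]})
        write_events_tsv(EventTable(df), tmp_path / "na_events.tsv")
        text = (tmp_path / "na_events.tsv").read_text()
        assert text == "onset\tduration\tx\n1.0\tn/a\tn/a\n"

    def test_empty_table(self, tmp_path):
        df = pd.DataFrame({"onset": [], "duration": []})
        write_events_tsv(EventTable(df), tmp_path / "empty_events.tsv")
        assert (tmp_path / "empty_events.tsv").read_text() == "onset\tduration\n"


class TestValidateDataset:
    @pytest.fixture()
    def dataset(self, tmp_path):
        return generate_dataset(tmp_path / "ds", 1, SessionSpec(seed=7))

    def test_clean_by_construction(self, dataset, schema):
        assert validate_dataset(dataset, schema) == []

    def test_deleted_level_detected(self, dataset, schema):
        sidecar_path = dataset / "task-FacePerception_events.json"
        data = json.loads(sidecar_path.read_text())
        del data["rep_status"]["HED"]["first_show"]
        sidecar_path.write_text(json.dumps(data))
        issues = validate_dataset(dataset, schema)
        assert issues
        assert all(i.code == "missing-level" for i in issues)

    def test_misspelled_tag_detected(self, dataset, schema):
        sidecar_path = dataset / "task-FacePerception_events.json"
        data = json.loads(sidecar_path.read_text())
        data["face_type"]["HED"]["famous_face"] = "Def/Famous-face-cond, Sensry-event"
        sidecar_path.write_text(json.dumps(data))
        issues = validate_dataset(dataset, schema)
        assert any(i.code == "annotation-parse" for i in issues)
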