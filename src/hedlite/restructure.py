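"""Unfolding by-trial event tables into one-marker-per-line tables.

A by-trial table stores one row per trial, with other trial events encoded
as durations or delays relative to a trial anchor.  The mapping from those
columns back to real event markers is supplied explicitly by the user as a
:class:`TrialMappingSpec` — the reference point of each stored delay is
part of the spec, never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

from .bids import NA, EventTable
from .errors import ConfigError, Issue

SIGN_AFTER = "after"
SIGN_BEFORE = "before"
ROLE_ONSET_DELTA = "onset-delta"
ROLE_DURATION = "duration-from-anchor"

TRIAL_COLUMN = "trial"
EVENT_TYPE_COLUMN = "event_type"


@dataclass
class DerivedEvent:
    """One event marker reconstructed from each trial row.

    ``source`` names the column holding the stored delay/duration; when it
    is None the event is emitted at the anchor time itself.  ``sign``
    states whether the stored (positive) value places the event before or
    after the anchor.  ``role`` records what the stored number meant.
    """

    name: str
    source: str | None = None
    sign: str = SIGN_AFTER
    role: str = ROLE_ONSET_DELTA


@dataclass
class TrialMappingSpec:
    anchor_column: str
    derived_events: list[DerivedEvent]
    pass_through: list[str] = field(default_factory=list)

    def validate(self, columns: list[str]) -> None:
        if self.anchor_column not in columns:
            raise ConfigError(f"anchor column {self.anchor_column!r} not in table")
        for derived in self.derived_events:
            if derived.source is not None and derived.source not in columns:
                raise ConfigError(
                    f"derived event {derived.name!r}: source column "
                    f"{derived.source!r} not in table"
                )
            if derived.sign not in (SIGN_AFTER, SIGN_BEFORE):
                raise ConfigError(f"bad sign {derived.sign!r}")
            if derived.role not in (ROLE_ONSET_DELTA, ROLE_DURATION):
                raise ConfigError(f"bad role {derived.role!r}")
        for column in self.pass_through:
            if column not in columns:
                raise ConfigError(f"pass-through column {column!r} not in table")


def load_trial_spec(source) -> TrialMappingSpec:
    """Load a :class:`TrialMappingSpec` from a YAML file path or stream."""
    if hasattr(source, "read"):
        data = yaml.safe_load(source.read())
    else:
        with open(source, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    try:
        derived = [
            DerivedEvent(
                name=entry["name"],
                source=entry.get("source"),
                sign=entry.get("sign", SIGN_AFTER),
                role=entry.get("role", ROLE_ONSET_DELTA),
            )
            for entry in data["derived_events"]
        ]
        return TrialMappingSpec(
            anchor_column=data["anchor_column"],
            derived_events=derived,
            pass_through=list(data.get("pass_through", [])),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed trial mapping spec: {exc}") from exc


def _format_time(t: float) -> str:
    return f"{t:.3f}".rstrip("0").rstrip(".") if "." in f"{t:.3f}" else f"{t:.3f}"


def explode_trials(
    table: EventTable, spec: TrialMappingSpec
) -> tuple[EventTable, list[Issue]]:
    """Emit one row per derived event, sorted by onset.

    Missing (``n/a``) source cells skip that derived event.  Negative
    resulting onsets are allowed but flagged.
    """
    spec.validate(table.columns)
    issues: list[Issue] = []
    records = []
    for trial_index, row in enumerate(table.rows()):
        anchor = float(row[spec.anchor_column])
        for derived in spec.derived_events:
            if derived.source is None:
                t = anchor
            else:
                cell = row[derived.source]
                if cell == NA or cell == "":
                    continue
                value = float(cell)
                t = anchor - value if derived.sign == SIGN_BEFORE else anchor + value
            if t < 0:
                issues.append(
                    Issue(
                        code="negative-onset",
                        message=(
                            f"trial {trial_index}: derived event "
                            f"{derived.name!r} lands at t={t:.3f} < 0"
                        ),
                        line=trial_index + 1,
                    )
                )
            record = {
                "onset": _format_time(t),
                "duration": NA,
                EVENT_TYPE_COLUMN: derived.name,
                TRIAL_COLUMN: str(trial_index + 1),
            }
            for column in spec.pass_through:
                record[column] = row[column]
            records.append(record)
    columns = ["onset", "duration", EVENT_TYPE_COLUMN, TRIAL_COLUMN] + list(
        spec.pass_through
    )
    df = pd.DataFrame(records, columns=columns)
    if len(df):
        df = df.iloc[
            df["onset"].astype(float).argsort(kind="stable")
        ].reset_index(drop=True)
    return EventTable(df), issues


def fold_trials(table: EventTable, spec: TrialMappingSpec) -> EventTable:
    """Inverse of :func:`explode_trials` (exact when no cells were missing)."""
    by_trial: dict[int, dict[str, dict]] = {}
    for row in table.rows():
        trial = int(row[TRIAL_COLUMN])
        by_trial.setdefault(trial, {})[row[EVENT_TYPE_COLUMN]] = row
    records = []
    for trial in sorted(by_trial):
        rows = by_trial[trial]
        anchor_event = next(d for d in spec.derived_events if d.source is None)
        anchor = float(rows[anchor_event.name]["onset"])
        record: dict[str, str] = {spec.anchor_column: _format_time(anchor)}
        for derived in spec.derived_events:
            if derived.source is None:
                continue
            if derived.name not in rows:
                record[derived.source] = NA
                continue
            t = float(rows[derived.name]["onset"])
            value = anchor - t if derived.sign == SIGN_BEFORE else t - anchor
            record[derived.source] = _format_time(value)
        some_row = rows[anchor_event.name]
        for column in spec.pass_through:
            record[column] = some_row[column]
        records.append(record)
    columns = [spec.anchor_column] + [
        d.source for d in spec.derived_events if d.source is not None
    ] + list(spec.pass_through)
    df = pd.DataFrame(records, columns=columns)
    if "duration" not in df.columns:
        df["duration"] = NA
    if "onset" not in df.columns:
        df = df.rename(columns={spec.anchor_column: "onset"})
    return EventTable(df)
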