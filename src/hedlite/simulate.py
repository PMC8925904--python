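"""Synthetic face-perception sessions in the W-H style.

Generates BIDS-like runs of event markers (setup meta-event, cross / face /
circle presentations, key presses) that satisfy the W-H design constraints
for every seed: 6 runs per session, 140-150 face presentations per run,
every face identity shown exactly twice in the session, half of the
repeats immediate (lag 1) and half delayed with lag uniform in 5-15
intervening presentations, and an exactly balanced female/male identity
inventory.  Timing distributions are configurable defaults, not claims
about the original recordings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources as importlib_resources
from pathlib import Path

import numpy as np
import pandas as pd

from .bids import NA, EventTable, Sidecar, sidecar_from_dict, write_events_tsv
from .errors import ConfigError
from .schema import HedSchema

KEY_LEFT = "left_sym"
KEY_RIGHT = "right_sym"

FACE_TYPES = ("famous_face", "unfamiliar_face", "scrambled_face")
_STIM_PREFIX = {"famous_face": "f", "unfamiliar_face": "u", "scrambled_face": "s"}
# trigger codes per (face_type, rep_status), loosely modeled on the original
# non-orthogonal encoding
_TRIGGERS = {
    ("famous_face", "first_show"): "5",
    ("famous_face", "immediate_repeat"): "6",
    ("famous_face", "delayed_repeat"): "7",
    ("unfamiliar_face", "first_show"): "13",
    ("unfamiliar_face", "immediate_repeat"): "14",
    ("unfamiliar_face", "delayed_repeat"): "15",
    ("scrambled_face", "first_show"): "17",
    ("scrambled_face", "immediate_repeat"): "18",
    ("scrambled_face", "delayed_repeat"): "19",
}

EVENT_COLUMNS = [
    "onset",
    "duration",
    "sample",
    "event_type",
    "face_type",
    "rep_status",
    "rep_lag",
    "value",
    "stim_file",
]


@dataclass
class SessionSpec:
    """Configuration of one synthetic recording session."""

    n_runs: int = 6
    presentations_per_run: tuple[int, int] = (140, 150)
    face_type_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    immediate_fraction: float = 0.5
    delayed_lag_range: tuple[int, int] = (5, 15)
    female_fraction: float = 0.5
    key_assignment: str = KEY_LEFT
    cross_duration: tuple[float, float] = (0.4, 0.6)
    face_duration: tuple[float, float] = (0.8, 1.0)
    response_latency: tuple[float, float] = (0.2, 2.5)
    circle_duration: tuple[float, float] = (1.2, 1.8)
    sampling_rate: float = 1100.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")
        lo, hi = self.presentations_per_run
        if not (2 <= lo <= hi):
            raise ConfigError("presentations_per_run range is empty or too small")
        if abs(sum(self.face_type_probs) - 1.0) > 1e-9:
            raise ConfigError("face_type_probs must sum to 1")
        if not 0.0 <= self.immediate_fraction <= 1.0:
            raise ConfigError("immediate_fraction must be in [0, 1]")
        llo, lhi = self.delayed_lag_range
        if not (1 <= llo <= lhi):
            raise ConfigError("delayed_lag_range is empty")
        if lhi >= lo:
            raise ConfigError(
                f"delayed lag range {self.delayed_lag_range} exceeds the "
                f"shortest run length {lo}"
            )
        if self.key_assignment not in (KEY_LEFT, KEY_RIGHT):
            raise ConfigError(f"bad key_assignment {self.key_assignment!r}")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")


@dataclass
class FaceIdentity:
    stim_file: str
    face_type: str
    sex: str  # "female" | "male"


@dataclass
class SessionData:
    runs: list[EventTable]
    sidecar: Sidecar
    inventory: list[FaceIdentity] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Presentation-order scheduling


def _schedule_run(
    n_faces: int, n_immediate: int, lag_range: tuple[int, int], rng: np.random.Generator
) -> list[tuple[int, str, int | None]]:
    """Order face presentations for one run.

    Returns a list over presentation slots of (identity-index, rep_status,
    lag).  Each identity occupies exactly two slots; immediate pairs are
    adjacent, delayed pairs are separated by a lag drawn from *lag_range*.
    Uses randomized greedy placement with whole-run retries.
    """
    length = 2 * n_faces
    lags = list(range(lag_range[0], lag_range[1] + 1))
    for _ in range(1000):
        remaining = {"immediate": n_immediate, "delayed": n_faces - n_immediate}
        slots: list[tuple[int, str, int | None] | None] = [None] * length
        identity = 0
        ok = True
        for pos in range(length):
            if slots[pos] is not None:
                continue
            immediate_ok = (
                remaining["immediate"] > 0
                and pos + 1 < length
                and slots[pos + 1] is None
            )
            feasible_lags = (
                [lag for lag in lags if pos + lag < length and slots[pos + lag] is None]
                if remaining["delayed"] > 0
                else []
            )
            if immediate_ok and feasible_lags:
                weights = np.array(
                    [remaining["immediate"], remaining["delayed"]], dtype=float
                )
                kind = ("immediate", "delayed")[
                    int(rng.choice(2, p=weights / weights.sum()))
                ]
            elif immediate_ok:
                kind = "immediate"
            elif feasible_lags:
                kind = "delayed"
            else:
                ok = False
                break
            slots[pos] = (identity, "first_show", None)
            if kind == "immediate":
                slots[pos + 1] = (identity, "immediate_repeat", 1)
            else:
                lag = int(rng.choice(feasible_lags))
                slots[pos + lag] = (identity, "delayed_repeat", lag)
            remaining[kind] -= 1
            identity += 1
        if ok and identity == n_faces:
            return slots  # type: ignore[return-value]
    raise ConfigError(
        f"could not schedule {n_faces} face pairs with lag range {lag_range}"
    )


# ---------------------------------------------------------------------------
# Session generation


def _run_face_counts(spec: SessionSpec, rng: np.random.Generator) -> list[int]:
    lo, hi = spec.presentations_per_run
    n_lo, n_hi = (lo + 1) // 2, hi // 2
    counts = [int(rng.integers(n_lo, n_hi + 1)) for _ in range(spec.n_runs)]
    # nudge the total even so the identity inventory can be split exactly
    if sum(counts) % 2:
        if counts[-1] + 1 <= n_hi:
            counts[-1] += 1
        else:
            counts[-1] -= 1
    return counts


def _build_inventory(
    counts: list[int], spec: SessionSpec, rng: np.random.Generator
) -> list[FaceIdentity]:
    total = sum(counts)
    face_types = [
        FACE_TYPES[i]
        for i in rng.choice(len(FACE_TYPES), size=total, p=list(spec.face_type_probs))
    ]
    n_female = round(total * spec.female_fraction)
    sexes = ["female"] * n_female + ["male"] * (total - n_female)
    rng.shuffle(sexes)
    per_type_counter: dict[str, int] = {}
    inventory = []
    for face_type, sex in zip(face_types, sexes):
        per_type_counter[face_type] = per_type_counter.get(face_type, 0) + 1
        stim_file = f"{_STIM_PREFIX[face_type]}{per_type_counter[face_type]:03d}.bmp"
        inventory.append(FaceIdentity(stim_file=stim_file, face_type=face_type, sex=sex))
    return inventory


def _generate_run(
    run_faces: list[FaceIdentity],
    spec: SessionSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_faces = len(run_faces)
    n_immediate = int(n_faces * spec.immediate_fraction)
    slots = _schedule_run(n_faces, n_immediate, spec.delayed_lag_range, rng)

    setup_type = "setup_left_sym" if spec.key_assignment == KEY_LEFT else "setup_right_sym"
    setup_value = "2" if spec.key_assignment == KEY_LEFT else "3"
    rows: list[dict[str, str]] = []

    def emit(t, event_type, face_type=NA, rep_status=NA, rep_lag=NA, value=NA, stim=NA):
        rows.append(
            {
                "onset": t,
                "duration": NA,
                "sample": "",
                "event_type": event_type,
                "face_type": face_type,
                "rep_status": rep_status,
                "rep_lag": rep_lag,
                "value": value,
                "stim_file": stim,
            }
        )

    emit(0.0, setup_type, value=setup_value)
    t = 0.5
    for i, (identity_index, rep_status, lag) in enumerate(slots):
        face = run_faces[identity_index]
        if i == 0:
            face_onset = t
            face_event = "show_face_initial"
        else:
            cross_onset = t
            emit(cross_onset, "show_cross", value="1", stim="cross.bmp")
            face_onset = cross_onset + rng.uniform(*spec.cross_duration)
            face_event = "show_face"
        emit(
            face_onset,
            face_event,
            face_type=face.face_type,
            rep_status=rep_status,
            rep_lag=NA if lag is None else str(lag),
            value=_TRIGGERS[(face.face_type, rep_status)],
            stim=face.stim_file,
        )
        press_onset = face_onset + rng.uniform(*spec.response_latency)
        press_side = "left_press" if rng.random() < 0.5 else "right_press"
        emit(
            press_onset,
            press_side,
            value="256" if press_side == "left_press" else "4096",
        )
        circle_onset = face_onset + rng.uniform(*spec.face_duration)
        emit(circle_onset, "show_circle", value="0", stim="circle.bmp")
        t = circle_onset + rng.uniform(*spec.circle_duration)

    rows.sort(key=lambda r: r["onset"])
    # quantize onsets, enforce strict monotonicity, derive the sample column
    tick = 1.0 / spec.sampling_rate
    prev = -1.0
    for row in rows:
        onset = round(float(row["onset"]), 4)
        if onset <= prev:
            onset = round(prev + tick, 4)
        prev = onset
        row["onset"] = f"{onset:.4f}"
        row["sample"] = str(int(round(onset * spec.sampling_rate)))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def load_wh_sidecar_dict() -> dict:
    """The packaged face-perception sidecar as a raw dictionary."""
    ref = importlib_resources.files("hedlite.data") / "task-FacePerception_events.json"
    return json.loads(ref.read_text(encoding="utf-8"))


def generate_session(spec: SessionSpec, schema: HedSchema | None = None) -> SessionData:
    """Generate one session: per-run event tables plus the packaged sidecar."""
    spec.validate()
    if schema is None:
        from .resources import load_mini_schema

        schema = load_mini_schema()
    rng = np.random.default_rng(spec.seed)
    counts = _run_face_counts(spec, rng)
    inventory = _build_inventory(counts, spec, rng)
    runs = []
    cursor = 0
    for n_faces in counts:
        run_faces = inventory[cursor : cursor + n_faces]
        cursor += n_faces
        runs.append(EventTable(_generate_run(run_faces, spec, rng)))
    sidecar = sidecar_from_dict(load_wh_sidecar_dict(), schema)
    return SessionData(runs=runs, sidecar=sidecar, inventory=inventory)


def generate_dataset(
    out_dir,
    n_participants: int,
    spec: SessionSpec | None = None,
    schema: HedSchema | None = None,
) -> Path:
    """Write a BIDS-like tree of synthetic sessions.

    Key assignment alternates across participants (exact counterbalance for
    even participant counts); each participant gets a derived seed.
    """
    if n_participants < 1:
        raise ConfigError("n_participants must be >= 1")
    spec = spec or SessionSpec()
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    with open(root / "task-FacePerception_events.json", "w", encoding="utf-8") as fh:
        json.dump(load_wh_sidecar_dict(), fh, indent=4)
        fh.write("\n")
    for p in range(1, n_participants + 1):
        assignment = KEY_LEFT if p % 2 == 1 else KEY_RIGHT
        participant_spec = replace(
            spec, key_assignment=assignment, seed=spec.seed * 100003 + p
        )
        session = generate_session(participant_spec, schema=schema)
        sub = f"sub-{p:02d}"
        sub_dir = root / sub
        sub_dir.mkdir(exist_ok=True)
        for r, run in enumerate(session.runs, start=1):
            write_events_tsv(
                run, sub_dir / f"{sub}_task-FacePerception_run-{r:02d}_events.tsv"
            )
    return root
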