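"""Loaders for the packaged fixtures.

The package ships a mini vocabulary schema, the reconstructed
face-perception sidecar, the worked-example MEEG events excerpt, a
by-trial fMRI excerpt, and the trial-mapping spec used to unfold it.
"""

from __future__ import annotations

import io
import json
from importlib import resources as importlib_resources

from .bids import EventTable, Sidecar, sidecar_from_dict
from .restructure import TrialMappingSpec, load_trial_spec
from .schema import HedSchema, parse_schema

_DATA = "hedlite.data"


def _read_text(name: str) -> str:
    return (importlib_resources.files(_DATA) / name).read_text(encoding="utf-8")


def mini_schema_text() -> str:
    return _read_text("mini_schema.txt")


def load_mini_schema() -> HedSchema:
    """Parse the packaged mini vocabulary schema (7 roots)."""
    return parse_schema(mini_schema_text())


def wh_sidecar_dict() -> dict:
    return json.loads(_read_text("task-FacePerception_events.json"))


def load_wh_sidecar(schema: HedSchema | None = None) -> Sidecar:
    """The reconstructed face-perception sidecar, parsed."""
    schema = schema or load_mini_schema()
    return sidecar_from_dict(wh_sidecar_dict(), schema, source="packaged sidecar")


def load_wh_excerpt() -> EventTable:
    """The 8-row MEEG events excerpt used throughout the worked examples."""
    import pandas as pd

    df = pd.read_csv(
        io.StringIO(_read_text("wh_excerpt_events.tsv")),
        sep="\t",
        dtype=str,
        keep_default_na=False,
    )
    return EventTable(df, path="wh_excerpt_events.tsv")


def load_wh_fmri_by_trial() -> EventTable:
    """The 3-row by-trial fMRI excerpt (one row per trial)."""
    import pandas as pd

    df = pd.read_csv(
        io.StringIO(_read_text("wh_fmri_by_trial_events.tsv")),
        sep="\t",
        dtype=str,
        keep_default_na=False,
    )
    return EventTable(df, path="wh_fmri_by_trial_events.tsv")


def load_wh_fmri_trial_spec() -> TrialMappingSpec:
    """The mapping that unfolds the by-trial fMRI layout into markers."""
    return load_trial_spec(io.StringIO(_read_text("wh_fmri_trial_spec.yaml")))
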