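import pytest

from hedlite.bids import assemble_events
from hedlite.resources import (
    load_mini_schema,
    load_wh_excerpt,
    load_wh_fmri_by_trial,
    load_wh_fmri_trial_spec,
    load_wh_sidecar,
)
from hedlite.temporal import resolve_processes


@pytest.fixture(scope="session")
def schema():
    return load_mini_schema()


@pytest.fixture(scope="session")
def sidecar(schema):
    return load_wh_sidecar(schema)


@pytest.fixture(scope="session")
def registry(sidecar):
    return sidecar.registry()


@pytest.fixture(scope="session")
def excerpt():
    return load_wh_excerpt()


@pytest.fixture(scope="session")
def excerpt_events(excerpt, sidecar):
    return assemble_events(excerpt, sidecar)


@pytest.fixture(scope="session")
def excerpt_timeline(excerpt_events):
    return resolve_processes(excerpt_events)


@pytest.fixture(scope="session")
def fmri_table():
    return load_wh_fmri_by_trial()


@pytest.fixture(scope="session")
def fmri_spec():
    return load_wh_fmri_trial_spec()
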