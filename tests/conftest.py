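import numpy as np
import pytest

from vancosorb.dataset import EventRecord, StudyDataset
from vancosorb.params import reference_parameters


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


def make_subject_events(
    sid="S1",
    effluent=2000.0,
    loading=(1500.0, 750.0),
    maintenance=(46.0, 2.0, 120.0),  # rate, start, end
    sessions=(),  # (start, end) pairs
    obs=(),  # (time, dv) pairs
):
    """Hand-build a plausible subject timeline."""
    rate, t_on, t_off = maintenance
    events = [
        EventRecord(sid, 0.0, 2, effluent=effluent, cyto=0, filter_id=0),
        EventRecord(sid, 0.0, 1, amt=loading[0], rate=loading[1]),
        EventRecord(sid, t_on, 1, amt=rate * (t_off - t_on), rate=rate),
    ]
    for k, (s, e) in enumerate(sessions, start=1):
        events.append(EventRecord(sid, s, 2, cyto=1, filter_id=k))
        events.append(EventRecord(sid, e, 2, cyto=0, filter_id=0))
    for t, y in obs:
        events.append(EventRecord(sid, t, 0, dv=y))
    events.sort(key=lambda ev: (ev.time, ev.evid != 2))
    return events


@pytest.fixture
def subject_events():
    return make_subject_events


@pytest.fixture
def two_subject_dataset():
    """Tiny valid dataset with one CytoSorb session per subject."""
    subs = {}
    for sid, dvs in (("S1", (21.0, 17.5, 19.0)), ("S2", (24.0, 19.0, 22.0))):
        subs[sid] = make_subject_events(
            sid=sid,
            sessions=((30.0, 40.0),),
            obs=tuple(zip((24.0, 35.0, 60.0), dvs)),
        )
    return StudyDataset(subs)
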