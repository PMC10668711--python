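import numpy as np
import pytest

from farrowcam.annotation import EventLog
from farrowcam.geometry import PenGeometry, irregular_array


@pytest.fixture(scope="session")
def geometry() -> PenGeometry:
    return PenGeometry()


@pytest.fixture(scope="session")
def array16(geometry):
    """Small irregular array: cheap but free of grating-lobe ambiguity."""
    return irregular_array(geometry, n_mics=16)


def spot_log(items) -> EventLog:
    """[(t, zone)] or [(t, zone, x, y)] -> spot EventLog."""
    rec = []
    for it in items:
        t, z = it[0], it[1]
        x, y = (it[2], it[3]) if len(it) > 2 else (np.nan, np.nan)
        rec.append(
            {"time_s": t, "duration_s": 0.0, "stream": "spot", "label": "spot",
             "zone": z, "x_m": x, "y_m": y, "audible": False}
        )
    return EventLog.from_records(rec)


def audible_log(items) -> EventLog:
    """[(t, label)] or [(t, label, duration)] -> audible EventLog."""
    rec = []
    for it in items:
        t, l = it[0], it[1]
        d = it[2] if len(it) > 2 else 0.0
        rec.append(
            {"time_s": t, "duration_s": d, "stream": "audible", "label": l,
             "zone": "none", "x_m": np.nan, "y_m": np.nan, "audible": True}
        )
    return EventLog.from_records(rec)


def behaviour_log(items) -> EventLog:
    """[(start, end, state)] -> behaviour EventLog."""
    return EventLog.from_records(
        [
            {"time_s": a, "duration_s": b - a, "stream": "behaviour", "label": s,
             "zone": "none", "x_m": np.nan, "y_m": np.nan, "audible": False}
            for a, b, s in items
        ]
    )
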