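"""Reference-annotation data model and I/O.

Observer-style logs are kept in one shared CSV dialect with columns
``time_s,duration_s,stream,label,zone,x_m,y_m,audible`` where ``stream``
is ``audible`` (sounds heard on the security-camera recording),
``behaviour`` (ethogram states of the sow) or ``spot`` (acoustic-camera
detections).  Behaviours are state events with a duration; audible sounds
and spots are short or point events.

The correspondence tables shipped with the package encode which
(spot zone, reference label) pairs count as "roughly the right location":
one table for the sound-only comparison and a pair of tables for the
slow-replay study in which spots were compared against audible sounds and
against sow behaviours.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import PenGeometry, Zone

log = logging.getLogger(__name__)

LOG_COLUMNS = ["time_s", "duration_s", "stream", "label", "zone", "x_m", "y_m", "audible"]
STREAMS = {"audible", "behaviour", "spot"}

#: Ethogram states.  The three-category simplified ethogram used around
#: farrowing is {lying, sitting_standing, jute_rooting}; the slow-replay
#: study scored a finer set which we accept as well.
ETHOGRAM = {
    "lying",
    "sitting_standing",
    "jute_rooting",
    "eating",
    "standing",
    "moving_leg_lying",
    "lying_down",
}

#: States during which the sow is actively producing localisable sound
#: (used by the matcher: an inactive, silent sow is "silence", not a
#: reference event a spot could correspond to).
ACTIVE_STATES = {"jute_rooting", "eating", "standing", "moving_leg_lying", "sitting_standing"}

#: Phase-wise time budgets of sow behaviour (fractions of observed time)
#: four hours before farrowing, during farrowing, and four hours after.
BEHAVIOUR_BUDGETS = {
    "before": {"lying": 0.717, "sitting_standing": 0.033, "jute_rooting": 0.250},
    "during": {"lying": 0.935, "sitting_standing": 0.062, "jute_rooting": 0.003},
    "after": {"lying": 1.000, "sitting_standing": 0.000, "jute_rooting": 0.000},
}


# ---------------------------------------------------------------------------
# event logs
# ---------------------------------------------------------------------------
@dataclass
class EventLog:
    """A time-sorted table of annotation entries (wraps a DataFrame)."""

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.entries.copy()
        missing = [c for c in LOG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"event log is missing column(s): {', '.join(missing)}")
        df = df[LOG_COLUMNS]
        df["time_s"] = df["time_s"].astype(float)
        df["duration_s"] = df["duration_s"].astype(float)
        if (df["duration_s"] < 0).any():
            raise ValueError("durations must be >= 0")
        bad = set(df["stream"].unique()) - STREAMS
        if bad:
            raise ValueError(f"unknown stream value(s): {sorted(bad)}")
        df["zone"] = df["zone"].map(lambda z: str(Zone(z)) if not isinstance(z, Zone) else str(z))
        if not df["time_s"].is_monotonic_increasing:
            log.info("event log not time-sorted; sorting on load")
            df = df.sort_values("time_s", kind="stable")
        self.entries = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return self.entries.itertuples(index=False)

    def select(self, stream: str) -> "EventLog":
        return EventLog(self.entries[self.entries["stream"] == stream])

    @property
    def times(self) -> np.ndarray:
        return self.entries["time_s"].to_numpy()

    @property
    def span(self) -> tuple[float, float]:
        """(first start, last end) over all entries."""
        if len(self.entries) == 0:
            return (0.0, 0.0)
        t = self.entries["time_s"].to_numpy()
        d = self.entries["duration_s"].to_numpy()
        return (float(t.min()), float((t + d).max()))

    @classmethod
    def from_records(cls, records: list[dict]) -> "EventLog":
        if not records:
            return cls(pd.DataFrame(columns=LOG_COLUMNS))
        return cls(pd.DataFrame.from_records(records))

    @classmethod
    def empty(cls) -> "EventLog":
        return cls(pd.DataFrame(columns=LOG_COLUMNS))


def read_log(path: str | Path) -> EventLog:
    """Read an event log CSV; rejects malformed rows with their line number."""
    df = pd.read_csv(path, dtype={"stream": str, "label": str, "zone": str}, comment="#")
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            float(row.time_s), float(row.duration_s)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
    return EventLog(df)


def write_log(log_: EventLog, path: str | Path) -> None:
    df = log_.entries.copy()
    df["audible"] = df["audible"].astype(bool)
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# correspondence tables
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class CorrespondenceTable:
    """Set of (zone, reference label) pairs judged location-correct.

    The lookup is total over the labels the table knows: any (zone, label)
    with a known label resolves to correct/incorrect; unknown labels are
    rejected so silent typos cannot masquerade as "incorrect".
    """

    pairs: frozenset[tuple[str, str]]

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(lbl for _, lbl in self.pairs)

    @classmethod
    def from_pairs(cls, pairs) -> "CorrespondenceTable":
        return cls(frozenset((str(Zone(z)), str(l)) for z, l in pairs))


def is_location_correct(spot_zone: Zone | str, ref_label: str, table: CorrespondenceTable) -> bool:
    if ref_label not in table.labels:
        raise ValueError(
            f"unknown reference label {ref_label!r}; known: {sorted(table.labels)}"
        )
    return (str(Zone(spot_zone)), ref_label) in table.pairs


def load_table(name: str) -> CorrespondenceTable:
    """Load a packaged correspondence table.

    Names: ``field1_sound`` (sound-only study), ``field2_sound`` and
    ``field2_behaviour`` (slow-replay study).  Each CSV has columns
    ``zone,label``; users can load their own with :func:`read_table`.
    """
    ref = resources.files("farrowcam.data") / f"{name}.csv"
    with resources.as_file(ref) as p:
        return read_table(p)


def read_table(path: str | Path) -> CorrespondenceTable:
    # keep_default_na: "None" is a legitimate reference label, not a NaN
    df = pd.read_csv(path, keep_default_na=False)
    if not {"zone", "label"} <= set(df.columns):
        raise ValueError(f"{path}: correspondence table needs 'zone' and 'label' columns")
    return CorrespondenceTable.from_pairs(zip(df["zone"], df["label"]))


# ---------------------------------------------------------------------------
# behaviour time budgets
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class PhaseBudget:
    phase: str
    proportions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if self.proportions and abs(total - 1.0) > 1e-9:
            raise ValueError(f"phase {self.phase!r}: proportions sum to {total}, not 1")


def time_budget(log_: EventLog, phases) -> list[PhaseBudget]:
    """Per-phase time budget of behaviour states.

    ``phases`` is a farrowing timeline (``t_start``/``t_onset``/
    ``t_end_farrowing``/``t_stop``) or a list of ``(name, start, end)``.
    The behaviour entries must tile each phase without gaps or overlaps.
    """
    if hasattr(phases, "t_onset"):
        spans = [
            ("before", phases.t_start, phases.t_onset),
            ("during", phases.t_onset, phases.t_end_farrowing),
            ("after", phases.t_end_farrowing, phases.t_stop),
        ]
    else:
        spans = [(str(n), float(a), float(b)) for n, a, b in phases]

    beh = log_.select("behaviour").entries
    starts = beh["time_s"].to_numpy()
    ends = starts + beh["duration_s"].to_numpy()
    states = beh["label"].to_numpy()
    order = np.argsort(starts, kind="stable")
    starts, ends, states = starts[order], ends[order], states[order]

    eps = 1e-6
    out: list[PhaseBudget] = []
    for name, a, b in spans:
        if b - a <= eps:
            out.append(PhaseBudget(name, {}))
            continue
        sel = (ends > a + eps) & (starts < b - eps)
        s, e, st = starts[sel], ends[sel], states[sel]
        if len(s) == 0:
            raise ValueError(f"phase {name!r} [{a}, {b}] has no behaviour coverage")
        # coverage check: clipped intervals must tile [a, b]
        cs, ce = np.clip(s, a, b), np.clip(e, a, b)
        if cs[0] > a + eps or ce[-1] < b - eps or np.any(cs[1:] - ce[:-1] > eps):
            raise ValueError(f"behaviour entries leave a gap in phase {name!r}")
        if np.any(cs[1:] - ce[:-1] < -eps):
            raise ValueError(f"behaviour entries overlap in phase {name!r}")
        totals: dict[str, float] = {}
        for si, ei, sti in zip(cs, ce, st):
            totals[sti] = totals.get(sti, 0.0) + (ei - si)
        span = sum(totals.values())
        out.append(PhaseBudget(name, {k: v / span for k, v in sorted(totals.items())}))
    return out
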