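"""Farrowing-onset detection and progress monitoring from spot streams.

The behavioural signature exploited here: before farrowing the sow roots
and plays with the jute sack, producing a steady stream of sound spots at
the head of the crate; that activity stops almost completely when
farrowing starts, and newborn piglets produce sound spots in the area
behind the sow for some time after each birth.  Hence:

* onset    — the head-zone spot rate, measured over a sliding window,
  falls below ``rooting_rate_low`` after having exceeded
  ``rooting_rate_high``, and a cluster of rear-zone spots confirms that
  births are under way;
* progress — as long as new rear-zone spots keep appearing the farrowing
  is in progress; a gap of ``progress_timeout_s`` raises a "stalled"
  alert (the use case: warn the farmer of a stagnating birth process);
* end      — the last rear-zone spot followed by sustained inactivity
  (no head- or rear-zone spots for a full timeout) marks the end.

All thresholds are configuration, not measurements: the source study
proposes the monitoring principle without numeric criteria, and the low
rooting threshold acknowledges the ~0.3 % residual rooting observed
during farrowing.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .annotation import EventLog
from .geometry import Zone

#: spot zones treated as nest-building / head activity
HEAD_ZONES = {str(Zone.HEAD)}
#: spot zones in the area behind the sow
REAR_ZONES = {str(Zone.RUMP)}


@dataclass
class OnsetConfig:
    window_s: float = 600.0
    rooting_rate_high: float = 2.0  # events/min: sustained nest-building
    rooting_rate_low: float = 1.0  # events/min: cessation
    rear_cluster_min: int = 5
    progress_timeout_s: float = 1800.0
    scan_step_s: float = 30.0

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")
        if not (0 <= self.rooting_rate_low < self.rooting_rate_high):
            raise ValueError("need 0 <= rooting_rate_low < rooting_rate_high")
        if self.rear_cluster_min < 1 or self.progress_timeout_s <= 0:
            raise ValueError("rear_cluster_min >= 1 and progress_timeout_s > 0 required")


@dataclass
class FarrowingReport:
    t_onset_est: float | None = None
    t_end_est: float | None = None
    progress_intervals: list[tuple[float, float]] = field(default_factory=list)
    alerts: list[tuple[float, str]] = field(default_factory=list)

    def validate(self) -> None:
        if self.t_onset_est is not None and self.t_end_est is not None:
            if self.t_end_est < self.t_onset_est:
                raise ValueError("estimated end precedes estimated onset")
        if any(self.alerts[i][0] > self.alerts[i + 1][0] for i in range(len(self.alerts) - 1)):
            raise ValueError("alerts must be time-sorted")

    def to_json(self, path) -> None:
        doc = {
            "t_onset_est": self.t_onset_est,
            "t_end_est": self.t_end_est,
            "progress_intervals": self.progress_intervals,
            "alerts": [{"t": t, "kind": k} for t, k in self.alerts],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


def _zone_times(spots: EventLog, zones: set[str]) -> np.ndarray:
    df = spots.entries
    return df.loc[df["zone"].isin(zones), "time_s"].to_numpy()


def detect_onset(spots: EventLog, cfg: OnsetConfig | None = None) -> FarrowingReport:
    """Estimate farrowing onset from a zone-annotated spot log.

    Scans candidate times on a regular step; a candidate marks cessation
    when the trailing-window head-zone rate has dropped below the low
    threshold after having been above the high threshold, and is confirmed
    by >= ``rear_cluster_min`` rear-zone spots within one window of it.
    The onset estimate is the last head-zone spot preceding the confirmed
    cessation (the moment rooting actually stopped), or the start of its
    window when none is present.
    """
    cfg = cfg or OnsetConfig()
    head = _zone_times(spots, HEAD_ZONES)
    rear = _zone_times(spots, REAR_ZONES)
    report = FarrowingReport()
    if len(head) == 0:
        return report  # nest-building never observed: cessation undefined
    t0, t1 = spots.span
    w = cfg.window_s
    armed = False
    for t in np.arange(t0 + w, t1 + cfg.scan_step_s, cfg.scan_step_s):
        n = int(((head > t - w) & (head <= t)).sum())
        rate = n / (w / 60.0)
        if rate >= cfg.rooting_rate_high:
            armed = True
            continue
        if not armed or rate >= cfg.rooting_rate_low:
            continue
        n_rear = int(((rear > t - w) & (rear <= t + w)).sum())
        if n_rear < cfg.rear_cluster_min:
            continue
        in_win = head[(head > t - w) & (head <= t)]
        est = float(in_win.max()) if len(in_win) else float(t - w)
        report.t_onset_est = est
        report.alerts.append((float(t), "onset"))
        break
    report.validate()
    return report


def monitor_progress(
    spots: EventLog, report: FarrowingReport, cfg: OnsetConfig | None = None
) -> FarrowingReport:
    """Track the birth process after a detected onset.

    Rear-zone spots separated by less than the timeout form progress
    intervals; each longer gap before the end raises a "stalled" alert.
    The end estimate is the last rear-zone spot followed by a full timeout
    without rear- or head-zone activity."""
    cfg = cfg or OnsetConfig()
    if report.t_onset_est is None:
        raise ValueError("monitor_progress requires a detected onset")
    t_on = report.t_onset_est
    rear = _zone_times(spots, REAR_ZONES)
    rear = rear[rear >= t_on]
    head = _zone_times(spots, HEAD_ZONES)
    _, t1 = spots.span
    if len(rear) == 0:
        report.validate()
        return report

    intervals: list[tuple[float, float]] = []
    cur = [float(rear[0]), float(rear[0])]
    for t in rear[1:]:
        if t - cur[1] < cfg.progress_timeout_s:
            cur[1] = float(t)
        else:
            intervals.append(tuple(cur))
            report.alerts.append((cur[1] + cfg.progress_timeout_s, "stalled"))
            cur = [float(t), float(t)]
    intervals.append(tuple(cur))
    report.progress_intervals = intervals

    last = float(rear[-1])
    quiet_until = last + cfg.progress_timeout_s
    # sustained inactivity: no further rear spots (by construction) and head
    # activity staying below the cessation rate (occasional vocalisations of
    # the resting sow are not nest-building)
    head_after = int(((head > last) & (head <= quiet_until)).sum())
    head_allowed = cfg.rooting_rate_low * cfg.progress_timeout_s / 60.0
    if quiet_until <= t1 + cfg.progress_timeout_s and head_after < head_allowed:
        report.t_end_est = last
        report.alerts.append((quiet_until, "ended"))
    report.alerts.sort(key=lambda a: a[0])
    report.validate()
    return report
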