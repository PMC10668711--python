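"""Synthetic farrowing scenes: timelines, behaviour, sound events, audio.

The generator emulates the statistical structure the analysis pipeline
assumes about one crated sow around farrowing:

* a timeline ``t_start <= t_onset <= births ... <= t_end_farrowing <= t_stop``
  where ``t_onset`` is the moment nest-building (jute-sack play / rooting)
  ceases and farrowing begins;
* a behaviour script (lying / sitting-standing / jute-rooting) sampled as a
  semi-Markov chain whose stationary time budgets match the observed
  phase-wise budgets (71.7/3.3/25 % before farrowing, 93.5/6.2/0.3 % during,
  100/0/0 % after);
* timed, located, band-limited sound events: sow vocalisations at the head
  of the crate, rooting bursts at the head during rooting bouts, trough and
  fence contacts, neighbour-sow noise outside the pen, piglet births at the
  birth times in the rear of the crate, and piglet movement behind the sow
  after each birth.  Piglet births and piglet movement produce sound the
  acoustic camera can localise but are *inaudible* to the human observer;
* multichannel microphone signals: each event is a band-limited noise burst
  with raised-cosine onset/offset, propagated to every microphone along the
  direct path (delay = distance / c, spherical 1/r attenuation) plus white
  background noise.  The simulated recorder starts ``recording_lag_s`` late,
  reproducing the constant lag of the real spot stream that is corrected by
  adding the same amount to detected spot times.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .annotation import ACTIVE_STATES, BEHAVIOUR_BUDGETS, EventLog
from .geometry import SPEED_OF_SOUND, MicArray, PenGeometry, Zone, distances, zone_of

EVENT_LABELS = (
    "sow_vocal",
    "jute_rooting",
    "trough",
    "fence",
    "piglet_birth",
    "piglet_move",
    "neighbour",
    "background",
)

#: reference-label vocabulary used in the audible annotation log
AUDIBLE_LABELS = {
    "sow_vocal": "Sow in crate",
    "jute_rooting": "Sow in crate",
    "trough": "Trough",
    "fence": "Metal fence",
    "neighbour": "Neighbour sow",
    "piglet_birth": "Piglet",
    "piglet_move": "Piglet",
    "background": "Background",
}

_PHASES = ("before", "during", "after")


@dataclass(frozen=True)
class SoundEvent:
    """A timed, located, band-limited acoustic emission."""

    t: float
    duration: float
    position: tuple[float, float]
    center_freq: float
    bandwidth: float
    amplitude: float
    audible: bool
    label: str

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("event duration must be > 0")
        if self.amplitude < 0:
            raise ValueError("event amplitude must be >= 0")
        if self.label not in EVENT_LABELS:
            raise ValueError(f"unknown event label {self.label!r}")

    @property
    def end(self) -> float:
        return self.t + self.duration


@dataclass(frozen=True)
class FarrowingTimeline:
    t_start: float
    t_onset: float
    birth_times: tuple[float, ...]
    t_end_farrowing: float
    t_stop: float

    def __post_init__(self) -> None:
        bt = tuple(float(b) for b in self.birth_times)
        object.__setattr__(self, "birth_times", bt)
        seq = [self.t_start, self.t_onset, *bt, self.t_end_farrowing, self.t_stop]
        if any(b - a < -1e-9 for a, b in zip(seq, seq[1:])):
            raise ValueError("timeline must be ordered: start <= onset <= births <= end <= stop")
        if any(b2 <= b1 for b1, b2 in zip(bt, bt[1:])):
            raise ValueError("birth times must be strictly increasing")

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    def phase_of(self, t: float) -> str:
        if t < self.t_onset:
            return "before"
        if t < self.t_end_farrowing:
            return "during"
        return "after"


@dataclass(frozen=True)
class BehaviourScript:
    """Non-overlapping, contiguous behaviour intervals covering the scene."""

    intervals: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        iv = tuple((float(a), float(b), str(s)) for a, b, s in self.intervals)
        object.__setattr__(self, "intervals", iv)
        for (a0, b0, _), (a1, _, _) in zip(iv, iv[1:]):
            if abs(a1 - b0) > 1e-6:
                raise ValueError("behaviour intervals must be contiguous and non-overlapping")

    def state_at(self, t: float) -> str | None:
        for a, b, s in self.intervals:
            if a <= t < b:
                return s
        return None


def _default_rates() -> dict[str, dict[str, float]]:
    """Spontaneous event rates (events/min) per label and phase.

    ``jute_rooting`` is the rate *within* a rooting bout; ``piglet_move``
    the rate within the postnatal window following each birth.
    """
    return {
        "sow_vocal": {"before": 0.4, "during": 0.3, "after": 0.2},
        "trough": {"before": 0.3, "during": 0.05, "after": 0.1},
        "fence": {"before": 0.3, "during": 0.1, "after": 0.1},
        "neighbour": {"before": 0.5, "during": 0.5, "after": 0.5},
        "jute_rooting": {"before": 10.0, "during": 10.0, "after": 0.0},
        "piglet_move": {"before": 0.0, "during": 2.0, "after": 2.0},
    }


def _default_dwells() -> dict[str, dict[str, float]]:
    """Mean bout lengths (s) of behaviour states per phase: restless ~5-min
    lying bouts interleaved with ~1.5-min rooting bouts before farrowing,
    longer lying bouts once farrowing starts.  Bout lengths are
    gamma-distributed (shape ``DWELL_SHAPE``): behaviour bouts are far more
    regular than memoryless, and only the mean affects the stationary time
    budgets."""
    return {
        "before": {"lying": 300.0, "sitting_standing": 60.0, "jute_rooting": 90.0},
        "during": {"lying": 600.0, "sitting_standing": 120.0, "jute_rooting": 20.0},
        "after": {"lying": 600.0, "sitting_standing": 120.0, "jute_rooting": 20.0},
    }


#: gamma shape of behaviour bout lengths (CV = 1/sqrt(shape))
DWELL_SHAPE = 4.0


@dataclass
class SimConfig:
    """All knobs of the scene generator.  Defaults describe the full study
    condition: 4 h pre-farrowing, a litter of 12 born ~15 min apart, 4 h
    post-farrowing; amplitudes are linear source levels at 1 m."""

    seed: int = 0
    fs: float = 192_000.0
    # timeline
    pre_farrowing_s: float = 4 * 3600.0
    post_farrowing_s: float = 4 * 3600.0
    litter_size: int = 12
    first_birth_delay_s: float = 600.0
    birth_interval_mean_s: float = 900.0
    postnatal_tail_s: float = 600.0
    # behaviour
    behaviour_budgets: dict = field(default_factory=lambda: {p: dict(BEHAVIOUR_BUDGETS[p]) for p in _PHASES})
    dwell_means_s: dict = field(default_factory=_default_dwells)
    # events
    event_rates: dict = field(default_factory=_default_rates)
    event_duration_mean_s: float = 0.15
    event_duration_min_s: float = 0.06
    amp_sigma: float = 0.25
    amp_min: float = 0.4
    amp_max: float = 2.5
    birth_amplitude: float = 0.9
    audible_prob: float = 0.9
    audibility_threshold: float = 0.2
    # audio
    center_freq: float = 42_730.0
    bandwidth: float = 2_000.0
    snr_db: float = 26.0
    recording_lag_s: float = 1.5

    def validate(self) -> None:
        if self.litter_size < 0:
            raise ValueError("litter size must be >= 0")
        for name in ("pre_farrowing_s", "post_farrowing_s", "first_birth_delay_s",
                     "birth_interval_mean_s", "postnatal_tail_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for phase in _PHASES:
            budgets = self.behaviour_budgets[phase]
            total = sum(budgets.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"behaviour budgets for {phase!r} sum to {total}, not 1")
        if self.fs <= 2.0 * (self.center_freq + self.bandwidth / 2.0):
            raise ValueError("fs must exceed twice the highest simulated frequency")

    @property
    def noise_rms(self) -> float:
        """Per-channel background-noise RMS; snr_db is referenced to a
        unit-amplitude source at 1 m."""
        return 10.0 ** (-self.snr_db / 20.0)

    def rng(self, stage: int) -> np.random.Generator:
        """Independent, reproducible stream per pipeline stage."""
        return np.random.default_rng([int(self.seed) & 0x7FFFFFFF, int(stage)])

    @classmethod
    def demo_30min(cls, seed: int = 0, **overrides) -> "SimConfig":
        """A compressed ~30-min scene (10 min pre, 4 births, short post)
        used for end-to-end audio runs.  The sampling rate is 96 kHz —
        still beyond twice the analysis band's upper edge — to keep a
        half-hour, 64-channel render tractable."""
        base = dict(
            seed=seed,
            fs=96_000.0,
            pre_farrowing_s=600.0,
            post_farrowing_s=240.0,
            litter_size=4,
            first_birth_delay_s=120.0,
            birth_interval_mean_s=180.0,
            postnatal_tail_s=300.0,
        )
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# timeline / behaviour
# ---------------------------------------------------------------------------
def generate_timeline(cfg: SimConfig) -> FarrowingTimeline:
    cfg.validate()
    rng = cfg.rng(0)
    t_start = 0.0
    t_onset = t_start + cfg.pre_farrowing_s
    if cfg.litter_size == 0:
        births: tuple[float, ...] = ()
        t_end = t_onset
    else:
        gaps = rng.exponential(cfg.birth_interval_mean_s, size=cfg.litter_size - 1)
        first = t_onset + cfg.first_birth_delay_s * (0.5 + rng.random())
        births = tuple(first + np.concatenate([[0.0], np.cumsum(gaps)]))
        t_end = births[-1] + cfg.postnatal_tail_s
    return FarrowingTimeline(t_start, t_onset, births, t_end, t_end + cfg.post_farrowing_s)


def _sample_phase_intervals(rng, a: float, b: float, budgets: dict, dwells: dict):
    """Alternating rest/activity renewal sampling of behaviour states.

    Lying bouts alternate with active bouts (sitting/standing or rooting,
    drawn with probability ∝ budget/dwell); the mean lying bout is derived
    from the lying budget so that, by renewal-reward, the stationary time
    share of every state equals its budget whatever the bout-length
    distribution.  Bout lengths are gamma(DWELL_SHAPE) — behaviour bouts
    are far more regular than memoryless."""
    states = [s for s, frac in budgets.items() if frac > 0]
    if not states or b - a <= 0:
        return []
    if len(states) == 1:
        return [(a, b, states[0])]
    b_ly = budgets.get("lying", 0.0)
    active = [s for s in states if s != "lying"]
    w = np.array([budgets[s] / dwells[s] for s in active])
    p = w / w.sum()
    mean_active = float(sum(pi * dwells[s] for pi, s in zip(p, active)))
    tau_lying = b_ly / (1.0 - b_ly) * mean_active if b_ly > 0 else None

    def draw(state_mean: float) -> float:
        return float(rng.gamma(DWELL_SHAPE, state_mean / DWELL_SHAPE))

    out = []
    t = a
    resting = b_ly > 0 and rng.random() < b_ly
    while t < b:
        if resting and tau_lying is not None:
            s, d = "lying", draw(tau_lying)
        else:
            s = active[int(rng.choice(len(active), p=p))]
            d = draw(dwells[s])
        out.append((t, min(t + d, b), s))
        t += d
        resting = not resting if tau_lying is not None else False
    return out


def generate_behaviour(timeline: FarrowingTimeline, cfg: SimConfig) -> BehaviourScript:
    cfg.validate()
    rng = cfg.rng(1)
    spans = [
        ("before", timeline.t_start, timeline.t_onset),
        ("during", timeline.t_onset, timeline.t_end_farrowing),
        ("after", timeline.t_end_farrowing, timeline.t_stop),
    ]
    intervals = []
    for phase, a, b in spans:
        intervals.extend(
            _sample_phase_intervals(rng, a, b, cfg.behaviour_budgets[phase], cfg.dwell_means_s[phase])
        )
    # merge adjacent intervals with identical state
    merged: list[tuple[float, float, str]] = []
    for a, b, s in intervals:
        if merged and merged[-1][2] == s and abs(merged[-1][1] - a) < 1e-9:
            merged[-1] = (merged[-1][0], b, s)
        else:
            merged.append((a, b, s))
    return BehaviourScript(tuple(merged))


# ---------------------------------------------------------------------------
# sound events
# ---------------------------------------------------------------------------
def _poisson_times(rng, rate_per_min: float, a: float, b: float) -> np.ndarray:
    if rate_per_min <= 0 or b <= a:
        return np.empty(0)
    n = rng.poisson(rate_per_min / 60.0 * (b - a))
    return np.sort(rng.uniform(a, b, size=n))


def _amp(rng, cfg: SimConfig) -> float:
    return float(np.clip(rng.lognormal(0.0, cfg.amp_sigma), cfg.amp_min, cfg.amp_max))


def _dur(rng, cfg: SimConfig) -> float:
    return float(max(cfg.event_duration_min_s, rng.exponential(cfg.event_duration_mean_s)))


def generate_sound_events(
    timeline: FarrowingTimeline,
    script: BehaviourScript,
    cfg: SimConfig,
    geometry: PenGeometry | None = None,
) -> list[SoundEvent]:
    cfg.validate()
    g = geometry or PenGeometry()
    rng = cfg.rng(2)
    cx0, cx1 = g.crate_x
    cy0, cy1 = g.crate_y
    hx0, hx1 = g.head_x
    rx0, rx1 = g.rear_x
    events: list[SoundEvent] = []

    def add(t, label, pos, amplitude=None, audible=None, duration=None):
        amplitude = _amp(rng, cfg) if amplitude is None else amplitude
        audible = bool(rng.random() < cfg.audible_prob) if audible is None else audible
        events.append(
            SoundEvent(
                t=float(t),
                duration=duration if duration is not None else _dur(rng, cfg),
                position=(float(pos[0]), float(pos[1])),
                center_freq=cfg.center_freq,
                bandwidth=cfg.bandwidth,
                amplitude=float(amplitude),
                audible=audible,
                label=label,
            )
        )

    phase_spans = [
        ("before", timeline.t_start, timeline.t_onset),
        ("during", timeline.t_onset, timeline.t_end_farrowing),
        ("after", timeline.t_end_farrowing, timeline.t_stop),
    ]
    margin = 0.06  # keep random positions strictly inside their zone boxes
    for phase, a, b in phase_spans:
        # sow vocalisations: from the mouth, head end of the crate
        for t in _poisson_times(rng, cfg.event_rates["sow_vocal"][phase], a, b):
            pos = (rng.uniform(hx0 + margin, hx1 - margin), rng.uniform(cy0 + margin, cy1 - margin))
            add(t, "sow_vocal", pos)
        # trough contacts
        for t in _poisson_times(rng, cfg.event_rates["trough"][phase], a, b):
            pos = (rng.uniform(0.02, max(0.03, g.sow_head_x - 0.02)), rng.uniform(cy0 + margin, cy1 - margin))
            add(t, "trough", pos)
        # fence contacts: boundary strip, long sides
        for t in _poisson_times(rng, cfg.event_rates["fence"][phase], a, b):
            y = rng.choice([rng.uniform(0.02, g.fence_strip_m - 0.02),
                            rng.uniform(g.pen_width_m - g.fence_strip_m + 0.02, g.pen_width_m - 0.02)])
            add(t, "fence", (rng.uniform(0.3, g.pen_length_m - 0.3), y))
        # neighbour sows: outside the pen bounds
        for t in _poisson_times(rng, cfg.event_rates["neighbour"][phase], a, b):
            side = rng.random() < 0.5
            x = rng.uniform(-0.6, -0.2) if side else rng.uniform(g.pen_length_m + 0.2, g.pen_length_m + 0.6)
            add(t, "neighbour", (x, rng.uniform(0.0, g.pen_width_m)))

    # rooting bursts within jute-rooting bouts, at the head of the sow
    for a, b, state in script.intervals:
        if state != "jute_rooting":
            continue
        phase = timeline.phase_of(a)
        for t in _poisson_times(rng, cfg.event_rates["jute_rooting"][phase], a, b):
            pos = (rng.uniform(hx0 + margin, hx1 - margin), rng.uniform(cy0 + margin, cy1 - margin))
            add(t, "jute_rooting", pos)

    # births (visible to the camera, inaudible to the observer) and
    # subsequent piglet movement behind the sow
    for bt in timeline.birth_times:
        pos = (rng.uniform(rx0 + margin, rx1 - margin), rng.uniform(cy0 + margin, cy1 - margin))
        add(bt, "piglet_birth", pos, amplitude=cfg.birth_amplitude, audible=False)
        rate = cfg.event_rates["piglet_move"][timeline.phase_of(bt)]
        for t in _poisson_times(rng, rate, bt + 1.0, min(bt + cfg.postnatal_tail_s, timeline.t_stop)):
            pos = (rng.uniform(rx0 + margin, rx1 - margin), rng.uniform(cy0 + margin, cy1 - margin))
            add(t, "piglet_move", pos, audible=False)

    events.sort(key=lambda e: (e.t, e.label))
    return events


# ---------------------------------------------------------------------------
# reference logs and idealised spot streams
# ---------------------------------------------------------------------------
def render_reference_logs(
    events: list[SoundEvent],
    script: BehaviourScript,
    cfg: SimConfig,
    geometry: PenGeometry | None = None,
) -> tuple[EventLog, EventLog]:
    """(audible log, behaviour log) as the human observer would score them.

    The audible log contains exactly the events flagged audible whose
    amplitude reaches the audibility threshold, labelled with the field
    vocabulary (``Sow in crate``, ``Trough``, ...).  The behaviour log
    carries the script intervals verbatim."""
    g = geometry or PenGeometry()
    aud = [
        {
            "time_s": e.t,
            "duration_s": e.duration,
            "stream": "audible",
            "label": AUDIBLE_LABELS[e.label],
            "zone": str(zone_of(e.position, g)),
            "x_m": np.nan,
            "y_m": np.nan,
            "audible": True,
        }
        for e in events
        if e.audible and e.amplitude >= cfg.audibility_threshold
    ]
    beh = [
        {
            "time_s": a,
            "duration_s": b - a,
            "stream": "behaviour",
            "label": s,
            "zone": str(Zone.NONE),
            "x_m": np.nan,
            "y_m": np.nan,
            "audible": False,
        }
        for a, b, s in script.intervals
    ]
    return EventLog.from_records(aud), EventLog.from_records(beh)


def events_to_spot_log(
    events: list[SoundEvent],
    geometry: PenGeometry | None = None,
    amplitude_floor: float = 0.0,
) -> EventLog:
    """Idealised acoustic-camera output: one spot per in-pen event above
    ``amplitude_floor``, at the true position and time.  Useful for studying
    the matcher and the onset monitor independently of the beamformer."""
    g = geometry or PenGeometry()
    rec = []
    for e in events:
        if e.amplitude < amplitude_floor:
            continue
        z = zone_of(e.position, g)
        if z is Zone.OUTSIDE_PEN:
            continue  # the camera's spatial filter hides out-of-pen sources
        rec.append(
            {
                "time_s": e.t,
                "duration_s": 0.0,
                "stream": "spot",
                "label": e.label,
                "zone": str(z),
                "x_m": e.position[0],
                "y_m": e.position[1],
                "audible": False,
            }
        )
    return EventLog.from_records(rec)


# ---------------------------------------------------------------------------
# audio synthesis
# ---------------------------------------------------------------------------
def _burst(rng, n: int, fs: float, f0: float, bw: float, peak: float) -> np.ndarray:
    """Band-limited noise burst with raised-cosine onset/offset, scaled to a
    given peak amplitude."""
    x = rng.standard_normal(n + 256)
    lo = max(10.0, f0 - bw / 2.0)
    hi = min(0.499 * fs, f0 + bw / 2.0)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, x)[256:]
    ramp = max(2, int(0.1 * n))
    win = np.ones(n)
    edge = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
    win[:ramp] = edge
    win[-ramp:] = edge[::-1]
    x *= win
    m = np.max(np.abs(x))
    return (x * (peak / m)).astype(np.float64) if m > 0 else x


def render_block(
    events: list[SoundEvent],
    array: MicArray,
    geometry: PenGeometry,
    cfg: SimConfig,
    t0: float,
    t1: float,
    noise_rng: np.random.Generator | None = None,
    attenuate: bool = True,
) -> np.ndarray:
    """Render scene time [t0, t1) into a (n_mics, n_samples) float32 block.

    ``t0``/``t1`` are *stream* times (scene time minus the recording lag).
    Each event reaches microphone m delayed by distance/c and attenuated by
    1/distance.  Per-event source waveforms come from an event-indexed
    stream so a block decomposition renders identical samples.
    """
    cfg.validate()
    fs = cfg.fs
    n = int(round((t1 - t0) * fs))
    if noise_rng is not None and cfg.snr_db is not None:
        out = noise_rng.standard_normal((array.n_mics, n), dtype=np.float32)
        out *= np.float32(cfg.noise_rms)
    else:
        out = np.zeros((array.n_mics, n), dtype=np.float32)

    mics = array.positions
    lag = cfg.recording_lag_s
    L_, W_ = geometry.pen_length_m, geometry.pen_width_m
    corners = np.array([[-0.7, 0.0], [L_ + 0.7, 0.0], [-0.7, W_], [L_ + 0.7, W_]])
    dmax_s = distances(corners, mics).max() / SPEED_OF_SOUND
    for k, e in enumerate(events):
        es = e.t - lag  # stream time of emission
        if es + e.duration + dmax_s < t0 or es > t1:
            continue
        ev_rng = np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, 7, k])
        ns = int(round(e.duration * fs))
        if ns < 8:
            continue
        s = _burst(ev_rng, ns, fs, e.center_freq, e.bandwidth, e.amplitude)
        d = distances(np.array([e.position]), mics)[0]  # (M,)
        for m in range(array.n_mics):
            i0 = int(round((es + d[m] / SPEED_OF_SOUND - t0) * fs))
            gain = (1.0 / d[m]) if attenuate else 1.0
            a, b = max(i0, 0), min(i0 + ns, n)
            if a >= b:
                continue
            out[m, a:b] += (s[a - i0 : b - i0] * gain).astype(np.float32)
    return out


def synthesize_mic_signals(
    events: list[SoundEvent],
    array: MicArray,
    geometry: PenGeometry,
    cfg: SimConfig,
    t0: float = 0.0,
    t1: float | None = None,
    attenuate: bool = True,
) -> np.ndarray:
    """Materialise the full multichannel recording for a (short) scene.

    Returns float32 of shape (n_mics, n_samples); sample i holds stream
    time ``t0 + i/fs`` (scene time ``t0 + recording_lag_s + i/fs``).  For
    long scenes prefer the chunked scanner in :mod:`farrowcam.scanner`.
    """
    if t1 is None:
        t1 = max((e.end for e in events), default=1.0) + 0.1
    noise_rng = cfg.rng(3) if cfg.snr_db is not None else None
    return render_block(events, array, geometry, cfg, t0, t1, noise_rng=noise_rng, attenuate=attenuate)


def simulate_scene(cfg: SimConfig, geometry: PenGeometry | None = None):
    """Convenience: timeline, behaviour script, events and reference logs."""
    g = geometry or PenGeometry()
    timeline = generate_timeline(cfg)
    script = generate_behaviour(timeline, cfg)
    events = generate_sound_events(timeline, script, cfg, g)
    audible, behaviour = render_reference_logs(events, script, cfg, g)
    return timeline, script, events, audible, behaviour
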