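"""Classify sound spots against reference streams into CP / FP / FN / CN.

Rules of the comparison:

* a spot pairs with an audible reference sound if the two lie within
  ``tolerance_s`` (default +/- 1 s) of each other; pairing is one-to-one
  and an exact maximum-cardinality, minimum total |dt| assignment;
* a paired spot in a zone that corresponds to the reference label (per
  the correspondence table) is a correct positive (CP); a paired spot in
  the wrong location is counted as FN or CP according to the location
  policy — both tallies are reported in the field data;
* unpaired spots are false positives (FP), unpaired reference sounds are
  false negatives (FN);
* every ``silence_s`` (default 2 s) stretch with neither spot nor
  reference activity scores one correct negative (CN);
* behaviours are states, so a spot validates against a behaviour when its
  time falls inside an *active* behaviour interval (tolerance applies at
  the edges) and its zone corresponds; in the combined mode a spot is
  correct if either the sound stream or the behaviour stream (or both)
  supports it;
* a "cloud" — at least ``cloud_min_spots`` spots within 1 s and 0.3 m —
  is collapsed to its first spot before matching, following the slowed-
  replay observation that clouds start with one spot in the right place.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .annotation import ACTIVE_STATES, CorrespondenceTable, EventLog, is_location_correct

POLICIES = ("wrong_as_FN", "wrong_as_CP")
REFERENCE_MODES = ("sound", "behaviour", "sound_or_behaviour")


@dataclass(frozen=True)
class ConfusionCounts:
    CP: int = 0
    FP: int = 0
    FN: int = 0
    CN: int = 0

    def __post_init__(self) -> None:
        if min(self.CP, self.FP, self.FN, self.CN) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.CP + self.FP + self.FN + self.CN

    def as_dict(self) -> dict[str, int]:
        return {"CP": self.CP, "FP": self.FP, "FN": self.FN, "CN": self.CN}


@dataclass
class MatchConfig:
    tolerance_s: float = 1.0
    silence_s: float = 2.0
    location_policy: str = "wrong_as_FN"
    reference_mode: str = "sound"
    cn_mode: str = "floor"  # floor: one CN per full silence_s of a silent stretch
    cloud_min_spots: int = 5
    cloud_window_s: float = 1.0
    cloud_radius_m: float = 0.3
    collapse_clouds: bool = True

    def __post_init__(self) -> None:
        if self.tolerance_s <= 0 or self.silence_s <= 0:
            raise ValueError("tolerance_s and silence_s must be > 0")
        if self.location_policy not in POLICIES:
            raise ValueError(f"location_policy must be one of {POLICIES}")
        if self.reference_mode not in REFERENCE_MODES:
            raise ValueError(f"reference_mode must be one of {REFERENCE_MODES}")
        if self.cn_mode not in ("floor", "per_stretch"):
            raise ValueError("cn_mode must be 'floor' or 'per_stretch'")


@dataclass(frozen=True)
class Pair:
    spot_idx: int
    ref_idx: int
    stream: str  # 'audible' or 'behaviour'
    dt: float
    location_correct: bool


@dataclass
class MatchResult:
    pairs: list[Pair]
    n_spots: int
    n_unmatched_spots: int
    n_unmatched_refs: int
    cn: int
    spot_class: list[str]  # per spot: CP / FN_location / FP
    config: MatchConfig

    @property
    def n_wrong_location(self) -> int:
        return sum(1 for p in self.pairs if not p.location_correct)

    def counts(self, policy: str | None = None) -> ConfusionCounts:
        policy = policy or self.config.location_policy
        if policy not in POLICIES:
            raise ValueError(f"unknown policy {policy!r}")
        right = sum(1 for p in self.pairs if p.location_correct)
        wrong = self.n_wrong_location
        if policy == "wrong_as_CP":
            cp, fn_extra = right + wrong, 0
        else:
            cp, fn_extra = right, wrong
        return ConfusionCounts(
            CP=cp, FP=self.n_unmatched_spots, FN=self.n_unmatched_refs + fn_extra, CN=self.cn
        )


def apply_location_policy(
    counts: ConfusionCounts,
    n_wrong_location: int,
    policy: str,
    current_policy: str = "wrong_as_FN",
) -> ConfusionCounts:
    """Re-express confusion counts under the other wrong-location policy.

    Switching ``wrong_as_FN`` -> ``wrong_as_CP`` moves every wrong-location
    pair from FN to CP; FP and CN are untouched, and CP + FN is conserved.
    """
    if policy not in POLICIES or current_policy not in POLICIES:
        raise ValueError(f"policies must be one of {POLICIES}")
    if n_wrong_location < 0:
        raise ValueError("n_wrong_location must be >= 0")
    if policy == current_policy:
        return counts
    if policy == "wrong_as_CP":
        return replace(counts, CP=counts.CP + n_wrong_location, FN=counts.FN - n_wrong_location)
    return replace(counts, CP=counts.CP - n_wrong_location, FN=counts.FN + n_wrong_location)


# ---------------------------------------------------------------------------
# cloud collapsing
# ---------------------------------------------------------------------------
def collapse_clouds(spots: EventLog, cfg: MatchConfig) -> EventLog:
    """Replace each cluster of >= cloud_min_spots spots within the cloud
    window/radius by its first spot."""
    df = spots.entries
    if len(df) == 0:
        return spots
    t = df["time_s"].to_numpy()
    x = df["x_m"].to_numpy(dtype=float)
    y = df["y_m"].to_numpy(dtype=float)
    keep = np.ones(len(df), dtype=bool)
    used = np.zeros(len(df), dtype=bool)
    for i in range(len(df)):
        if used[i]:
            continue
        close = ~used & (t >= t[i]) & (t <= t[i] + cfg.cloud_window_s)
        if np.isfinite(x[i]):
            close &= (np.abs(x - x[i]) <= cfg.cloud_radius_m) & (np.abs(y - y[i]) <= cfg.cloud_radius_m)
        idx = np.flatnonzero(close)
        if len(idx) >= cfg.cloud_min_spots:
            used[idx] = True
            keep[idx] = False
            keep[idx[0]] = True
    return EventLog(df[keep])


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------
def _assign(spot_times: np.ndarray, ref_times: np.ndarray, tol: float) -> list[tuple[int, int]]:
    """Exact one-to-one pairing: maximum cardinality over pairs with
    |dt| <= tol, ties broken by minimum total |dt|.  Solved blockwise with
    the Hungarian algorithm; blocks are connected components of the
    feasibility graph, so the problem stays small even for long logs."""
    ns, nr = len(spot_times), len(ref_times)
    if ns == 0 or nr == 0:
        return []
    order_s = np.argsort(spot_times, kind="stable")
    order_r = np.argsort(ref_times, kind="stable")
    st, rt = spot_times[order_s], ref_times[order_r]

    pairs: list[tuple[int, int]] = []
    # sweep both sorted streams, cutting a block wherever a gap > tol
    # separates every remaining spot from every remaining ref
    i = j = 0
    bs: list[int] = []
    br: list[int] = []

    def flush():
        if bs and br:
            big = tol * (len(bs) + len(br) + 1) * 4 + 1.0
            cost = np.abs(st[bs][:, None] - rt[br][None, :])
            feas = cost <= tol
            cost = np.where(feas, cost, big)
            ri, ci = linear_sum_assignment(cost)
            for a, b in zip(ri, ci):
                if feas[a, b]:
                    pairs.append((int(order_s[bs[a]]), int(order_r[br[b]])))
        bs.clear()
        br.clear()

    events = sorted(
        [(t, 0, k) for k, t in enumerate(st)] + [(t, 1, k) for k, t in enumerate(rt)]
    )
    last_t = None
    for t, kind, k in events:
        if last_t is not None and t - last_t > 2 * tol:
            flush()
        (bs if kind == 0 else br).append(k)
        last_t = t
    flush()
    return pairs


def brute_force_max_matching(spot_times, ref_times, tol: float) -> int:
    """Independent oracle: maximum-cardinality tolerance matching by
    exhaustive recursion.  Only viable for tiny instances."""
    spot_times = list(spot_times)
    ref_times = list(ref_times)

    def rec(i: int, used: set[int]) -> int:
        if i == len(spot_times):
            return 0
        best = rec(i + 1, used)  # leave spot i unmatched
        for j, rt in enumerate(ref_times):
            if j not in used and abs(spot_times[i] - rt) <= tol:
                used.add(j)
                best = max(best, 1 + rec(i + 1, used))
                used.remove(j)
        return best

    return rec(0, set())


# ---------------------------------------------------------------------------
# correct negatives
# ---------------------------------------------------------------------------
def count_correct_negatives(
    occupied: list[tuple[float, float]], window: tuple[float, float], cfg: MatchConfig
) -> int:
    """CNs from the silent complement of the occupied intervals.

    ``floor`` mode credits one CN per full ``silence_s`` contained in each
    maximal silent stretch; ``per_stretch`` credits one per stretch."""
    t0, t1 = window
    if t1 <= t0:
        return 0
    ivs = sorted((max(a, t0), min(b, t1)) for a, b in occupied if b > t0 and a < t1)
    merged: list[tuple[float, float]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    edges = [t0] + [x for ab in merged for x in ab] + [t1]
    cn = 0
    for a, b in zip(edges[::2], edges[1::2]):
        gap = b - a
        if cfg.cn_mode == "floor":
            cn += int(math.floor(gap / cfg.silence_s + 1e-9))
        else:
            cn += 1 if gap >= cfg.silence_s - 1e-9 else 0
    return cn


# ---------------------------------------------------------------------------
# main entry
# ---------------------------------------------------------------------------
def match(
    spots: EventLog,
    cfg: MatchConfig | None = None,
    audible: EventLog | None = None,
    behaviour: EventLog | None = None,
    sound_table: CorrespondenceTable | None = None,
    behaviour_table: CorrespondenceTable | None = None,
    window: tuple[float, float] | None = None,
) -> MatchResult:
    """Classify a spot stream against the reference stream(s).

    ``window`` is the observation span used for correct-negative counting;
    by default it spans the earliest to latest entry of all given logs.
    """
    cfg = cfg or MatchConfig()
    mode = cfg.reference_mode
    if mode in ("sound", "sound_or_behaviour") and (audible is None or sound_table is None):
        raise ValueError(f"reference_mode {mode!r} needs an audible log and a sound table")
    if mode in ("behaviour", "sound_or_behaviour") and (behaviour is None or behaviour_table is None):
        raise ValueError(f"reference_mode {mode!r} needs a behaviour log and a behaviour table")
    for name, lg in (("spots", spots), ("audible", audible), ("behaviour", behaviour)):
        if lg is not None and not lg.entries["time_s"].is_monotonic_increasing:
            raise ValueError(f"{name} log must be time-sorted")

    if cfg.collapse_clouds:
        spots = collapse_clouds(spots, cfg)
    sdf = spots.entries
    n_spots = len(sdf)
    spot_t = sdf["time_s"].to_numpy()
    spot_zone = sdf["zone"].to_numpy()

    logs = [lg for lg in (spots, audible, behaviour) if lg is not None and len(lg)]
    if window is None:
        if logs:
            window = (min(lg.span[0] for lg in logs), max(lg.span[1] for lg in logs))
        else:
            window = (0.0, 0.0)

    pairs: list[Pair] = []
    matched_spot = np.zeros(n_spots, dtype=bool)
    n_unmatched_refs = 0
    occupied: list[tuple[float, float]] = [(t, t) for t in spot_t]

    # --- audible sounds: point events, one-to-one within the tolerance ----
    if mode in ("sound", "sound_or_behaviour"):
        adf = audible.entries
        ref_t = adf["time_s"].to_numpy()
        ref_lbl = adf["label"].to_numpy()
        occupied += [(t, t + d) for t, d in zip(ref_t, adf["duration_s"].to_numpy())]
        ap = _assign(spot_t, ref_t, cfg.tolerance_s)
        for si, ri in ap:
            ok = is_location_correct(spot_zone[si], ref_lbl[ri], sound_table)
            pairs.append(Pair(si, ri, "audible", float(spot_t[si] - ref_t[ri]), ok))
            matched_spot[si] = True
        n_unmatched_refs += len(ref_t) - len(ap)

    # --- behaviours: states; a spot inside an active interval (tolerance
    # at the edges) with a corresponding zone is supported by behaviour ---
    if mode in ("behaviour", "sound_or_behaviour"):
        bdf = behaviour.entries
        act = bdf[bdf["label"].isin(ACTIVE_STATES)]
        b_start = act["time_s"].to_numpy()
        b_end = b_start + act["duration_s"].to_numpy()
        b_lbl = act["label"].to_numpy()
        occupied += [(a, b) for a, b in zip(b_start, b_end)]
        interval_hit = np.zeros(len(act), dtype=bool)
        for si in range(n_spots):
            t = spot_t[si]
            inside = np.flatnonzero((t >= b_start - cfg.tolerance_s) & (t <= b_end + cfg.tolerance_s))
            if len(inside) == 0:
                continue
            ok_j = wrong_j = None
            for j in inside:
                if is_location_correct(spot_zone[si], b_lbl[j], behaviour_table):
                    ok_j = j
                    break
                wrong_j = j
            j = ok_j if ok_j is not None else wrong_j
            interval_hit[inside] = True
            if matched_spot[si] and ok_j is None:
                continue  # already has a sound pairing at least as good
            if matched_spot[si] and ok_j is not None:
                # upgrade a wrong-location sound pair to a behaviour-correct one
                prior = next(p for p in pairs if p.spot_idx == si)
                if prior.location_correct:
                    continue
                pairs.remove(prior)
                n_unmatched_refs += 1  # its audible ref is unmatched again
            pairs.append(Pair(si, int(j), "behaviour", 0.0, ok_j is not None))
            matched_spot[si] = True
        n_unmatched_refs += int((~interval_hit).sum())

    cn = count_correct_negatives(occupied, window, cfg)
    spot_class = []
    by_spot = {p.spot_idx: p for p in pairs}
    for si in range(n_spots):
        p = by_spot.get(si)
        if p is None:
            spot_class.append("FP")
        elif p.location_correct:
            spot_class.append("CP")
        else:
            spot_class.append("CP" if cfg.location_policy == "wrong_as_CP" else "FN_location")
    return MatchResult(
        pairs=pairs,
        n_spots=n_spots,
        n_unmatched_spots=int((~matched_spot).sum()),
        n_unmatched_refs=n_unmatched_refs,
        cn=cn,
        spot_class=spot_class,
        config=cfg,
    )
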