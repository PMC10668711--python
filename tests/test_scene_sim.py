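import numpy as np
import pytest
from scipy import signal as sps

from farrowcam.annotation import BEHAVIOUR_BUDGETS
from farrowcam.geometry import MicArray, Zone, zone_of
from farrowcam.scene_sim import (
    SimConfig,
    SoundEvent,
    generate_behaviour,
    generate_sound_events,
    generate_timeline,
    render_block,
    render_reference_logs,
    simulate_scene,
    synthesize_mic_signals,
)


def phase_shares(script, a, b):
    tot = {}
    for s0, s1, state in script.intervals:
        lo, hi = max(s0, a), min(s1, b)
        if hi > lo:
            tot[state] = tot.get(state, 0.0) + (hi - lo)
    T = sum(tot.values())
    return {k: v / T for k, v in tot.items()}


class TestTimeline:
    def test_zero_litter_collapses_farrowing(self):
        cfg = SimConfig(seed=0, litter_size=0, pre_farrowing_s=300, post_farrowing_s=300)
        tl = generate_timeline(cfg)
        assert tl.birth_times == ()
        assert tl.t_onset == tl.t_end_farrowing

    def test_births_ordered_within_farrowing(self):
        cfg = SimConfig(seed=7, litter_size=12)
        tl = generate_timeline(cfg)
        bt = np.array(tl.birth_times)
        assert len(bt) == 12
        assert np.all(np.diff(bt) > 0)
        assert tl.t_onset < bt[0] and bt[-1] < tl.t_end_farrowing

    def test_same_seed_same_timeline(self):
        cfg = SimConfig(seed=11)
        assert generate_timeline(cfg) == generate_timeline(cfg)

    def test_negative_litter_rejected(self):
        with pytest.raises(ValueError, match="litter"):
            generate_timeline(SimConfig(litter_size=-1))

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_timeline(SimConfig(pre_farrowing_s=-5))


class TestBehaviour:
    def test_pre_farrowing_rooting_share_near_observed(self):
        """4-h pre-farrowing phase: the jute-rooting time share lands within
        5 percentage points of the 25 % field budget."""
        cfg = SimConfig(seed=1)
        tl = generate_timeline(cfg)
        script = generate_behaviour(tl, cfg)
        shares = phase_shares(script, tl.t_start, tl.t_onset)
        assert shares["jute_rooting"] == pytest.approx(0.25, abs=0.05)

    def test_post_farrowing_is_lying_only(self):
        cfg = SimConfig(seed=2)
        tl = generate_timeline(cfg)
        script = generate_behaviour(tl, cfg)
        shares = phase_shares(script, tl.t_end_farrowing, tl.t_stop)
        assert shares == {"lying": pytest.approx(1.0)}

    def test_zero_length_timeline_empty_script(self):
        cfg = SimConfig(seed=0, litter_size=0, pre_farrowing_s=0.0, post_farrowing_s=0.0)
        tl = generate_timeline(cfg)
        script = generate_behaviour(tl, cfg)
        assert script.intervals == ()

    def test_bad_budgets_rejected(self):
        cfg = SimConfig()
        cfg.behaviour_budgets["before"] = {"lying": 0.5, "jute_rooting": 0.4}
        with pytest.raises(ValueError, match="sum"):
            generate_behaviour(generate_timeline(SimConfig()), cfg)

    def test_intervals_tile_scene_exactly(self):
        cfg = SimConfig(seed=3)
        tl = generate_timeline(cfg)
        script = generate_behaviour(tl, cfg)
        iv = script.intervals
        assert iv[0][0] == pytest.approx(tl.t_start)
        assert iv[-1][1] == pytest.approx(tl.t_stop)
        for (a0, b0, _), (a1, _, _) in zip(iv, iv[1:]):
            assert a1 == pytest.approx(b0)


@pytest.fixture(scope="module")
def scene(geometry):
    cfg = SimConfig(seed=4)
    tl = generate_timeline(cfg)
    script = generate_behaviour(tl, cfg)
    return cfg, tl, script, generate_sound_events(tl, script, cfg, geometry)


class TestEvents:
    def test_no_births_no_piglet_events(self, geometry):
        cfg = SimConfig(seed=4, litter_size=0)
        tl = generate_timeline(cfg)
        script = generate_behaviour(tl, cfg)
        events = generate_sound_events(tl, script, cfg, geometry)
        assert not any(e.label.startswith("piglet") for e in events)

    def test_births_are_inaudible(self, scene):
        _, tl, _, events = scene
        births = [e for e in events if e.label == "piglet_birth"]
        assert len(births) == len(tl.birth_times)
        assert all(not e.audible for e in births)

    def test_piglet_events_in_rear_zone(self, scene, geometry):
        _, _, _, events = scene
        for e in events:
            if e.label.startswith("piglet"):
                assert zone_of(e.position, geometry) is Zone.RUMP

    def test_piglet_movement_only_after_first_birth(self, scene):
        _, tl, _, events = scene
        moves = [e.t for e in events if e.label == "piglet_move"]
        assert moves and min(moves) > tl.birth_times[0]

    def test_rooting_events_in_head_zone_during_bouts(self, scene, geometry):
        _, _, script, events = scene
        for e in events:
            if e.label == "jute_rooting":
                assert zone_of(e.position, geometry) is Zone.HEAD
                assert script.state_at(e.t) == "jute_rooting"

    def test_neighbour_events_outside_pen(self, scene, geometry):
        _, _, _, events = scene
        neigh = [e for e in events if e.label == "neighbour"]
        assert neigh
        assert all(zone_of(e.position, geometry) is Zone.OUTSIDE_PEN for e in neigh)
        others = [e for e in events if e.label != "neighbour"]
        assert all(zone_of(e.position, geometry) is not Zone.OUTSIDE_PEN for e in others)

    def test_event_stream_reproducible(self, scene, geometry):
        cfg, tl, script, events = scene
        again = generate_sound_events(tl, script, cfg, geometry)
        assert events == again


class TestReferenceLogs:
    def test_audibility_partition(self, geometry):
        """Every event lands in exactly one of {audible log, inaudible set}."""
        cfg = SimConfig(seed=5)
        tl, script, events, audible, _ = simulate_scene(cfg, geometry)
        n_aud = sum(1 for e in events if e.audible and e.amplitude >= cfg.audibility_threshold)
        assert len(audible) == n_aud

    def test_high_threshold_empties_audible_log(self, geometry):
        cfg = SimConfig(seed=5)
        cfg.audibility_threshold = 1e9
        _, _, _, audible, _ = simulate_scene(cfg, geometry)
        assert len(audible) == 0

    def test_no_piglet_entries_in_audible_log(self, geometry):
        cfg = SimConfig(seed=5)
        _, _, _, audible, _ = simulate_scene(cfg, geometry)
        assert not (audible.entries["label"] == "Piglet").any()

    def test_behaviour_log_durations_sum_to_scene(self, geometry):
        cfg = SimConfig(seed=5)
        tl, _, _, _, behaviour = simulate_scene(cfg, geometry)
        assert behaviour.entries["duration_s"].sum() == pytest.approx(tl.duration)


class TestAudioSynthesis:
    def _one_event(self, pos=(1.4, 0.875), amp=1.0):
        return SoundEvent(t=0.01, duration=0.03, position=pos, center_freq=44000.0,
                          bandwidth=2000.0, amplitude=amp, audible=True, label="sow_vocal")

    def test_equidistant_mics_identical_channels(self, geometry):
        cfg = SimConfig(seed=0, snr_db=None, recording_lag_s=0.0)
        mics = MicArray(np.array([[1.0, 0.875, 2.0], [1.8, 0.875, 2.0]]))
        sig = synthesize_mic_signals([self._one_event()], mics, geometry, cfg, t1=0.06)
        np.testing.assert_allclose(sig[0], sig[1])

    def test_closer_mic_leads_by_expected_delay(self, geometry):
        """A mic 0.343 m closer receives the burst 1.0 ms earlier."""
        cfg = SimConfig(seed=0, snr_db=None, recording_lag_s=0.0)
        src = (1.4, 0.875)
        mics = MicArray(np.array([[1.4, 0.875, 1.0], [1.4, 0.875, 1.343]]))
        sig = synthesize_mic_signals([self._one_event(pos=src)], mics, geometry, cfg, t1=0.08)
        xc = sps.correlate(sig[0], sig[1], mode="full")
        lag = (np.argmax(xc) - (sig.shape[1] - 1)) / cfg.fs
        assert lag == pytest.approx(-1.0e-3, abs=2 / cfg.fs)

    def test_empty_events_no_noise_all_zero(self, geometry, array16):
        cfg = SimConfig(seed=0, snr_db=None)
        sig = synthesize_mic_signals([], array16, geometry, cfg, t1=0.05)
        assert not sig.any()

    def test_aliasing_rejected(self, geometry, array16):
        cfg = SimConfig(seed=0, fs=48000.0)
        with pytest.raises(ValueError, match="fs"):
            synthesize_mic_signals([self._one_event()], array16, geometry, cfg, t1=0.05)

    def test_block_decomposition_matches_single_render(self, geometry, array16):
        """Chunked rendering reproduces the one-shot render sample for
        sample (noise off): events are drawn from event-indexed streams."""
        cfg = SimConfig(seed=0, snr_db=None, recording_lag_s=0.0)
        ev = [self._one_event(), self._one_event(pos=(2.0, 1.2))]
        whole = render_block(ev, array16, geometry, cfg, 0.0, 0.1)
        parts = np.concatenate(
            [render_block(ev, array16, geometry, cfg, 0.0, 0.04),
             render_block(ev, array16, geometry, cfg, 0.04, 0.1)],
            axis=1,
        )
        np.testing.assert_allclose(whole, parts, atol=1e-7)
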