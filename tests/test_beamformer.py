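import numpy as np
import pytest

from farrowcam.beamformer import (
    AcousticMap,
    BandConfig,
    DetectorConfig,
    band_filter,
    beamform_recording,
    compute_delays,
    das_beamform,
    das_beamform_reference,
    detect_spots,
    make_grid,
)
from farrowcam.geometry import SPEED_OF_SOUND, Zone, irregular_array
from farrowcam.scene_sim import SimConfig, SoundEvent, synthesize_mic_signals

FS = 192_000.0


def burst_event(pos, amp=1.0, t=0.01, dur=0.03):
    return SoundEvent(t=t, duration=dur, position=pos, center_freq=44_000.0,
                      bandwidth=2_000.0, amplitude=amp, audible=True, label="sow_vocal")


def quiet_cfg(**kw):
    kw.setdefault("snr_db", None)
    kw.setdefault("recording_lag_s", 0.0)
    return SimConfig(seed=0, center_freq=44_000.0, **kw)


class TestDelays:
    def test_zero_delay_at_mic_position(self, array16):
        mic0 = array16.positions[0]
        tab = compute_delays(array16, mic0[None, :])
        assert tab.delays[0, 0] == 0.0

    def test_delay_is_distance_over_c(self, array16):
        # 3.43 m at 343 m/s -> exactly 10 ms
        mic0 = array16.positions[0]
        pt = mic0 + np.array([3.43, 0.0, 0.0])
        tab = compute_delays(array16, pt[None, :])
        assert tab.delays[0, 0] == pytest.approx(10e-3)

    def test_delay_proportional_to_distance(self, array16):
        mic0 = array16.positions[0]
        p1 = mic0 + np.array([1.0, 0, 0])
        p2 = mic0 + np.array([2.0, 0, 0])
        tab = compute_delays(array16, np.vstack([p1, p2]))
        assert tab.delays[1, 0] == pytest.approx(2 * tab.delays[0, 0])

    def test_invalid_speed_rejected(self, array16):
        with pytest.raises(ValueError):
            compute_delays(array16, np.zeros((1, 2)), c=0.0)


class TestBandFilter:
    def test_out_of_band_tone_suppressed(self):
        t = np.arange(int(0.05 * FS)) / FS
        tone = np.sin(2 * np.pi * 44_000 * t)
        out = band_filter(tone, BandConfig(39_570, 41_570), FS)
        assert np.sqrt(np.mean(out**2)) <= 0.01 * np.sqrt(np.mean(tone**2))

    def test_band_centre_tone_preserved(self):
        t = np.arange(int(0.05 * FS)) / FS
        tone = np.sin(2 * np.pi * 40_570 * t)
        out = band_filter(tone, BandConfig(39_570, 41_570), FS)
        assert np.sqrt(np.mean(out**2)) == pytest.approx(np.sqrt(np.mean(tone**2)), rel=0.11)

    def test_zero_in_zero_out(self):
        out = band_filter(np.zeros(4096), BandConfig(39_570, 41_570), FS)
        assert not out.any()

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            BandConfig(41_570, 39_570)

    def test_undersampled_rejected(self):
        with pytest.raises(ValueError, match="twice"):
            band_filter(np.zeros(1024), BandConfig(39_570, 41_570), 48_000.0)


class TestDASBeamform:
    def test_all_zero_frame_gives_zero_map(self, geometry, array16):
        pts, shape, origin = make_grid((0.5, 1.0, 0.5, 1.0), 0.1)
        tab = compute_delays(array16, pts)
        frame = np.zeros((16, 8000))
        amap = das_beamform(frame, tab, FS, length=2000, grid_shape=shape, origin=origin)
        assert not amap.grid.any()

    def test_short_frame_rejected(self, geometry, array16):
        pts, shape, origin = make_grid((0.5, 1.0, 0.5, 1.0), 0.1)
        tab = compute_delays(array16, pts)
        with pytest.raises(ValueError, match="shorter"):
            das_beamform(np.zeros((16, 100)), tab, FS, length=2000)

    def test_kernel_matches_numpy_reference(self, geometry, array16):
        """Compiled time-domain kernel vs the independent interpolating
        brute-force implementation, same points, same frame."""
        cfg = quiet_cfg()
        sig = synthesize_mic_signals([burst_event((1.4, 0.9))], array16, geometry, cfg, t1=0.08)
        pts = np.array([[1.4, 0.9], [1.0, 0.5], [2.2, 1.3], [0.4, 1.2]])
        tab = compute_delays(array16, pts)
        amap = das_beamform(sig.astype(np.float64), tab, FS, length=6000)
        ref = das_beamform_reference(sig, pts, array16, FS, length=6000)
        np.testing.assert_allclose(amap.grid.ravel(), ref, rtol=1e-6)

    def test_single_source_localised_to_grid_cell(self, geometry, array16):
        cfg = quiet_cfg()
        truth = (1.40, 0.90)
        sig = synthesize_mic_signals([burst_event(truth)], array16, geometry, cfg, t1=0.08)
        det = DetectorConfig(lag_correction_s=0.0)
        spots = beamform_recording(sig, FS, array16, geometry, None, det)
        assert spots
        for s in spots:
            assert abs(s.position[0] - truth[0]) <= det.grid_spacing_m + 1e-9
            assert abs(s.position[1] - truth[1]) <= det.grid_spacing_m + 1e-9

    def test_focus_value_invariant_to_mic_count(self, geometry):
        """1/N normalisation: with attenuation off, the beamformed value at
        the focus point does not depend on the array size.  Sampled well
        above the carrier so that sub-sample interpolation is near-ideal."""
        fs = 768_000.0
        cfg = quiet_cfg(fs=fs)
        truth = np.array([[1.40, 0.90]])
        vals = []
        for n in (8, 32):
            arr = irregular_array(geometry, n_mics=n)
            sig = synthesize_mic_signals([burst_event(truth[0])], arr, geometry, cfg,
                                         t1=0.08, attenuate=False)
            tab = compute_delays(arr, truth)
            amap = das_beamform(sig.astype(np.float64), tab, fs, length=int(0.03 * fs))
            vals.append(amap.grid.ravel()[0])
        assert vals[0] == pytest.approx(vals[1], rel=0.05)


class TestDetectSpots:
    def _map(self, t, grid):
        return AcousticMap(frame_time=t, grid=np.asarray(grid, float),
                           grid_spacing_m=0.05, origin=(0.0, 0.0))

    def test_silent_maps_give_no_spots(self, geometry):
        maps = [self._map(0.0, np.zeros((5, 5)))]
        assert detect_spots(maps, DetectorConfig(), geometry) == []

    def test_weak_peak_below_floor_margin_dropped(self, geometry):
        g = np.ones((5, 5))
        g[2, 2] = 1.5  # < 6 dB above the median floor
        assert detect_spots([self._map(0.0, g)], DetectorConfig(), geometry) == []

    def test_clear_peak_detected_with_lag_correction(self, geometry):
        g = np.full((5, 5), 0.1)
        g[2, 3] = 1.0
        det = DetectorConfig(lag_correction_s=1.5)
        (spot,) = detect_spots([self._map(2.0, g)], det, geometry)
        assert spot.t == pytest.approx(3.5)
        assert spot.position == (pytest.approx(0.10), pytest.approx(0.15))
        assert spot.zone is Zone.FENCE

    def test_unordered_maps_rejected(self, geometry):
        maps = [self._map(1.0, np.zeros((2, 2))), self._map(0.0, np.zeros((2, 2)))]
        with pytest.raises(ValueError, match="time-ordered"):
            detect_spots(maps, DetectorConfig(), geometry)

    def test_out_of_region_source_suppressed(self, geometry, array16):
        """The spatial filter hides a source outside the pen even though
        its sound reaches the array."""
        cfg = quiet_cfg()
        sig = synthesize_mic_signals([burst_event((-0.45, 0.9))], array16, geometry, cfg, t1=0.08)
        det = DetectorConfig(lag_correction_s=0.0)
        assert beamform_recording(sig, FS, array16, geometry, None, det) == []

    def test_time_shift_equivariance(self, geometry, array16):
        """Delaying every channel by a whole number of hops shifts every
        spot time by the same amount."""
        cfg = quiet_cfg()
        sig = synthesize_mic_signals([burst_event((1.4, 0.9))], array16, geometry, cfg, t1=0.10)
        det = DetectorConfig(lag_correction_s=0.0)
        base = beamform_recording(sig, FS, array16, geometry, None, det)
        shift = int(2 * det.hop_s * FS)
        delayed = np.pad(sig, ((0, 0), (shift, 0)))
        moved = beamform_recording(delayed, FS, array16, geometry, None, det)
        assert len(base) == len(moved) > 0
        for a, b in zip(base, moved):
            assert b.t - a.t == pytest.approx(2 * det.hop_s)
            assert b.position == a.position
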