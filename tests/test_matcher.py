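import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import audible_log, behaviour_log, spot_log
from farrowcam.annotation import load_table
from farrowcam.matcher import (
    ConfusionCounts,
    MatchConfig,
    _assign,
    apply_location_policy,
    brute_force_max_matching,
    collapse_clouds,
    count_correct_negatives,
    match,
)

SOUND = load_table("field1_sound")
BEH = load_table("field2_behaviour")


def match_sound(spots, audible, window, **cfg_kw):
    return match(spots, MatchConfig(**cfg_kw), audible=audible, sound_table=SOUND, window=window)


class TestSoundMatching:
    def test_spot_near_audible_is_correct_positive(self):
        r = match_sound(spot_log([(1.0, "head")]), audible_log([(1.4, "Sow in crate")]), (0, 2))
        assert r.counts().as_dict() == {"CP": 1, "FP": 0, "FN": 0, "CN": 0}

    def test_pair_outside_tolerance_splits_into_fp_and_fn(self):
        r = match_sound(spot_log([(5.0, "trough")]), audible_log([(6.5, "Trough")]), (4.5, 7.0))
        c = r.counts()
        assert (c.FP, c.FN, c.CP) == (1, 1, 0)

    def test_empty_streams_count_silence(self):
        r = match_sound(spot_log([]), audible_log([]), (0.0, 10.0))
        assert r.counts().as_dict() == {"CP": 0, "FP": 0, "FN": 0, "CN": 5}

    def test_wrong_location_pair_by_policy(self):
        spots = spot_log([(1.0, "trough")])
        aud = audible_log([(1.2, "Metal fence")])
        fn = match_sound(spots, aud, (0, 2), location_policy="wrong_as_FN").counts()
        cp = match_sound(spots, aud, (0, 2), location_policy="wrong_as_CP").counts()
        assert (fn.CP, fn.FN) == (0, 1)
        assert (cp.CP, cp.FN) == (1, 0)
        assert fn.FP == cp.FP and fn.CN == cp.CN

    def test_unsorted_spots_rejected(self):
        import pandas as pd

        log = spot_log([(1.0, "head"), (2.0, "head")])
        log.entries = log.entries.iloc[::-1]  # bypass constructor sorting
        with pytest.raises(ValueError, match="sorted"):
            match_sound(log, audible_log([]), (0, 3))


class TestBehaviourAndCombined:
    def test_spot_inside_matching_behaviour_interval_is_cp(self):
        spots = spot_log([(10.0, "head")])
        beh = behaviour_log([(0, 20, "jute_rooting")])
        r = match(spots, MatchConfig(reference_mode="behaviour"),
                  behaviour=beh, behaviour_table=BEH, window=(0, 20))
        assert r.counts().CP == 1

    def test_spot_during_lying_only_is_fp(self):
        spots = spot_log([(10.0, "head")])
        beh = behaviour_log([(0, 20, "lying")])
        r = match(spots, MatchConfig(reference_mode="behaviour"),
                  behaviour=beh, behaviour_table=BEH, window=(0, 20))
        assert r.counts().FP == 1

    def test_tolerance_applies_at_interval_edges(self):
        spots = spot_log([(20.8, "head")])
        beh = behaviour_log([(0, 20, "jute_rooting")])
        r = match(spots, MatchConfig(reference_mode="behaviour"),
                  behaviour=beh, behaviour_table=BEH, window=(0, 21))
        assert r.counts().CP == 1

    def test_combined_mode_accepts_either_stream(self):
        """A spot unsupported by sound but inside a corresponding behaviour
        interval is correct in the combined reference."""
        spots = spot_log([(10.0, "head")])
        aud = audible_log([])
        beh = behaviour_log([(0, 20, "jute_rooting")])
        sound_only = match_sound(spots, aud, (0, 20))
        combined = match(spots, MatchConfig(reference_mode="sound_or_behaviour"),
                         audible=aud, behaviour=beh,
                         sound_table=SOUND, behaviour_table=BEH, window=(0, 20))
        assert sound_only.counts().FP == 1
        assert combined.counts().CP == 1


class TestLocationPolicyArithmetic:
    def test_field_counts_policy_switch(self):
        col1 = ConfusionCounts(CP=1509, FP=10751, FN=1823, CN=1582)
        col2 = apply_location_policy(col1, 1747, "wrong_as_CP")
        assert col2.as_dict() == {"CP": 3256, "FP": 10751, "FN": 76, "CN": 1582}

    def test_zero_wrong_pairs_is_identity(self):
        c = ConfusionCounts(CP=3, FP=4, FN=5, CN=6)
        assert apply_location_policy(c, 0, "wrong_as_CP") == c

    def test_round_trip_and_monotonicity(self):
        c = ConfusionCounts(CP=3, FP=4, FN=5, CN=6)
        up = apply_location_policy(c, 2, "wrong_as_CP")
        assert up.CP >= c.CP and up.CP + up.FN == c.CP + c.FN
        back = apply_location_policy(up, 2, "wrong_as_FN", current_policy="wrong_as_CP")
        assert back == c


class TestCorrectNegatives:
    def test_floor_counting(self):
        cfg = MatchConfig()
        assert count_correct_negatives([], (0, 10), cfg) == 5
        assert count_correct_negatives([(4.0, 4.5)], (0, 10), cfg) == 2 + 2

    def test_concatenated_silent_recordings_add(self):
        """Silent stretches of L1 and L2 around a boundary event give
        floor(L1/2) + floor(L2/2)."""
        cfg = MatchConfig()
        L1, L2 = 7.0, 9.0
        cn = count_correct_negatives([(L1, L1)], (0, L1 + L2), cfg)
        assert cn == int(L1 // 2) + int(L2 // 2)

    def test_per_stretch_mode(self):
        cfg = MatchConfig(cn_mode="per_stretch")
        assert count_correct_negatives([(4.0, 4.5)], (0, 10), cfg) == 2
        assert count_correct_negatives([(1.0, 1.1)], (0, 2.5), cfg) == 0  # both stretches < 2 s
        assert count_correct_negatives([(1.0, 1.1)], (0, 3.5), cfg) == 1


class TestClouds:
    def test_cloud_collapsed_to_first_spot(self):
        items = [(10.0 + 0.1 * k, "head", 1.0 + 0.01 * k, 0.5) for k in range(6)]
        out = collapse_clouds(spot_log(items), MatchConfig())
        assert len(out) == 1
        assert out.entries.iloc[0]["time_s"] == pytest.approx(10.0)

    def test_sparse_spots_untouched(self):
        items = [(10.0 + 2.0 * k, "head", 1.0, 0.5) for k in range(6)]
        out = collapse_clouds(spot_log(items), MatchConfig())
        assert len(out) == 6


class TestPairingOptimality:
    def test_greedy_counterexample_solved_optimally(self):
        # nearest-|dt| greedy would pair (0, 0.5) first and find one pair
        got = _assign(np.array([-1.0, 0.5]), np.array([0.0, 1.0]), 1.0)
        assert len(got) == 2

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 10), max_size=6),
        st.lists(st.floats(0, 10), max_size=6),
    )
    def test_matches_brute_force_cardinality(self, spots, refs):
        spots, refs = np.sort(spots), np.sort(refs)
        assert len(_assign(spots, refs, 1.0)) == brute_force_max_matching(spots, refs, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-50, 50), st.data())
    def test_shift_invariance_of_counts(self, shift, data):
        ts = sorted(data.draw(st.lists(st.floats(0, 30), min_size=1, max_size=8)))
        rs = sorted(data.draw(st.lists(st.floats(0, 30), min_size=1, max_size=8)))
        zones = ["head", "trough", "fence"]
        sp0 = spot_log([(t, zones[i % 3]) for i, t in enumerate(ts)])
        au0 = audible_log([(t, "Sow in crate") for t in rs])
        sp1 = spot_log([(t + shift, zones[i % 3]) for i, t in enumerate(ts)])
        au1 = audible_log([(t + shift, "Sow in crate") for t in rs])
        c0 = match_sound(sp0, au0, (0, 31)).counts()
        c1 = match_sound(sp1, au1, (shift, 31 + shift)).counts()
        assert c0 == c1

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_policy_invariants_on_random_instances(self, data):
        ts = sorted(data.draw(st.lists(st.floats(0, 20), max_size=8)))
        rs = sorted(data.draw(st.lists(st.floats(0, 20), max_size=8)))
        zones = ["head", "trough", "fence", "rump"]
        labels = ["Sow in crate", "Trough", "Metal fence"]
        sp = spot_log([(t, zones[i % 4]) for i, t in enumerate(ts)])
        au = audible_log([(t, labels[i % 3]) for i, t in enumerate(rs)])
        r = match_sound(sp, au, (0, 21))
        fn, cp = r.counts("wrong_as_FN"), r.counts("wrong_as_CP")
        assert fn.FP == cp.FP and fn.CN == cp.CN
        assert fn.CP + fn.FN == cp.CP + cp.FN
        assert cp.CP >= fn.CP
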