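"""Landscape labels, window segmentation, control inference."""

import logging

import pytest

from riboscan.landscape import EnergyEnvelope
from riboscan.rna_core import parse_dotbracket
from riboscan.synthetic_data import make_planted_label_series
from riboscan.window_classifier import (
    BARRIER_LIMITED,
    CLUSTER,
    FUNNEL,
    ClassifierThresholds,
    Window,
    contains_motif,
    funnel_vicinity,
    functional_opposition,
    infer_control,
    label_from_features,
    motif_from_dotbracket,
    segment_windows,
)


class TestLabelFunction:
    @pytest.mark.parametrize("barrier", [4.99, 5.00, 10.00, 10.01])
    @pytest.mark.parametrize("sc", [0.39, 0.40])
    @pytest.mark.parametrize("alt", [False, True])
    @pytest.mark.parametrize("vic", [False, True])
    def test_total_over_threshold_grid(self, barrier, sc, alt, vic):
        label = label_from_features(sc, barrier, alt, vic)
        if sc < 0.4:
            expected = FUNNEL  # silhouette gate removes two-state labels
        elif barrier < 5.0:
            expected = FUNNEL
        elif barrier > 10.0:
            expected = CLUSTER
        else:  # the closed 5-10 band
            expected = BARRIER_LIMITED if (alt and vic) else FUNNEL
        assert label == expected

    def test_single_basin_is_funnel(self):
        assert label_from_features(None, None, True, True) == FUNNEL
        assert label_from_features(0.8, None, True, True) == FUNNEL


class TestVicinity:
    def test_strictly_decreasing_into_minimum(self):
        env = EnergyEnvelope(bin_width=1, env={0: -1, 1: -3, 2: -6, 3: -4, 4: -2})
        assert funnel_vicinity(env, 2)

    def test_bump_next_to_minimum(self):
        env = EnergyEnvelope(bin_width=1, env={0: -1, 1: -5, 2: -6, 3: -7, 4: -2})
        # approaching bin 3 from the left: -1, -5, -6 ok; right side -2 above... fine;
        # but approaching bin 1 has the deeper bin 2 beyond it -> bump
        assert funnel_vicinity(env, 3)
        assert not funnel_vicinity(env, 1)

    def test_single_bin_vacuous(self):
        env = EnergyEnvelope(bin_width=1, env={5: -4})
        assert funnel_vicinity(env, 5)

    def test_span_limits_the_check(self):
        # a bump 4 bins away is outside the default span of 3
        env = EnergyEnvelope(
            bin_width=1, env={0: -9, 1: -2, 2: -3, 3: -4, 4: -5, 5: -6}
        )
        assert funnel_vicinity(env, 5, span=3)
        assert not funnel_vicinity(env, 5, span=5)


class TestMotifs:
    def test_fraction_counting(self):
        s = parse_dotbracket("((((....))))")
        full = motif_from_dotbracket("helix", "((((....))))")
        assert contains_motif(s, full) == 1.0
        disjoint = motif_from_dotbracket("other", "..((.....)).")  # (3,12),(4,11)
        assert contains_motif(s, disjoint) == 0.0
        # 2 of 4 required pairs present
        from riboscan.rna_core import BasePair
        from riboscan.window_classifier import MotifSpec

        half = MotifSpec(
            name="half",
            required_pairs=frozenset(
                {BasePair(1, 12), BasePair(2, 11), BasePair(1, 8), BasePair(2, 7)}
            ),
        )
        assert contains_motif(s, half) == 0.5

    def test_out_of_range_motif(self):
        s = parse_dotbracket("(((...)))")
        m = motif_from_dotbracket("long", "((........))")
        with pytest.raises(ValueError, match="beyond"):
            contains_motif(s, m)

    def test_opposition_true_for_distinct_motifs(self):
        term = motif_from_dotbracket("terminator", "((((....))))........")
        anti = motif_from_dotbracket("antiterminator", "........((((....))))")
        a = parse_dotbracket("((((....))))........")
        b = parse_dotbracket("........((((....))))")
        assert functional_opposition(a, b, [term, anti])

    def test_opposition_false_for_same_motif(self):
        term = motif_from_dotbracket("terminator", "((((....))))........")
        anti = motif_from_dotbracket("antiterminator", "........((((....))))")
        a = parse_dotbracket("((((....))))........")
        assert not functional_opposition(a, a, [term, anti])

    def test_no_motifs_warns_and_returns_false(self, caplog):
        a = parse_dotbracket("(((...)))")
        with caplog.at_level(logging.WARNING):
            assert not functional_opposition(a, a, [])
        assert "no functional motifs" in caplog.text

    def test_partial_coverage_respects_min_fraction(self):
        term = motif_from_dotbracket("terminator", "((((....))))........")
        anti = motif_from_dotbracket("antiterminator", "........((((....))))")
        # medoid a holds 3 of 4 terminator pairs (75% < 80% default)
        a = parse_dotbracket("(((......)))........")
        b = parse_dotbracket("........((((....))))")
        assert not functional_opposition(a, b, [term, anti])


class TestSegmentation:
    def test_five_consecutive_barrier_limited(self):
        labels, opp, _ = make_planted_label_series("BBBBB")
        assert segment_windows(labels, opp) == [
            Window(kind="sensing", start_len=100, end_len=104)
        ]

    def test_four_is_not_enough(self):
        labels, opp, _ = make_planted_label_series("BBBB")
        assert segment_windows(labels, opp) == []

    def test_ordered_window_sequence(self):
        labels, opp, true_windows = make_planted_label_series("FFFFFCCCCCBBBBB")
        windows = segment_windows(labels, opp)
        assert [w.kind for w in windows] == ["downhill", "functional", "sensing"]
        assert windows == true_windows

    def test_single_interruption_breaks_a_run(self):
        labels, opp, _ = make_planted_label_series("BBBBFBBBB")
        assert segment_windows(labels, opp) == []

    def test_cluster_run_needs_opposition_everywhere(self):
        labels, opp, _ = make_planted_label_series("CCCCC", opposition_mask="11011")
        assert segment_windows(labels, opp) == []
        labels, opp, _ = make_planted_label_series("CCCCC", opposition_mask="11111")
        assert [w.kind for w in segment_windows(labels, opp)] == ["functional"]

    def test_windows_partition_consistently(self, nprng):
        import numpy as np

        for _ in range(25):
            pattern = "".join(nprng.choice(list("BFC"), size=int(nprng.integers(1, 30))))
            labels, opp, true_windows = make_planted_label_series(pattern)
            windows = segment_windows(labels, opp)
            assert windows == true_windows  # exact recovery on noiseless input
            by_len = {lab.length: lab.label for lab in labels}
            kind_of = {"barrier_limited": "sensing", "funnel": "downhill", "cluster": "functional"}
            covered = set()
            for w in windows:
                for L in range(w.start_len, w.end_len + 1):
                    assert L not in covered  # no overlap
                    covered.add(L)
                    assert kind_of[by_len[L]] == w.kind

    def test_noncontiguous_lengths_rejected(self):
        labels, _, _ = make_planted_label_series("BBBBB")
        with pytest.raises(ValueError):
            segment_windows([labels[0], labels[2], labels[3], labels[4]], None)


class TestControl:
    def test_sensing_early_is_kinetic(self):
        windows = [
            Window("sensing", 156, 171),
            Window("downhill", 172, 179),
            Window("functional", 181, 190),
        ]
        call = infer_control(windows, full_length=190)
        assert call.mechanism == "kinetic"
        assert call.window_order == ("sensing", "downhill", "functional")

    def test_sensing_at_full_length_is_thermodynamic(self):
        windows = [
            Window("downhill", 100, 110),
            Window("functional", 111, 120),
            Window("sensing", 121, 130),
        ]
        assert infer_control(windows, full_length=130).mechanism == "thermodynamic"

    def test_no_sensing_window_is_ambiguous(self):
        windows = [Window("downhill", 100, 110)]
        assert infer_control(windows, full_length=120).mechanism == "ambiguous"
        assert infer_control([], full_length=120).mechanism == "ambiguous"
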