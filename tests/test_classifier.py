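"""Social-marking criteria (a)-(d): searching phase, buzz, discreteness,
repetition, rate band, and the combined conservative decision."""

import math

import numpy as np
import pytest

import nbhfsocial as nh
from conftest import train_from_rates, train_from_times

CRIT = nh.SocialCriteria()


def mushroom_burst(start=0.0, peak=600.0, base=300.0, n=80, train_id="m"):
    rates = [base + (peak - base) * math.sin(math.pi * i / (n - 1)) for i in range(n)]
    return train_from_rates(rates, start=start, train_id=train_id)


def wiggle_burst(start=0.0, mid=500.0, amp=0.3, cycles=3, n=120, train_id="w"):
    rates = [mid * (1 + amp * math.sin(2 * math.pi * cycles * i / (n - 1))) for i in range(n)]
    return train_from_rates(rates, start=start, train_id=train_id)


class TestSearchingPhase:
    def test_constant_fast_burst_has_none(self):
        assert not nh.has_searching_phase(train_from_rates([500.0] * 50), CRIT)

    def test_slow_opening_run_detected(self):
        tr = train_from_rates([50.0] * 20 + [500.0] * 50)
        assert nh.has_searching_phase(tr, CRIT)

    def test_single_slow_ici_tolerated(self):
        rates = [500.0] * 60 + [150.0] + [500.0] * 40
        assert not nh.has_searching_phase(train_from_rates(rates), CRIT)

    def test_tightening_tolerance_is_monotone(self):
        rates = [500.0] * 60 + [150.0] * 5 + [500.0] * 40
        loose = nh.SocialCriteria(max_subthreshold_fraction=0.10)
        tight = nh.SocialCriteria(max_subthreshold_fraction=0.01)
        tr = train_from_rates(rates)
        assert not nh.has_searching_phase(tr, loose)
        assert nh.has_searching_phase(tr, tight)


class TestBuzz:
    def test_rising_terminal_rates_are_a_buzz(self):
        rates = [120.0] * 60 + list(np.linspace(100.0, 600.0, 10))
        assert nh.ends_in_buzz(train_from_rates(rates), CRIT)

    def test_constant_rate_is_not(self):
        assert not nh.ends_in_buzz(train_from_rates([400.0] * 50), CRIT)

    def test_mushroom_rise_fall_is_not(self):
        assert not nh.ends_in_buzz(mushroom_burst(), CRIT)

    def test_short_train_evaluates_false(self):
        assert not nh.ends_in_buzz(train_from_rates([300.0] * 5), CRIT)


class TestDiscreteness:
    def test_isolated_burst_discrete(self):
        tr = mushroom_burst(start=10.0)
        assert nh.is_discrete(tr, [], CRIT)

    def test_small_gap_merges_trains(self):
        a = train_from_rates([300.0] * 50, start=0.0, train_id="a")
        b = mushroom_burst(start=a.end_time + 0.050, train_id="b")  # 50 ms gap
        assert not nh.is_discrete(b, [a], CRIT)

    def test_200ms_gaps_both_sides_discrete(self):
        a = train_from_rates([300.0] * 50, start=0.0, train_id="a")
        b = mushroom_burst(start=a.end_time + 0.200, train_id="b")
        c = train_from_rates([300.0] * 50, start=b.end_time + 0.200, train_id="c")
        assert nh.is_discrete(b, [a, c], CRIT)


class TestRepeats:
    def test_two_similar_mushrooms_count_two(self):
        a = mushroom_burst(start=0.0, train_id="a")
        b = mushroom_burst(start=3.0, train_id="b")
        assert nh.find_repeats(a, [a, b], CRIT) == 2

    def test_lone_burst_counts_one(self):
        a = mushroom_burst()
        assert nh.find_repeats(a, [a], CRIT) == 1

    def test_dissimilar_shapes_do_not_pair(self):
        a = mushroom_burst(train_id="a")
        b = wiggle_burst(start=3.0, n=a.n_clicks, train_id="b")
        assert nh.find_repeats(a, [a, b], CRIT) == 1

    def test_duration_ratio_gate(self):
        a = mushroom_burst(n=40, train_id="a")
        b = mushroom_burst(start=5.0, n=200, train_id="b")  # ~5x longer
        assert nh.find_repeats(a, [a, b], CRIT) == 1


class TestRateBand:
    @pytest.mark.parametrize(
        "rate,expected", [(600.0, True), (1200.0, False), (200.0, True), (150.0, False)]
    )
    def test_band_inclusive(self, rate, expected):
        assert nh.in_rate_band(train_from_rates([rate] * 30), CRIT) is expected


class TestPatternLabel:
    def test_mushroom_and_wiggle_shapes(self):
        assert nh.label_pattern(mushroom_burst()) is nh.Pattern.MUSHROOM
        assert nh.label_pattern(wiggle_burst()) is nh.Pattern.WIGGLE

    def test_flat_profile_is_none(self):
        assert nh.label_pattern(train_from_rates([400.0] * 60)) is nh.Pattern.NONE

    def test_nonsocial_train_rejected(self):
        tr = mushroom_burst().with_label(nh.Label.NONSOCIAL)
        with pytest.raises(ValueError):
            nh.label_pattern(tr)


class TestClassify:
    def _frame_for(self, trains):
        end = 15.0 * math.ceil(max(t.end_time for t in trains) / 15.0 + 1e-9)
        return nh.frame_partition(trains, 0.0, end)

    def test_repeated_mushrooms_are_social(self):
        a = mushroom_burst(start=1.0, train_id="a")
        b = mushroom_burst(start=5.0, train_id="b")
        frames = self._frame_for([a, b])
        res = {r.train_id: r for r in nh.classify([a, b], frames)}
        assert res["a"].decision == "social" and res["b"].decision == "social"
        assert res["a"].pattern is nh.Pattern.MUSHROOM

    def test_lone_burst_fails_repetition(self):
        a = mushroom_burst(start=1.0, train_id="a")
        frames = self._frame_for([a])
        (r,) = nh.classify([a], frames)
        assert r.decision == "nonsocial" and "c_repeat" in r.failed_criteria

    def test_buzz_is_a_hard_veto(self):
        rates = [450.0] * 60 + list(np.linspace(300.0, 900.0, 12))
        a = train_from_rates(rates, start=1.0, train_id="a")
        b = train_from_rates(rates, start=6.0, train_id="b")
        frames = self._frame_for([a, b])
        res = {r.train_id: r for r in nh.classify([a, b], frames)}
        for r in res.values():
            assert r.decision == "nonsocial"
            assert "a_buzz" in r.failed_criteria

    def test_empty_input_empty_output(self):
        assert nh.classify([], []) == []

    def test_deterministic_decisions(self):
        a = mushroom_burst(start=1.0, train_id="a")
        b = mushroom_burst(start=5.0, train_id="b")
        frames = self._frame_for([a, b])
        r1 = nh.classify([a, b], frames)
        r2 = nh.classify([a, b], frames)
        assert [(r.train_id, r.decision, r.failed_criteria) for r in r1] == [
            (r.train_id, r.decision, r.failed_criteria) for r in r2
        ]

    def test_tightening_criteria_never_increases_social_count(self, easy5):
        """Conservatism: stricter similarity and slow-click tolerance can only
        shrink the set of social marks."""
        cfg, trains, truth, base = easy5
        strict = nh.SocialCriteria(max_subthreshold_fraction=0.02, similarity_min=0.9)
        stricter = nh.classify_deployment(
            trains, cfg.duration_days * 86400.0, nh.FilterConfig(), strict
        )
        n_base = sum(r.decision == "social" for r in base)
        n_strict = sum(r.decision == "social" for r in stricter)
        assert n_strict <= n_base
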