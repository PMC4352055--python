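"""Pyramid arithmetic, trace generation, and the threaded scheduler."""

import numpy as np
import pytest

from cogmap.task_models import (
    MODULES,
    MULTITASK_CONDITIONS,
    AlgebraParams,
    DemandTrace,
    MultitaskParams,
    TrialSpec,
    count_carries,
    generate_algebra_session,
    generate_algebra_trace,
    generate_multitask_session,
    generate_multitask_trace,
    pyramid_solve,
    pyramid_value,
)


def assert_serial(trace: DemandTrace):
    """Every module's intervals are sorted and pairwise disjoint."""
    for module in trace.active_modules():
        ivs = trace.module_intervals(module)
        for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
            assert a0 < b0 and a1 < b1
            assert b0 <= a1 + 1e-12, f"{module} overlaps at {b0:.3f}"


class TestPyramidArithmetic:
    @pytest.mark.parametrize(
        "base,height,value",
        [(4, 3, 9), (4, 2, 7), (9, 5, 35), (9, 3, 24), (5, 1, 5), (9, 2, 17)],
    )
    def test_pyramid_value(self, base, height, value):
        assert pyramid_value(base, height) == value

    @pytest.mark.parametrize("base", range(2, 12))
    def test_two_term_closed_form(self, base):
        assert pyramid_value(base, 2) == 2 * base - 1

    @pytest.mark.parametrize("bad", [(3, 5), (0, 1), (4, 0), (-2, 1)])
    def test_invalid_problems_rejected(self, bad):
        with pytest.raises(ValueError):
            pyramid_value(*bad)

    def test_solve_for_value_chain(self):
        sol = pyramid_solve(base=4, height=3, value=None)
        assert sol.answer == 9
        assert sol.chain == [(4, 3, 7), (7, 2, 9)]
        assert sol.exact

    def test_solve_for_height(self):
        assert pyramid_solve(base=5, height=None, value=9).answer == 2

    def test_solve_for_height_inverse_consistency(self):
        # brute-force oracle: solving for height must invert pyramid_value
        for b in range(4, 10):
            for h in range(2, min(b, 5) + 1):
                v = sum(b - i for i in range(h))
                assert pyramid_solve(base=b, height=None, value=v).answer == h

    def test_solve_for_base_guess_and_check(self):
        # brute force over bases 4..9 gives 8 for x $ 4 = 26
        truth = [b for b in range(4, 10) if pyramid_value(b, 4) == 26]
        assert truth == [8]
        sol = pyramid_solve(base=None, height=4, value=26)
        assert sol.answer == 8 and sol.exact

    def test_solve_unsolvable_flags_not_raises(self):
        sol = pyramid_solve(base=5, height=None, value=1000)
        assert not sol.exact and sol.answer == -1

    def test_solve_requires_single_unknown(self):
        with pytest.raises(ValueError):
            pyramid_solve(base=4, height=3, value=9)

    @pytest.mark.parametrize(
        "chain,n",
        [
            ([(9, 8, 17), (17, 7, 24)], 2),
            ([(4, 3, 7), (7, 2, 9)], 0),
            ([(9, 8, 17), (17, 7, 24), (24, 6, 30), (30, 5, 35)], 3),
            ([], 0),
        ],
    )
    def test_count_carries(self, chain, n):
        # column-addition oracle: carry iff the units digits sum to >= 10
        oracle = sum(1 for a, b, *_ in [(c[0], c[1]) for c in chain]
                     if a % 10 + b % 10 >= 10)
        assert count_carries(chain) == n == oracle


class TestAlgebraTraces:
    def trial(self, base, height, unknown="value"):
        payload = {"base": base, "height": height,
                   "value": pyramid_value(base, height)}
        payload[unknown] = None
        return TrialSpec("c", 0.0, 30.0, payload)

    def test_declarative_count_matches_chain_length(self, rng):
        trace, _ = generate_algebra_trace(self.trial(4, 3), AlgebraParams(), rng)
        assert trace.n_events("declarative") == 2  # chain 4+3, 7+2

    def test_three_visual_encodes_and_manual_response(self, rng):
        trace, _ = generate_algebra_trace(self.trial(4, 3), AlgebraParams(), rng)
        assert trace.n_events("visual") == 3
        # answer 9 has one digit -> one digit click + submit
        assert trace.n_events("manual_right") == 2

    def test_rt_is_sum_of_step_durations(self, rng):
        trace, rt = generate_algebra_trace(self.trial(6, 4), AlgebraParams(), rng)
        total = sum(trace.total_duration(m) for m in trace.active_modules())
        assert rt == pytest.approx(total)
        assert rt == pytest.approx(
            max(b for ivs in trace.intervals.values() for _, b in ivs))

    def test_carry_adds_problem_state_interval(self, rng):
        p = AlgebraParams(retrieval_shape=None)
        t_nocarry, _ = generate_algebra_trace(self.trial(4, 3), p, rng)
        t_carry, _ = generate_algebra_trace(self.trial(9, 3), p, rng)
        # same chain length (2 additions) but 9$3 has two carries
        assert t_carry.n_events("problem_state") == \
            t_nocarry.n_events("problem_state") + 2

    def test_traces_serial(self, rng):
        for b, h in [(4, 2), (9, 5), (7, 4)]:
            for unknown in ("value", "height", "base"):
                trace, _ = generate_algebra_trace(
                    self.trial(b, h, unknown), AlgebraParams(), rng)
                assert_serial(trace)

    def test_fixed_retrieval_duration_option(self, rng):
        p = AlgebraParams(retrieval_shape=None)
        trace, _ = generate_algebra_trace(self.trial(9, 5), p, rng)
        durs = {round(b - a, 6) for a, b in trace.module_intervals("declarative")}
        assert durs == {0.483}

    def test_session_counts(self):
        trace, trials, rts = generate_algebra_session(
            AlgebraParams(), np.random.default_rng(0))
        assert len(trials) == 72
        from collections import Counter

        counts = Counter(t.condition for t in trials)
        assert set(counts.values()) == {18}
        assert_serial(trace)
        assert np.all(rts > 0)

    def test_session_reproducible(self):
        a = generate_algebra_session(AlgebraParams(), np.random.default_rng(5))
        b = generate_algebra_session(AlgebraParams(), np.random.default_rng(5))
        assert a[0].intervals == b[0].intervals
        assert np.array_equal(a[2], b[2])


class TestMultitaskTraces:
    def test_track_uses_only_visual_and_manual(self):
        trace = generate_multitask_trace("track", MultitaskParams(),
                                         np.random.default_rng(1))
        assert trace.n_events("aural") == 0
        assert trace.n_events("declarative") == 0
        assert trace.n_events("visual") > 0
        assert trace.n_events("manual_right") > 0

    def test_count_has_twenty_tone_onsets_within_trial(self):
        trace = generate_multitask_trace("count", MultitaskParams(),
                                         np.random.default_rng(1))
        onsets = [a for a, _ in trace.module_intervals("aural")]
        assert len(onsets) == 20
        assert all(0 <= a < 30.0 for a in onsets)

    def test_high_tone_count_range_over_seeded_trials(self):
        rng = np.random.default_rng(42)
        p = MultitaskParams()
        for _ in range(300):
            trace = generate_multitask_trace("count", p, rng)
            # each high tone updates the counter; responses echo the count
            n_high = trace.n_events("problem_state")
            assert 10 <= n_high <= 17
            assert trace.n_events("manual_right") == n_high

    def test_nback_letter_schedule(self):
        p = MultitaskParams()
        trace = generate_multitask_trace("nback", p, np.random.default_rng(1))
        onsets = [a for a, _ in trace.module_intervals("visual")]
        assert len(onsets) == 12
        assert onsets == pytest.approx([k * 2.5 for k in range(12)])
        assert trace.n_events("declarative") == 10  # retrieval from letter 3 on
        assert trace.n_events("manual_left") == 12

    def test_swap_only_when_both_tasks_hold_state(self):
        p = MultitaskParams()
        both = generate_multitask_trace("nback+count", p, np.random.default_rng(2))
        single = generate_multitask_trace("track+nback", p, np.random.default_rng(2))
        nback_only = generate_multitask_trace("nback", p, np.random.default_rng(2))
        assert single.n_events("declarative") == nback_only.n_events("declarative")
        assert both.n_events("declarative") > nback_only.n_events("declarative")

    @pytest.mark.parametrize("condition", MULTITASK_CONDITIONS)
    def test_scheduler_seriality(self, condition):
        trace = generate_multitask_trace(condition, MultitaskParams(),
                                         np.random.default_rng(3))
        assert_serial(trace)

    def test_equal_seed_bitwise_reproducible(self):
        p = MultitaskParams()
        a = generate_multitask_trace("nback+count", p, np.random.default_rng(9))
        b = generate_multitask_trace("nback+count", p, np.random.default_rng(9))
        assert a.intervals == b.intervals

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="condition"):
            generate_multitask_trace("juggle", MultitaskParams(),
                                     np.random.default_rng(0))

    def test_session_counts(self):
        trace, trials = generate_multitask_session(
            MultitaskParams(), np.random.default_rng(0))
        assert len(trials) == 72
        from collections import Counter

        assert set(Counter(t.condition for t in trials).values()) == {12}
        assert_serial(trace)


class TestDemandTrace:
    def test_rejects_unknown_module(self):
        with pytest.raises(ValueError, match="unknown module"):
            DemandTrace("r", {"telepathy": [(0.0, 1.0)]})

    def test_rejects_overlap(self):
        with pytest.raises(ValueError, match="overlap"):
            DemandTrace("r", {"visual": [(0.0, 2.0), (1.0, 3.0)]})

    def test_rejects_negative_or_empty_interval(self):
        with pytest.raises(ValueError):
            DemandTrace("r", {"visual": [(-1.0, 1.0)]})
        with pytest.raises(ValueError):
            DemandTrace("r", {"visual": [(2.0, 2.0)]})

    def test_sorts_intervals(self):
        t = DemandTrace("r", {"visual": [(3.0, 4.0), (0.0, 1.0)]})
        assert t.module_intervals("visual") == [(0.0, 1.0), (3.0, 4.0)]
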