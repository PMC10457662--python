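import numpy as np
import pytest

from blockalign import (GLOBAL, NEG_INF, XDROP, AlignParams, align,
                        full_dp_oracle, make_dna_scheme, pssm_from_sequence)
from blockalign.block_driver import (BlockState, decide_shift, grow_trigger,
                                     shrink_trigger, xdrop_check)
from blockalign.dp_core import DpRegionState
from blockalign.traceback import DOWN, RIGHT, cigar_score

from conftest import random_seq


class TestAlignParams:
    def test_rejects_non_power_of_two(self):
        with pytest.raises(ValueError):
            AlignParams(b_min=33, b_max=64)

    def test_rejects_bad_ordering(self):
        with pytest.raises(ValueError):
            AlignParams(b_min=64, b_max=32)

    def test_rejects_small_bmin(self):
        with pytest.raises(ValueError):
            AlignParams(b_min=8, b_max=32, s=8)

    def test_xdrop_needs_threshold(self):
        with pytest.raises(ValueError):
            AlignParams(mode=XDROP, x=None)


class TestDecideShift:
    def _state_with_borders(self, right_vals, bottom_vals, b=16):
        st = BlockState(i=0, j=0, b=b)
        dp = DpRegionState()
        dp.origin = False
        dp.update_col_border(b - 1, 0, np.array(right_vals, dtype=np.int64),
                             np.full(len(right_vals), NEG_INF, dtype=np.int64))
        dp.update_row_border(b - 1, 0, np.array(bottom_vals, dtype=np.int64),
                             np.full(len(bottom_vals), NEG_INF, dtype=np.int64),
                             np.full(len(bottom_vals), NEG_INF, dtype=np.int64))
        return st, dp

    def test_right_wins(self):
        st, dp = self._state_with_borders([10] * 16, [7] * 16)
        assert decide_shift(st, dp, 8) == RIGHT

    def test_down_wins(self):
        st, dp = self._state_with_borders([7] * 16, [10] * 16)
        assert decide_shift(st, dp, 8) == DOWN

    def test_tie_breaks_right(self):
        st, dp = self._state_with_borders([5] * 16, [5] * 16)
        assert decide_shift(st, dp, 8) == RIGHT

    def test_only_first_s_cells_compared(self):
        # huge score beyond the S topmost right-border cells must not count
        right = [0] * 16
        right[12] = 99
        st, dp = self._state_with_borders(right, [1] * 16)
        assert decide_shift(st, dp, 8) == DOWN


class TestGrowShrinkPredicates:
    @pytest.mark.parametrize("b,steps,expected", [
        (32, 3, True),   # Y = 32/8 - 1 = 3
        (32, 2, False),
        (64, 7, True),   # Y = 7
        (64, 6, False),
    ])
    def test_grow_trigger_threshold(self, b, steps, expected):
        st = BlockState(b=b, steps_since_improve=steps)
        assert grow_trigger(st, AlignParams(b_min=32, b_max=256)) is expected

    def test_no_grow_at_bmax(self):
        st = BlockState(b=256, steps_since_improve=1000)
        assert not grow_trigger(st, AlignParams(b_min=32, b_max=256))

    def test_shrink_corner_cells_enumerated(self):
        # S=8 -> the S/4 = 2 rightmost bottom-border cells and 2 bottom-most
        # right-border cells trigger; everything else does not
        params = AlignParams(b_min=32, b_max=256)
        b = 64
        corner = {(b - 1, b - 1), (b - 1, b - 2), (b - 2, b - 1)}
        for di in range(b - 4, b):
            for dj in range(b - 4, b):
                st = BlockState(i=0, j=0, b=b, max_pos=(di, dj))
                assert shrink_trigger(st, params) == ((di, dj) in corner)

    def test_no_shrink_at_bmin(self):
        st = BlockState(b=32, max_pos=(31, 31))
        assert not shrink_trigger(st, AlignParams(b_min=32, b_max=256))

    def test_no_shrink_when_max_outside_block(self):
        st = BlockState(i=100, j=100, b=64, max_pos=(63, 63))
        assert not shrink_trigger(st, AlignParams(b_min=32, b_max=256))


class TestXdropCheck:
    def _params(self):
        return AlignParams(mode=XDROP, x=50, b_min=32, b_max=32)

    def test_two_consecutive_strikes_terminate(self):
        st = BlockState(max_score=100, curr_score=45)
        p = self._params()
        assert not xdrop_check(st, p)
        assert xdrop_check(st, p)

    def test_recovery_resets_counter(self):
        st = BlockState(max_score=100, curr_score=45)
        p = self._params()
        assert not xdrop_check(st, p)
        st.curr_score = 90
        assert not xdrop_check(st, p)
        assert st.xdrop_strikes == 0

    def test_global_mode_never_terminates(self):
        st = BlockState(max_score=100, curr_score=-10**6)
        assert not xdrop_check(st, AlignParams(mode=GLOBAL))


class TestAlignGlobal:
    def test_perfect_match_in_one_block(self, dna24):
        res = align("ACGTACGT", "ACGTACGT", AlignParams(b_min=16, b_max=16),
                    matrix=dna24, g_open=-4, g_ext=-2)
        assert res.score == 16 and res.cigar == "8M"

    def test_single_cell(self, dna24):
        res = align("A", "A", matrix=dna24, g_open=-4, g_ext=-2)
        assert res.score == 2 and res.cigar == "1M"
        assert res.end_pos == (1, 1)

    def test_exact_at_full_coverage(self, dna24):
        """b_min = b_max = 512 >= matrix: identical to the oracle."""
        rng = np.random.default_rng(31)
        params = AlignParams(b_min=512, b_max=512)
        for _ in range(15):
            q = random_seq(rng, int(rng.integers(1, 200)))
            p = random_seq(rng, int(rng.integers(1, 200)))
            pssm = pssm_from_sequence(p, dna24, -4, -2)
            assert align(q, pssm, params).score == full_dp_oracle(q, pssm)[0]

    def test_feasibility_bound(self, dna24):
        """The block score is a feasible alignment: never above the oracle."""
        rng = np.random.default_rng(37)
        for _ in range(25):
            n = int(rng.integers(50, 300))
            p = random_seq(rng, n)
            # mutate heavily so the block path can be suboptimal
            q = "".join(c if rng.random() > 0.25
                        else str(rng.choice(list("ACGT"))) for c in p)
            pssm = pssm_from_sequence(p, dna24, -4, -2)
            res = align(q, pssm, AlignParams(b_min=32, b_max=32))
            assert res.score <= full_dp_oracle(q, pssm)[0]
            assert cigar_score(res.cigar, q, pssm) == res.score

    def test_global_cigar_consumes_everything(self, dna24):
        rng = np.random.default_rng(41)
        for _ in range(10):
            q = random_seq(rng, int(rng.integers(10, 150)))
            p = random_seq(rng, int(rng.integers(10, 150)))
            res = align(q, p, AlignParams(b_min=32, b_max=64), matrix=dna24,
                        g_open=-4, g_ext=-2)
            assert res.cigar.query_span() == len(q)
            assert res.cigar.target_span() == len(p)

    def test_deterministic_replay(self, dna24):
        q = random_seq(np.random.default_rng(5), 400)
        p = random_seq(np.random.default_rng(6), 380)
        pssm = pssm_from_sequence(p, dna24, -4, -2)
        params = AlignParams(b_min=32, b_max=128)
        a = align(q, pssm, params)
        b = align(q, pssm, params)
        assert a.score == b.score and str(a.cigar) == str(b.cigar)
        assert a.stats == b.stats

    def test_empty_query_rejected(self, dna24):
        with pytest.raises(ValueError):
            align("", "ACGT", matrix=dna24, g_open=-4, g_ext=-2)


class TestGapSpanning:
    """Growing lets a small starting block span a long deletion; a fixed
    small block cannot (the grow-ablation contrast)."""

    def _gap_pair(self, gap=300, n=1000, seed=2):
        rng = np.random.default_rng(seed)
        p = random_seq(rng, n)
        q = p[:350] + p[350 + gap:]
        return q, p

    def test_growing_spans_long_deletion(self, dna24):
        q, p = self._gap_pair()
        pssm = pssm_from_sequence(p, dna24, -4, -2)
        res = align(q, pssm, AlignParams(b_min=32, b_max=1024))
        assert res.score == full_dp_oracle(q, pssm)[0]
        assert res.stats["grows"] >= 1
        assert cigar_score(res.cigar, q, pssm) == res.score

    def test_fixed_small_block_is_strictly_suboptimal(self, dna24):
        q, p = self._gap_pair()
        pssm = pssm_from_sequence(p, dna24, -4, -2)
        res = align(q, pssm, AlignParams(b_min=32, b_max=32))
        assert res.score < full_dp_oracle(q, pssm)[0]


class TestAlignXdrop:
    def test_stops_after_divergence(self, dna24):
        q = "ACGTACGTAC" + "T" * 40
        p = "ACGTACGTAC" + "G" * 40
        res = align(q, p, AlignParams(mode=XDROP, x=10, b_min=16, b_max=16),
                    matrix=dna24, g_open=-4, g_ext=-2)
        assert res.score == 20 and res.end_pos == (10, 10)
        assert res.cigar == "10M"

    def test_xdrop_never_exceeds_unpruned_maximum(self, dna24):
        rng = np.random.default_rng(43)
        for _ in range(10):
            q = random_seq(rng, int(rng.integers(20, 150)))
            p = random_seq(rng, int(rng.integers(20, 150)))
            pssm = pssm_from_sequence(p, dna24, -4, -2)
            res = align(q, pssm, AlignParams(mode=XDROP, x=30, b_min=32,
                                             b_max=64))
            assert res.score <= full_dp_oracle(q, pssm, mode=XDROP)[0]
            if res.score > 0:
                assert cigar_score(res.cigar, q, pssm) == res.score


class TestClamp16:
    def test_identical_when_no_clamp_occurs(self, dna24):
        rng = np.random.default_rng(47)
        for _ in range(8):
            q = random_seq(rng, 120)
            p = random_seq(rng, 120)
            pssm = pssm_from_sequence(p, dna24, -4, -2)
            plain = align(q, pssm, AlignParams(b_min=32, b_max=64))
            clamped = align(q, pssm, AlignParams(b_min=32, b_max=64,
                                                 clamp16=True))
            assert plain.score == clamped.score
            assert str(plain.cigar) == str(clamped.cigar)


class TestSpaceContract:
    def test_live_borders_stay_order_bmax(self, dna24):
        """Border arrays never exceed O(Bmax) cells while aligning."""
        from blockalign import block_driver, dp_core

        max_seen = 0
        orig = dp_core.compute_rect

        def spy(state, rect, q, pssm, orientation=RIGHT, trace=None, L=16):
            nonlocal max_seen
            out = orig(state, rect, q, pssm, orientation, trace, L)
            for b in (state.col_border, state.row_border):
                if b is not None:
                    max_seen = max(max_seen, len(b.D))
            return out

        q = random_seq(np.random.default_rng(51), 600)
        p = random_seq(np.random.default_rng(52), 600)
        block_driver.compute_rect = spy
        try:
            align(q, p, AlignParams(b_min=32, b_max=128), matrix=dna24,
                  g_open=-4, g_ext=-2)
        finally:
            block_driver.compute_rect = orig
        assert 0 < max_seen <= 128


class TestGrowShrinkOps:
    def test_grow_doubles_from_checkpoint(self):
        from blockalign.block_driver import Checkpoint, grow
        dp = DpRegionState()
        from blockalign.traceback import TraceStack
        t = TraceStack()
        ck = Checkpoint(4, 4, 32, dp.snapshot(), 0, (10, 10))
        st = BlockState(i=20, j=28, b=32, max_pos=(30, 30))
        grow(st, ck, dp, t, AlignParams(b_min=32, b_max=256))
        assert (st.b, st.b_prev) == (64, 32)
        assert (st.i, st.j) == (4, 4) and st.dir == "GROW"
        # repeated trigger from the same checkpoint: B doubles again,
        # Bprev stays at the checkpoint's size
        grow(st, ck, dp, t, AlignParams(b_min=32, b_max=256))
        assert (st.b, st.b_prev) == (128, 32)

    def test_grow_caps_at_bmax(self):
        from blockalign.block_driver import Checkpoint, grow
        from blockalign.traceback import TraceStack
        dp = DpRegionState()
        ck = Checkpoint(0, 0, 0, dp.snapshot(), 0, (0, 0))
        st = BlockState(b=128)
        grow(st, ck, dp, TraceStack(), AlignParams(b_min=32, b_max=128))
        assert st.b == 128

    def test_shrink_halves_then_moves_by_new_b(self):
        from blockalign.block_driver import shrink
        from blockalign.traceback import TraceStack
        st = BlockState(i=0, j=0, b=64, steps_since_improve=5)
        ck = shrink(st, DpRegionState(), TraceStack())
        assert (st.i, st.j, st.b) == (32, 32, 32)
        assert st.steps_since_improve == 0
        assert (ck.i, ck.j, ck.b) == (32, 32, 32)

    def test_shrink_arithmetic(self):
        from blockalign.block_driver import shrink
        from blockalign.traceback import TraceStack
        st = BlockState(i=8, j=16, b=32)
        shrink(st, DpRegionState(), TraceStack())
        assert (st.i, st.j, st.b) == (24, 32, 16)
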