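"""Location-record reduction: runs, sweeps, durations, errors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tonguekin.kinematics import (
    KinematicsParams,
    LocationRecord,
    Run,
    UnusableVideoError,
    count_sweeps,
    detect_errors,
    locate_tongue,
    mean_sweep_duration,
    profile,
    run_length_encode,
)
from tonguekin.segmentation import MaskSequence


def record(symbols, fps=30.0):
    return LocationRecord(symbols, fps)


def runs_of(*pairs):
    out, start = [], 0
    for side, n in pairs:
        out.append(Run(side, start, n))
        start += n
    return out


class TestRunLengthEncode:
    @pytest.mark.parametrize(
        "symbols, gap, expected",
        [
            # plain alternating runs
            ("RRRRLLLLRRRR", 3, [("R", 4), ("L", 4), ("R", 4)]),
            # short undetected gap with same-side flanks is absorbed
            ("RRUURRLLLL", 3, [("R", 6), ("L", 4)]),
            # long gap splits, but same-side fragments concatenate
            ("RRUUUUURRLLLL", 3, [("R", 4), ("L", 4)]),
            # discordant flanks: gap dropped, genuine transition remains
            ("RRUULL", 3, [("R", 2), ("L", 2)]),
            # leading and trailing gaps are dropped
            ("UURRLLUU", 3, [("R", 2), ("L", 2)]),
            ("RRRR", 3, [("R", 4)]),
        ],
    )
    def test_encoding(self, symbols, gap, expected):
        runs = run_length_encode(record(symbols), gap_tolerance_frames=gap)
        assert [(r.side, r.length_frames) for r in runs] == expected

    def test_all_undetected_gives_empty_list(self):
        assert run_length_encode(record("UUUU")) == []

    def test_runs_tile_and_alternate(self):
        runs = run_length_encode(record("RRRLLLUULLRR"), 3)
        sides = [r.side for r in runs]
        assert all(a != b for a, b in zip(sides, sides[1:]))


class TestCountSweeps:
    @pytest.mark.parametrize(
        "pairs, n_expected, lengths_expected",
        [
            ([("R", 4), ("L", 4), ("R", 4)], 2, [4.0, 4.0]),
            ([("R", 7)], 0, []),
            ([("L", 3), ("R", 5)], 1, [4.0]),  # 1.5 + 2.5
            ([], 0, []),
        ],
    )
    def test_examples(self, pairs, n_expected, lengths_expected):
        n, lengths = count_sweeps(runs_of(*pairs))
        assert n == n_expected
        assert lengths == pytest.approx(lengths_expected)

    def test_requires_alternation(self):
        with pytest.raises(ValueError, match="alternate"):
            count_sweeps(runs_of(("R", 2), ("R", 2)))

    def test_fractional_halves_are_exact(self):
        _, lengths = count_sweeps(runs_of(("R", 3), ("L", 3)))
        assert lengths == [3.0]  # 1.5 + 1.5, no rounding


class TestMeanSweepDuration:
    def test_frames_to_seconds(self):
        assert mean_sweep_duration([4.0, 4.0], 30) == pytest.approx(4 / 30)
        assert mean_sweep_duration([6.0], 25) == pytest.approx(0.24)

    def test_no_sweeps_is_flagged_absent_not_zero(self):
        assert mean_sweep_duration([], 30) is None

    def test_rejects_bad_fps(self):
        with pytest.raises(ValueError):
            mean_sweep_duration([4.0], 0)


class TestDetectErrors:
    def test_single_long_dwell_is_an_outlier(self):
        # lengths 4 x9 plus 30: mean 6.6, sample SD ~8.22, cut ~23.0 < 30
        runs = runs_of(*[("RL"[i % 2], 4) for i in range(9)], ("L", 30))
        assert detect_errors(runs, k=2.0) == 1

    def test_uniform_runs_have_zero_spread_hence_zero_errors(self):
        runs = runs_of(*[("RL"[i % 2], 5) for i in range(8)])
        assert detect_errors(runs, k=2.0) == 0

    def test_single_run_degenerate(self):
        assert detect_errors(runs_of(("R", 50)), k=2.0) == 0

    def test_matches_hand_rolled_filter(self, rng):
        for _ in range(50):
            lengths = rng.integers(2, 40, size=rng.integers(2, 25))
            runs = runs_of(*[("RL"[i % 2], int(n)) for i, n in enumerate(lengths)])
            m, s = lengths.mean(), lengths.std(ddof=1)
            expected = 0 if s == 0 else int((lengths > m + 2 * s).sum())
            assert detect_errors(runs, k=2.0) == expected


class TestLocateTongue:
    @staticmethod
    def masks_from_columns(cols, width=20, fps=30.0):
        """One 10x`width` mask per entry; None means empty."""
        n = len(cols)
        masks = np.zeros((n, 10, width), dtype=bool)
        for i, c in enumerate(cols):
            if c is not None:
                masks[i, 4:6, c] = True
        return MaskSequence(masks=masks, fps=fps)

    def test_sides_and_undetected(self):
        rec = locate_tongue(self.masks_from_columns([2, 17, None, 2]))
        assert rec.symbols == "LRUL"

    def test_all_empty_masks(self):
        rec = locate_tongue(self.masks_from_columns([None] * 4))
        assert rec.symbols == "UUUU"

    def test_tie_on_midline_without_predecessor_is_undetected(self):
        masks = np.zeros((1, 10, 21), dtype=bool)
        masks[0, 4, 10] = True  # centroid exactly at 10.5 = width * 0.5
        rec = locate_tongue(MaskSequence(masks=masks, fps=30.0))
        assert rec.symbols == "U"

    def test_tie_inherits_previous_side(self):
        masks = np.zeros((2, 10, 21), dtype=bool)
        masks[0, 4, 2] = True
        masks[1, 4, 10] = True
        rec = locate_tongue(MaskSequence(masks=masks, fps=30.0))
        assert rec.symbols == "LL"


class TestProfile:
    def test_composition_example(self):
        prof = profile(record("RRRRLLLLRRRR", fps=30.0))
        assert prof.n_sweeps == 2
        assert prof.mean_sweep_duration_s == pytest.approx(4 / 30)
        assert prof.n_errors == 0
        assert prof.n_runs == 3
        assert prof.n_undetected_frames == 0

    def test_uniform_schedule(self):
        prof = profile(record("".join("RL"[i % 2] * 10 for i in range(13))))
        assert prof.n_sweeps == 12
        assert prof.mean_sweep_duration_s == pytest.approx(10 / 30)

    def test_all_undetected_raises(self):
        with pytest.raises(UnusableVideoError):
            profile(record("UUUU"))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            KinematicsParams(midline_frac=1.5)
        with pytest.raises(ValueError):
            KinematicsParams(gap_tolerance_frames=-1)


u_free_records = st.text(alphabet="LR", min_size=1, max_size=300)


class TestInvariants:
    @settings(derandomize=True, max_examples=200)
    @given(u_free_records)
    def test_sweeps_equal_brute_force_transition_count(self, symbols):
        brute = sum(1 for a, b in zip(symbols, symbols[1:]) if a != b)
        prof = profile(record(symbols))
        assert prof.n_sweeps == brute

    @settings(derandomize=True, max_examples=200)
    @given(u_free_records)
    def test_sweep_length_sum_conservation(self, symbols):
        # sum of sweep lengths = total frames - half of first and last run
        runs = run_length_encode(record(symbols))
        _, lengths = count_sweeps(runs)
        expected = len(symbols) - runs[0].length_frames / 2 - runs[-1].length_frames / 2
        assert sum(lengths) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100)
    @given(u_free_records, st.integers(min_value=1, max_value=20))
    def test_appending_opposite_run_adds_one_sweep(self, symbols, extra):
        before = profile(record(symbols))
        opposite = "L" if symbols[-1] == "R" else "R"
        after = profile(record(symbols + opposite * extra))
        assert after.n_sweeps == before.n_sweeps + 1
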