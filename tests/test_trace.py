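import numpy as np
import pytest

from ecgseg import (
    NoSignalFound,
    TrackingParams,
    extract_page,
    find_seed,
    next_point,
    track_trace,
)
from ecgseg.synth import render_synthetic_page
from ecgseg.preprocess import binarize_page, PreprocessParams
from ecgseg.layout import detect_layout
from .conftest import SMALL_CONFIG, small_spec
from ._oracles import literal_track


def patch_with_line(h, w, row, cols=None):
    patch = np.zeros((h, w), dtype=np.uint8)
    patch[row, cols if cols is not None else slice(None)] = 1
    return patch


class TestFindSeed:
    def test_line_at_baseline_seeds_at_first_column(self):
        patch = patch_with_line(100, 40, row=50)
        assert find_seed(patch, baseline_row=50, alpha=150) == (0, 50)

    def test_window_semantics(self):
        patch = patch_with_line(200, 40, row=110)
        # alpha=150 -> +-75 window catches a line 10 px below the baseline
        assert find_seed(patch, 100, alpha=150) == (0, 110)
        # alpha=10 -> +-5 window misses it
        with pytest.raises(NoSignalFound):
            find_seed(patch, 100, alpha=10)

    def test_first_qualifying_column_wins(self):
        patch = np.zeros((100, 40), dtype=np.uint8)
        patch[50, 7:] = 1
        col, row = find_seed(patch, 50, alpha=150)
        assert (col, row) == (7, 50)

    def test_seed_row_is_median_of_window_ink(self):
        patch = np.zeros((100, 10), dtype=np.uint8)
        patch[[48, 49, 50, 51, 52], 0] = 1
        assert find_seed(patch, 50, alpha=20) == (0, 50)
        patch2 = np.zeros((100, 10), dtype=np.uint8)
        patch2[[48, 49, 51, 52], 0] = 1  # even count -> lower middle
        assert find_seed(patch2, 50, alpha=20) == (0, 49)


class TestNextPoint:
    def test_median_of_five(self):
        patch = np.zeros((60, 3), dtype=np.uint8)
        patch[[18, 19, 20, 21, 22], 1] = 1
        assert next_point(patch, col=1, prev_row=20, beta=75) == 20

    def test_even_count_lower_middle(self):
        patch = np.zeros((60, 3), dtype=np.uint8)
        patch[[18, 19, 21, 22], 1] = 1
        assert next_point(patch, col=1, prev_row=20, beta=75) == 19

    def test_empty_column_returns_none(self):
        patch = np.zeros((60, 3), dtype=np.uint8)
        assert next_point(patch, col=1, prev_row=20, beta=75) is None

    def test_out_of_window_ink_ignored(self):
        patch = np.zeros((100, 3), dtype=np.uint8)
        patch[80, 1] = 1
        assert next_point(patch, col=1, prev_row=20, beta=20) is None


class TestTrackTrace:
    params = TrackingParams(alpha=150, beta=75, gamma=15)

    def test_flat_line_gives_zero_offsets(self):
        patch = patch_with_line(100, 37, row=50)
        offsets, seed_col = track_trace(patch, 50, self.params)
        assert seed_col == 0
        assert offsets.size == 37
        np.testing.assert_array_equal(offsets, 0)

    def test_gap_carry_forward(self):
        patch = np.zeros((100, 80), dtype=np.uint8)
        patch[50, :60] = 1
        patch[50, 70:] = 1
        offsets, _ = track_trace(patch, 50, self.params)
        np.testing.assert_array_equal(offsets, np.zeros(80))

    def test_jump_beyond_gamma_is_rejected_forever(self):
        # offset jumps from 0 to -30, inside the beta window but beyond
        # gamma=15: every candidate past the jump fails validation, so
        # offsets stay 0.
        patch = np.zeros((120, 60), dtype=np.uint8)
        patch[50, :30] = 1
        patch[80, 30:] = 1
        offsets, _ = track_trace(patch, 50, self.params)
        np.testing.assert_array_equal(offsets, np.zeros(60))

    def test_jump_within_gamma_followed(self):
        patch = np.zeros((120, 60), dtype=np.uint8)
        patch[50, :30] = 1
        patch[60, 30:] = 1  # jump of 10 <= gamma
        offsets, _ = track_trace(patch, 50, self.params)
        np.testing.assert_array_equal(offsets[:30], 0)
        np.testing.assert_array_equal(offsets[30:], -10)

    def test_columns_before_seed_filled_with_seed_offset(self):
        patch = np.zeros((100, 50), dtype=np.uint8)
        patch[45, 20:] = 1
        offsets, seed_col = track_trace(patch, 50, self.params)
        assert seed_col == 20
        np.testing.assert_array_equal(offsets[:20], 5)

    def test_no_signal_raises(self):
        with pytest.raises(NoSignalFound):
            track_trace(np.zeros((100, 20), dtype=np.uint8), 50, self.params)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_literal_pseudocode_on_random_patches(self, seed):
        """Two-route check against an unoptimized step-by-step transcription."""
        rng = np.random.default_rng(seed)
        h = int(rng.integers(20, 60))
        w = int(rng.integers(5, 51))
        patch = (rng.random((h, w)) < 0.08).astype(np.uint8)
        baseline = int(rng.integers(0, h))
        params = TrackingParams(
            alpha=int(rng.integers(2, 40)),
            beta=int(rng.integers(2, 30)),
            gamma=int(rng.integers(0, 12)),
        )
        expected = literal_track(patch, baseline, params.alpha, params.beta, params.gamma)
        if expected is None:
            with pytest.raises(NoSignalFound):
                track_trace(patch, baseline, params)
        else:
            offsets, seed_col = track_trace(patch, baseline, params)
            assert seed_col == expected[1]
            np.testing.assert_array_equal(offsets, expected[0])

    @pytest.mark.parametrize("seed", range(5))
    def test_successive_jumps_bounded_by_gamma(self, seed):
        rng = np.random.default_rng(seed + 100)
        patch = (rng.random((80, 120)) < 0.1).astype(np.uint8)
        patch[40, 0] = 1  # guarantee a seed point
        params = TrackingParams(alpha=60, beta=30, gamma=7)
        offsets, seed_col = track_trace(patch, 40, params)
        jumps = np.abs(np.diff(offsets[seed_col:]))
        assert offsets.size == 120
        assert jumps.size == 0 or jumps.max() <= params.gamma


class TestExtractPage:
    def test_sixteen_traces_with_column_major_lead_numbers(self, clean_truth, clean_result):
        traces = clean_result.traces
        assert len(traces) == 16
        # patch 1 carries leads 1, 5, 9 in rows 1-3
        patch1 = [t.lead for t in traces if t.patch_index == 1]
        assert patch1 == [1, 5, 9, None]
        rhythm = [t for t in traces if t.is_rhythm]
        assert len(rhythm) == 4 and all(t.row_index == 4 for t in rhythm)

    def test_trace_lengths_equal_patch_widths(self, clean_result):
        for t in clean_result.traces:
            assert t.offsets.size == t.col_end - t.col_start

    def test_clean_page_mean_abs_error_within_one_pixel(self, clean_truth, clean_result):
        truth_by_key = {(t.patch_index, t.row_index): t for t in clean_truth.traces}
        for det in clean_result.traces:
            tru = truth_by_key[(det.patch_index, det.row_index)]
            a = max(det.col_start, tru.col_start)
            b = min(det.col_end, tru.col_end)
            det_rows = det.baseline_row - det.offsets[a - det.col_start : b - det.col_start]
            tru_rows = tru.baseline_row - tru.offsets[a - tru.col_start : b - tru.col_start]
            assert np.mean(np.abs(det_rows - tru_rows)) <= 1.0

    def test_blank_lead_becomes_missing_not_fatal(self):
        truth = render_synthetic_page(small_spec(seed=5))
        _, mask = binarize_page(truth.page, PreprocessParams(apply_crop=False))
        layout = detect_layout(mask)
        # blank out patch 2's top lead entirely
        a, b = layout.patch_spans[1]
        base = int(np.sort(layout.baselines[1])[0])
        mask[max(0, base - 30) : base + 30, a:b] = 0
        traces = extract_page(mask, layout, SMALL_CONFIG.tracking_params())
        assert len(traces) == 16
        missing = [t for t in traces if t.missing]
        assert [(t.patch_index, t.row_index) for t in missing] == [(2, 1)]

    def test_gap_degradation_never_changes_length(self):
        spec = small_spec(seed=9)
        gappy = small_spec(seed=9, n_random_gaps=4, max_gap=8)
        cfg = SMALL_CONFIG
        for s in (spec, gappy):
            truth = render_synthetic_page(s)
            _, mask = binarize_page(truth.page, PreprocessParams(apply_crop=False))
            layout = detect_layout(mask)
            for t in extract_page(mask, layout, cfg.tracking_params()):
                assert t.missing or t.offsets.size == t.col_end - t.col_start
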