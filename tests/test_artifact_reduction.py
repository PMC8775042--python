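"""Coarse-presence criterion, thresholds and the reduction procedure."""

import numpy as np
import pytest

from cecgclean import (
    TimeSeries,
    ValidationError,
    coarse_artifact_present,
    compute_thresholds,
    extract_clean,
    fluctuation_series,
    make_segment_grid,
    reduce_artifacts,
    reduce_online,
)
from cecgclean.artifact_reduction import TH3
from cecgclean.errors import DegenerateSignalError
from cecgclean.synthetic import CoarseParams, SlowParams, SyntheticConfig, generate_cecg
from oracles import reduction_oracle, th1_oracle


class TestCoarsePresence:
    def test_constant_series_is_quiet(self):
        flag, stat = coarse_artifact_present(np.full(100, 3.0))
        assert not flag
        assert stat == pytest.approx(-3.0)

    def test_dense_square_wave_is_not_sparse_spikes(self):
        # range/2 equals the RMS for an equal-magnitude square wave
        x = 5.0 * np.where(np.arange(1000) % 2 == 0, 1.0, -1.0)
        flag, stat = coarse_artifact_present(x)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert not flag

    def test_sparse_spikes_flagged(self):
        x = np.zeros(1001)
        x[300], x[700] = 4.0, -4.0
        flag, stat = coarse_artifact_present(x)
        assert stat == pytest.approx(4.0 - np.sqrt(32.0 / 1001.0))
        assert flag

    def test_single_spike_flips_quiet_record(self):
        # a lone large transient on a modest ECG-scale record must trip the criterion
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = 0.3 * np.sin(2 * np.pi * np.arange(2000) / 50) + 0.02 * rng.normal(size=2000)
            assert not coarse_artifact_present(x)[0]
            x[int(rng.integers(0, 2000))] += 5.0 * rng.choice([-1.0, 1.0])
            assert coarse_artifact_present(x)[0]


class TestThresholds:
    def _series_profile(self, seed=7):
        series, _ = generate_cecg(
            SyntheticConfig(duration=60.0, coarse=CoarseParams(count=2),
                            slow=SlowParams(count=1), seed=seed)
        )
        grid = make_segment_grid(series.n, int(round(0.5 * series.fs)), "auto", fs=series.fs)
        return series, fluctuation_series(series, grid)

    def test_identities_th2_th3(self):
        series, prof = self._series_profile()
        th = compute_thresholds(series, prof, c=0.25)
        assert th.th2 == th.th1 / 2.0
        assert th.th3 == TH3 == 0.1

    def test_matches_formula_transcription(self):
        series, prof = self._series_profile()
        th = compute_thresholds(series, prof, c=0.25, c1=1.0)
        expected = th1_oracle(series.samples, prof.values, 0.25, 1.0)
        assert th.th1 == pytest.approx(expected, rel=1e-9)

    def test_linearity_in_c1(self):
        series, prof = self._series_profile()
        th1 = compute_thresholds(series, prof, c=0.25, c1=1.0)
        th2 = compute_thresholds(series, prof, c=0.25, c1=2.0)
        assert th2.th1 - th1.th1 == pytest.approx(
            (th1.sd_fd + th1.sd_x) / (th1.sd_fd * th1.sd_x), rel=1e-9
        )

    def test_constant_signal_is_degenerate(self):
        series = TimeSeries(np.full(4000, 1.0), fs=400.0)
        grid = make_segment_grid(series.n, 200, "forward")
        prof = fluctuation_series(series, grid)
        with pytest.raises(DegenerateSignalError):
            compute_thresholds(series, prof)


class TestReduce:
    def test_no_bursts_means_no_coarse_eliminations(self):
        series, _ = generate_cecg(
            SyntheticConfig(duration=60.0, ecg_amp=0.3, coarse=CoarseParams(count=0),
                            slow=SlowParams(count=0), seed=5)
        )
        result = reduce_artifacts(series)
        assert not result.coarse_present
        assert "coarse" not in result.reasons and "adjacent" not in result.reasons

    def test_burst_segments_eliminated_and_oracle_agrees(self):
        series, truth = generate_cecg(
            SyntheticConfig(duration=60.0, coarse=CoarseParams(count=1, amp_range=(5.0, 5.0),
                                                               duration_range=(1.0, 1.0)),
                            slow=SlowParams(count=0), seed=3)
        )
        result = reduce_artifacts(series)
        assert result.coarse_present
        bounds = result.grid.segment_bounds()
        (start, end, _), = truth.artifact_intervals("coarse")
        overlapping = (bounds[:, 0] < end) & (bounds[:, 1] > start)
        # the burst interior must be eliminated
        interior = (bounds[:, 0] >= start) & (bounds[:, 1] <= end)
        assert np.all(~result.kept[interior])
        assert list(result.reasons) == reduction_oracle(series.samples, series.fs)

    def test_prose_adjacency_uses_neighbour_own_fd(self):
        series, _ = generate_cecg(
            SyntheticConfig(duration=60.0, coarse=CoarseParams(count=2), seed=9)
        )
        result = reduce_artifacts(series, adjacency="own")
        th2 = result.thresholds.th2
        for j, reason in enumerate(result.reasons):
            if reason == "adjacent":
                assert result.fd[j] > th2
                assert "coarse" in {
                    result.reasons[k]
                    for k in (j - 1, j + 1)
                    if 0 <= k < len(result.reasons)
                }
        assert list(result.reasons) == reduction_oracle(
            series.samples, series.fs, adjacency="own"
        )

    def test_quiet_record_passes_through_untouched(self):
        rng = np.random.default_rng(0)
        # moderate noise: no rule can fire (stat < 1, F_D well above TH3)
        x = 0.3 * np.sin(2 * np.pi * np.arange(24000) / 40) + 0.05 * rng.normal(size=24000)
        series = TimeSeries(x, fs=400.0)
        result = reduce_artifacts(series)
        if not result.coarse_present and result.thresholds.mean_fd - result.thresholds.sd_fd <= 0.1:
            assert np.all(result.kept)
            np.testing.assert_array_equal(result.cleaned.samples, series.samples)
            np.testing.assert_array_equal(result.index_map, np.arange(series.n))

    def test_oracle_equivalence_on_synthetic_records(self):
        for seed in range(20):
            series, _ = generate_cecg(
                SyntheticConfig(duration=45.0, coarse=CoarseParams(count=2),
                                slow=SlowParams(count=1), seed=seed)
            )
            result = reduce_artifacts(series)
            assert list(result.reasons) == reduction_oracle(series.samples, series.fs), seed

    def test_monotone_in_c_for_positive_first_term(self):
        series, _ = generate_cecg(
            SyntheticConfig(duration=60.0, coarse=CoarseParams(count=3), seed=13)
        )
        counts = []
        for c in (0.15, 0.25, 0.35):
            result = reduce_artifacts(series, c=c)
            th = result.thresholds
            assert ((th.x_max - th.x_min) / 2) ** 2 - th.second_moment >= 0
            counts.append(sum(r == "coarse" for r in result.reasons))
        assert counts[0] >= counts[1] >= counts[2]

    def test_idempotent_at_original_thresholds(self):
        series, _ = generate_cecg(
            SyntheticConfig(duration=60.0, coarse=CoarseParams(count=2), seed=21)
        )
        result = reduce_artifacts(series)
        th = result.thresholds
        sl = result.grid.sl_samples
        cleaned = result.cleaned
        grid2 = make_segment_grid(cleaned.n, sl, result.grid.mode, fs=cleaned.fs)
        fd2 = fluctuation_series(cleaned, grid2).values
        assert not np.any(fd2 > th.th1)

    def test_degenerate_record_returned_unreduced_with_warning(self):
        series = TimeSeries(np.full(4000, 2.0), fs=400.0)
        with pytest.warns(RuntimeWarning):
            result = reduce_artifacts(series)
        assert result.degenerate and np.all(result.kept)
        np.testing.assert_array_equal(result.cleaned.samples, series.samples)

    def test_too_short_record_rejected(self):
        series = TimeSeries(np.random.default_rng(0).normal(size=300), fs=400.0)
        with pytest.raises(ValidationError):
            reduce_artifacts(series)  # under 2 segments at SL=0.5 s


class TestExtractClean:
    def test_all_kept_is_identity(self):
        series = TimeSeries(np.arange(10, dtype=float), fs=2.0)
        grid = make_segment_grid(10, 2, "forward")
        cleaned, index_map = extract_clean(series, grid, np.ones(5, bool))
        np.testing.assert_array_equal(cleaned.samples, series.samples)
        np.testing.assert_array_equal(index_map, np.arange(10))

    def test_none_kept_is_empty(self):
        series = TimeSeries(np.arange(10, dtype=float), fs=2.0)
        grid = make_segment_grid(10, 2, "forward")
        cleaned, index_map = extract_clean(series, grid, np.zeros(5, bool))
        assert cleaned.n == 0 and index_map.size == 0

    def test_alternating_keeps_jump_by_segment_length(self):
        series = TimeSeries(np.arange(12, dtype=float), fs=2.0)
        grid = make_segment_grid(12, 3, "forward")
        kept = np.array([True, False, True, False])
        cleaned, index_map = extract_clean(series, grid, kept)
        np.testing.assert_array_equal(index_map, [0, 1, 2, 6, 7, 8])
        np.testing.assert_array_equal(cleaned.samples, series.samples[index_map])
        gaps = np.diff(index_map)
        assert set(gaps[gaps > 1]) == {4}  # jump of SL+1 at each eliminated block


class TestOnline:
    def test_init_window_matches_batch_prefix(self, short_record):
        series, _ = short_record
        decisions = list(reduce_online([series], init_seconds=50.0))
        init = TimeSeries(series.samples[: int(50 * series.fs)], fs=series.fs)
        batch = reduce_artifacts(init, grid_mode="forward")
        n_init = batch.grid.n_segments
        assert [d.kept for d in decisions[:n_init]] == list(batch.kept)
        assert [d.reason for d in decisions[:n_init]] == list(batch.reasons)

    def test_agreement_with_batch_on_stationary_record(self):
        series, _ = generate_cecg(SyntheticConfig(duration=300.0, seed=3))
        # feed in 1 s chunks to exercise buffering
        fs = series.fs
        chunks = [series.samples[i : i + int(fs)] for i in range(0, series.n, int(fs))]
        online = list(reduce_online(chunks, fs=fs, init_seconds=50.0))
        batch = reduce_artifacts(series, grid_mode="forward")
        n_init = int(50 * fs) // batch.grid.sl_samples
        online_kept = np.array([d.kept for d in online])
        agree = online_kept[n_init:] == batch.kept[n_init : online_kept.size]
        assert np.mean(agree) >= 0.95

    def test_short_stream_rejected(self):
        rng = np.random.default_rng(1)
        chunks = [rng.normal(size=2000) for _ in range(2)]  # 10 s at 400 Hz
        with pytest.raises(ValidationError):
            list(reduce_online(chunks, fs=400.0, init_seconds=50.0))
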