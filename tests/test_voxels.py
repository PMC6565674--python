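import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import zfscreen as z
from zfscreen.voxels import (
    SupervoxelSet,
    VolumeSeries,
    build_supervoxels,
    compute_dff,
    detect_active_supervoxels,
    select_timevarying_voxels,
    time_averaged_signal,
)


class TestTimeAveragedSignal:
    @pytest.mark.parametrize(
        "trace, expected",
        [([1, 1, 1, 1], 0.0), ([0, 2], np.sqrt(2)), ([1, 2, 3], 1.0)],
    )
    def test_hand_values(self, trace, expected):
        assert time_averaged_signal(trace) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=200))
    def test_matches_two_pass_sd_oracle(self, trace):
        f = np.asarray(trace)
        mean = sum(trace) / len(trace)
        oracle = np.sqrt(sum((v - mean) ** 2 for v in trace) / (len(trace) - 1))
        assert time_averaged_signal(f) == pytest.approx(oracle, abs=1e-9, rel=1e-9)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            time_averaged_signal([1.0])


def _volume_from_slice_traces(traces: np.ndarray, shape_yx, rate=20.0):
    """One-slice VolumeSeries whose voxel (0, i//nx, i%nx) has traces[i]."""
    ny, nx = shape_yx
    T = traces.shape[1]
    data = np.zeros((T, 1, ny, nx), dtype=np.float32)
    for i in range(traces.shape[0]):
        data[:, 0, i // nx, i % nx] = traces[i]
    return VolumeSeries(data=data, frame_rate=rate)


class TestTimeVaryingFilter:
    def test_degenerate_slice_keeps_all(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 1, size=100)
        traces = np.tile(base, (9, 1))  # identical signal in every voxel
        vol = _volume_from_slice_traces(traces, (3, 3))
        mask = select_timevarying_voxels(vol, (0.0, 5.0))
        assert mask.all()

    def test_flat_voxel_removed(self):
        rng = np.random.default_rng(1)
        traces = np.vstack([
            10 + rng.normal(0, 1.0, size=(10, 100)),
            np.full((1, 100), 10.0),  # constant voxel: s = 0
        ])
        vol = _volume_from_slice_traces(traces, (1, 11))
        mask = select_timevarying_voxels(vol, (0.0, 5.0))
        assert mask.sum() == 10
        assert not mask[0, 0, 10]

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        traces = np.abs(rng.normal(10, 3, size=(12, 80)))
        vol1 = _volume_from_slice_traces(traces, (3, 4))
        vol2 = _volume_from_slice_traces(traces * 7.3, (3, 4))
        m1 = select_timevarying_voxels(vol1, (0.0, 4.0))
        m2 = select_timevarying_voxels(vol2, (0.0, 4.0))
        assert np.array_equal(m1, m2)


class TestDff:
    def test_constant_trace_is_zero(self):
        dff = compute_dff(np.full(900, 5.0), rate=20.0)
        assert np.allclose(dff, 0.0)

    def test_single_frame_spike_hand_value(self):
        """Spike 10 -> 20 against a 20-s x 20-Hz (400-frame) baseline window."""
        trace = np.full(1200, 10.0)
        trace[600] = 20.0
        dff = compute_dff(trace, rate=20.0, baseline_window=20.0)
        f_baseline = (399 * 10 + 20) / 400
        assert dff[600] == pytest.approx((20 - f_baseline) / f_baseline)
        assert dff[600] == pytest.approx(0.995, abs=1e-3)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        trace = np.abs(rng.normal(50, 5, size=1000)) + 1
        d1 = compute_dff(trace, 20.0)
        d2 = compute_dff(trace * 13.7, 20.0)
        assert np.allclose(d1, d2, atol=1e-10)

    def test_too_short_and_nonpositive_raise(self):
        with pytest.raises(ValueError):
            compute_dff(np.ones(100), rate=20.0)  # shorter than window
        with pytest.raises(ValueError, match="baseline"):
            compute_dff(np.zeros(900), rate=20.0)


class TestBuildSupervoxels:
    def test_two_blocks_recovered(self):
        """Two disjoint 2x2 blocks with block-wise identical, mutually
        independent traces merge into exactly 2 supervoxels."""
        rng = np.random.default_rng(4)
        T = 300
        a, b = rng.normal(size=T), rng.normal(size=T)
        data = np.zeros((T, 1, 8, 8), dtype=np.float32)
        mask = np.zeros((1, 8, 8), dtype=bool)
        for (y, x) in [(1, 1), (1, 2), (2, 1), (2, 2)]:
            data[:, 0, y, x] = 10 + a
            mask[0, y, x] = True
        for (y, x) in [(5, 5), (5, 6), (6, 5), (6, 6)]:
            data[:, 0, y, x] = 10 + b
            mask[0, y, x] = True
        vol = VolumeSeries(data=data, frame_rate=20.0)
        sv = build_supervoxels(vol, mask, seed=0)
        assert sv.n_supervoxels == 2
        member_sets = sorted(
            tuple(sorted(map(tuple, m[:, 1:]))) for m in sv.members
        )
        assert member_sets == [
            ((1, 1), (1, 2), (2, 1), (2, 2)),
            ((5, 5), (5, 6), (6, 5), (6, 6)),
        ]

    def test_singleton_voxel(self):
        rng = np.random.default_rng(5)
        data = np.zeros((100, 1, 4, 4), dtype=np.float32)
        mask = np.zeros((1, 4, 4), dtype=bool)
        data[:, 0, 2, 2] = 10 + rng.normal(size=100)
        mask[0, 2, 2] = True
        vol = VolumeSeries(data=data, frame_rate=20.0)
        sv = build_supervoxels(vol, mask, seed=0)
        assert sv.n_supervoxels == 1
        assert np.array_equal(sv.members[0], [[0, 2, 2]])

    def test_partition_contract(self, wt_recording, atlas11):
        vol, _ = wt_recording
        mask = select_timevarying_voxels(vol, (0.0, 240.0))
        sv = build_supervoxels(vol, mask, atlas=atlas11, seed=0)
        seen = {}
        for k, m in enumerate(sv.members):
            for vox in map(tuple, m):
                assert vox not in seen, "voxel in two supervoxels"
                seen[vox] = k
        assert set(seen) == set(map(tuple, np.argwhere(mask)))
        assert sv.n_supervoxels <= mask.sum()

    def test_empty_mask_raises(self):
        vol = VolumeSeries(np.zeros((10, 1, 4, 4), dtype=np.float32), 20.0)
        with pytest.raises(ValueError):
            build_supervoxels(vol, np.zeros((1, 4, 4), dtype=bool))


class TestSupervoxelRecovery:
    def test_count_and_trace_fidelity(self, wt_recording, atlas11):
        """Supervoxel count within +-20% of planted neurons; mean
        supervoxel-to-truth trace correlation >= 0.9."""
        vol, truth = wt_recording
        mask = np.zeros(atlas11.label_volume.shape, dtype=bool)
        for vox in truth.neuron_voxels:
            mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        sv = build_supervoxels(vol, mask, atlas=atlas11, seed=0)
        n = len(truth.neuron_voxels)
        assert abs(sv.n_supervoxels - n) <= 0.2 * n
        from scipy.signal import lfilter

        decay = np.exp(-1.0 / (1.5 * 20.0))
        cal = lfilter([1.0], [1.0, -decay], truth.spike_counts, axis=1)
        best = []
        for k in range(sv.n_supervoxels):
            rs = [np.corrcoef(sv.traces[k], cal[i])[0, 1] for i in range(n)]
            best.append(max(rs))
        assert np.mean(best) >= 0.9


class TestActiveDetection:
    def _sv_from_raw(self, raw, rate=20.0):
        n = raw.shape[0]
        return SupervoxelSet(
            members=[np.array([[0, 0, i]]) for i in range(n)],
            traces=raw, frame_rate=rate, diameter_um=np.ones(n),
        )

    def test_zero_dff_inactive(self):
        sv = self._sv_from_raw(np.full((1, 1200), 7.0))
        detect_active_supervoxels(sv, (0.0, 60.0))
        assert not sv.active[0]

    def test_planted_transients_detected(self):
        """Transients at 10x the noise SD are flagged in >= 99% of traces."""
        rng = np.random.default_rng(6)
        n, T = 100, 1200
        raw = 100.0 * (1.0 + 0.01 * rng.standard_normal((n, T)))
        for i in range(n):
            for t0 in rng.integers(100, T - 60, size=3):
                raw[i, t0:t0 + 30] += 100.0 * 0.1 * np.exp(-np.arange(30) / 30.0)
        sv = self._sv_from_raw(raw)
        detect_active_supervoxels(sv, (0.0, 60.0))
        assert sv.active.mean() >= 0.99

    def test_plain_noise_rarely_active(self):
        rng = np.random.default_rng(7)
        raw = 100.0 * (1.0 + 0.01 * rng.standard_normal((200, 1200)))
        sv = self._sv_from_raw(raw)
        detect_active_supervoxels(sv, (0.0, 60.0))
        assert sv.active.mean() <= 0.10

    def test_active_fraction_monotone_in_c(self):
        rng = np.random.default_rng(8)
        raw = 100.0 * (1.0 + 0.01 * rng.standard_normal((50, 1200)))
        raw[:25] += 2.0 * rng.random((25, 1200)) ** 8  # skewed excursions
        fractions = []
        for c in (2.0, 3.0, 4.5, 6.0):
            sv = self._sv_from_raw(raw.copy())
            detect_active_supervoxels(sv, (0.0, 60.0), c=c)
            fractions.append(sv.active.mean())
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))


def test_pipeline_scale_invariance(wt_recording, atlas11):
    """Global positive intensity rescaling leaves the reduction unchanged."""
    vol, _ = wt_recording
    T = 3000
    # A power-of-two factor keeps float32 arithmetic exact, so the test
    # probes the pipeline's mathematical scale invariance rather than
    # floating-point tie-breaking in k-means.
    small = VolumeSeries(vol.data[:T], vol.frame_rate, vol.voxel_size)
    scaled = VolumeSeries(vol.data[:T] * 4.0, vol.frame_rate, vol.voxel_size)
    sv1 = z.process_volume(small, atlas11, (0.0, 120.0), seed=1)
    sv2 = z.process_volume(scaled, atlas11, (0.0, 120.0), seed=1)
    assert sv1.n_supervoxels == sv2.n_supervoxels
    assert np.array_equal(sv1.active, sv2.active)
    assert np.allclose(sv1.dff, sv2.dff, atol=1e-5)
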