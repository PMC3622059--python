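"""ROI trace pipeline: binning alignment, ratio pairing, kinetic estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from clsense.imaging import FrameStack
from clsense.traces import (
    ROISet,
    RatioTrace,
    Trace,
    align_binning,
    expression_filter,
    extract_traces,
    gain_balance_factor,
    half_time,
    inhibition_percent,
    normalize_first,
    pair_ratio,
    pearson_r,
    peak_drop_percent,
    steady_state_level,
)


def make_trace(values, channel=500, dt=10.0, roi=1):
    v = np.asarray(values, float)
    return Trace(roi_id=roi, channel=channel, t=np.arange(len(v)) * dt, value=v)


class TestAlignBinning:
    def test_block_mean_downsample(self):
        out = align_binning(np.array([[1.0, 3.0], [5.0, 7.0]]), 1, 2)
        assert np.array_equal(out, [[4.0]])

    def test_replication_upsample(self):
        out = align_binning(np.array([[4.0]]), 2, 1)
        assert np.array_equal(out, [[4.0, 4.0], [4.0, 4.0]])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hnp.arrays(float, (8, 8), elements=st.floats(0, 1e4)))
    def test_down_up_down_idempotent(self, img):
        down = align_binning(img, 1, 4)
        again = align_binning(align_binning(down, 4, 1), 1, 4)
        assert np.allclose(down, again, rtol=1e-12)

    def test_mean_preserved(self):
        img = np.arange(64.0).reshape(8, 8)
        for b in (2, 4, 8):
            assert align_binning(img, 1, b).mean() == pytest.approx(img.mean())

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            align_binning(np.zeros((6, 6)), 2, 3)


def uniform_stack(roi_value, bg_value, labels, channel=500, n=3):
    frames, meta = [], []
    for i in range(n):
        img = np.full(labels.shape, float(bg_value))
        img[labels == 1] = roi_value
        frames.append(img)
        meta.append(dict(t_s=10.0 * i, channel=channel, binning=1))
    return FrameStack(frames=frames, metadata=meta)


class TestExtract:
    labels = np.zeros((8, 8), dtype=int)
    labels[2:4, 2:4] = 1

    def test_background_subtraction(self):
        stack = uniform_stack(150.0, 50.0, self.labels)
        traces = extract_traces(stack, ROISet(self.labels))
        assert np.allclose(traces[0].value, 100.0)

    def test_background_only_roi_reads_zero(self):
        stack = uniform_stack(50.0, 50.0, self.labels)
        traces = extract_traces(stack, ROISet(self.labels))
        assert np.allclose(traces[0].value, 0.0)

    def test_empty_background_rejected(self):
        full = np.ones((4, 4), dtype=int)
        with pytest.raises(ValueError):
            ROISet(full)

    def test_shape_mismatch_rejected(self):
        stack = uniform_stack(1.0, 0.0, np.zeros((6, 6), dtype=int))
        stack.frames[0] = np.zeros((3, 3))
        labels = np.zeros((6, 6), dtype=int)
        labels[0, 0] = 1
        with pytest.raises(ValueError):
            extract_traces(stack, ROISet(labels))


class TestPairRatio:
    def test_simple_division(self):
        f430 = make_trace([100.0, 100.0], channel=430)
        f500 = make_trace([50.0, 50.0], channel=500)
        ratio = pair_ratio(f430, f500, order="500_first")
        assert np.allclose(ratio.r, 2.0)
        assert ratio.dropped == 0

    def test_orphan_frame_dropped_with_count(self):
        f430 = make_trace([], channel=430)
        f500 = make_trace([50.0], channel=500)
        f430.t = np.array([])
        f430.value = np.array([])
        with pytest.warns(UserWarning):
            ratio = pair_ratio(f430, f500, order="500_first")
        assert len(ratio.r) == 0
        assert ratio.dropped == 1

    def test_scale_invariance_and_offset_sensitivity(self):
        """R is invariant to a gain factor; a raw offset distorts it unless
        background subtraction removed it first."""
        rng = np.random.default_rng(0)
        v430 = rng.uniform(900, 1100, 10)
        v500 = rng.uniform(1900, 2100, 10)
        r0 = pair_ratio(make_trace(v430, 430), make_trace(v500)).r
        r_scaled = pair_ratio(
            make_trace(3.7 * v430, 430), make_trace(3.7 * v500)
        ).r
        assert np.allclose(r0, r_scaled, rtol=1e-12)
        r_offset = pair_ratio(
            make_trace(v430 + 500.0, 430), make_trace(v500 + 500.0)
        ).r
        assert not np.allclose(r0, r_offset, rtol=1e-3)


class TestNormalize:
    def test_example(self):
        out = normalize_first(make_trace([2.0, 2.0, 3.0]))
        assert np.allclose(out.value, [0.0, 0.0, 0.5])

    def test_constant_trace_is_flat_zero(self):
        out = normalize_first(make_trace([5.0] * 4))
        assert np.all(out.value == 0.0)

    def test_scale_invariance(self):
        v = [2.0, 2.5, 1.5]
        a = normalize_first(make_trace(v)).value
        b = normalize_first(make_trace([10 * x for x in v])).value
        assert np.allclose(a, b)

    def test_zero_first_value_rejected(self):
        with pytest.raises(ValueError):
            normalize_first(make_trace([0.0, 1.0]))


class TestInhibition:
    def test_flat_trace_gives_zero(self):
        tr = make_trace([100.0] * 6)
        assert inhibition_percent(tr, event_time=35.0) == 0.0

    def test_arithmetic_example(self):
        tr = make_trace([100.0, 100.0, 100.0, 97.2])
        assert inhibition_percent(tr, 25.0) == pytest.approx(2.8, rel=1e-12)

    def test_scale_invariance(self):
        tr = make_trace([100.0, 100.0, 100.0, 90.0])
        big = make_trace([1e4, 1e4, 1e4, 9e3])
        assert inhibition_percent(tr, 25.0) == pytest.approx(
            inhibition_percent(big, 25.0)
        )

    def test_insufficient_baseline_rejected(self):
        with pytest.raises(ValueError):
            inhibition_percent(make_trace([1.0, 2.0]), 15.0)

    def test_peak_drop_uses_window_minimum(self):
        tr = make_trace([100.0, 100.0, 100.0, 95.0, 80.0, 90.0, 99.0])
        assert peak_drop_percent(tr, (30.0, 55.0)) == pytest.approx(20.0)


class TestHalfTime:
    def test_exponential_decay_half_time(self):
        t = np.arange(0, 600.0, 10.0)
        v = 1.0 + 2.0 * np.exp(-t / 100.0)
        tr = Trace(roi_id=1, channel=500, t=t, value=v)
        ht = half_time(tr, peak_time=0.0, baseline_value=1.0)
        assert not ht.extrapolated
        assert ht.minutes * 60.0 == pytest.approx(100.0 * math.log(2), rel=1e-3)

    def test_extrapolation_when_never_crossing(self):
        t = np.arange(0, 300.0, 10.0)
        v = 1.0 + 2.0 * np.exp(-t / 3000.0)
        tr = Trace(roi_id=1, channel=500, t=t, value=v)
        ht = half_time(tr, 0.0, 1.0)
        assert ht.extrapolated
        assert ht.minutes * 60.0 == pytest.approx(3000.0 * math.log(2), rel=1e-6)

    def test_non_decaying_trace_rejected(self):
        t = np.arange(0, 100.0, 10.0)
        tr = Trace(roi_id=1, channel=500, t=t, value=1.0 + 0.01 * t)
        with pytest.raises(ValueError):
            half_time(tr, 0.0, 1.0)


class TestSteadyState:
    def test_constant_trace(self):
        assert steady_state_level(make_trace([5.0] * 7)) == 100.0

    def test_tail_mean_example(self):
        tr = make_trace([100, 98, 97.5, 97.5, 97.5, 97.5, 97.5])
        assert steady_state_level(tr, tail_n=5) == pytest.approx(97.5)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            steady_state_level(make_trace([1.0, 2.0]), tail_n=5)


class TestExpressionFilter:
    def test_boundaries_inclusive(self):
        vals = {1: 700.0, 2: 1000.0, 3: 5000.0, 4: 8000.0, 5: 9000.0}
        kept = expression_filter(vals)
        assert sorted(kept) == [2, 3, 4]

    def test_empty_input(self):
        assert expression_filter({}) == {}


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x)[0][0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0][0] == pytest.approx(-1.0)

    def test_against_covariance_formula(self, rng):
        x = rng.normal(size=60)
        y = 0.3 * x + rng.normal(size=60)
        r, p, n = pearson_r(x, y)[0]
        rx = x - x.mean()
        ry = y - y.mean()
        r_oracle = (rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum())
        assert r == pytest.approx(r_oracle, abs=1e-12)
        assert n == 60

    def test_two_tailed_p_from_t_distribution(self, rng):
        from scipy import stats

        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        r, p, n = pearson_r(x, y)[0]
        t = r * math.sqrt((n - 2) / (1 - r**2))
        p_oracle = 2 * stats.t.sf(abs(t), n - 2)
        assert p == pytest.approx(p_oracle, rel=1e-9)

    def test_strata(self):
        x = np.concatenate([np.arange(10.0), 100 + np.arange(10.0)])
        y = np.concatenate([2 * np.arange(10.0), -np.arange(10.0)])
        out = pearson_r(x, y, strata=[(0, 50), (50, 200)])
        assert out[0][0] == pytest.approx(1.0)
        assert out[1][0] == pytest.approx(-1.0)

    def test_tiny_stratum_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 2.0], [1.0, 2.0])


def test_gain_balance_factor_targets_unity_ratio():
    f430 = make_trace([800.0] * 5, channel=430)
    f500 = make_trace([2000.0] * 5, channel=500)
    k = gain_balance_factor(f430, f500)
    assert k == pytest.approx(0.4)
    assert np.median(f430.value / (f500.value * k)) == pytest.approx(1.0)
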