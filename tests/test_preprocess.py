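"""Filter-stage tests against independent oracles.

The streaming median is checked against a naive sort-then-middle oracle;
the two integer recursions are checked against direct FIR convolution with
their expanded boxcar kernels (exact integer equality).
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from afentropy.preprocess import (
    HIGH_GAIN_SHIFT,
    HighFilterState,
    LOW_GAIN_SHIFT,
    LOW_TAPS,
    LowFilterState,
    MedianState,
    align_and_delta,
    median_step,
)

# FIR-equivalent kernels: H_l = boxcar(16); H_h = boxcar(32) * boxcar(64)
KERNEL_LOW = np.ones(LOW_TAPS, dtype=np.int64)
KERNEL_HIGH = np.convolve(np.ones(32, dtype=np.int64), np.ones(64, dtype=np.int64))


def run_low(xs):
    st_ = LowFilterState()
    return [st_.step(int(x)) for x in xs]


def run_high(xs):
    st_ = HighFilterState()
    return [st_.step(int(x)) for x in xs]


class TestMedian:
    def test_constant_stream(self):
        m = MedianState(8)
        assert all(m.step(800) == 800 for _ in range(50))

    def test_single_outlier_suppressed(self):
        m = MedianState(8)
        outputs = [m.step(x) for x in [800] * 8 + [1600] + [800] * 8]
        assert outputs[-1] == 800

    def test_unprimed_step_raises(self):
        with pytest.raises(RuntimeError):
            median_step(MedianState(8), 800)

    @given(st.lists(st.integers(200, 2000), min_size=1, max_size=400))
    def test_matches_sort_median_oracle(self, xs):
        """Streaming output equals the middle of the sorted 17-window, where
        the window is the last 17 inputs, left-padded with the first value
        (the priming convention)."""
        w = 8
        size = 2 * w + 1
        m = MedianState(w)
        padded = [xs[0]] * (size - 1) + xs
        for i, x in enumerate(xs):
            got = m.step(x)
            window = padded[i : i + size]
            assert got == sorted(window)[w]

    def test_duplicate_heavy_stream(self, rng):
        xs = rng.integers(798, 803, size=500)
        w = 8
        m = MedianState(w)
        padded = [int(xs[0])] * (2 * w) + list(map(int, xs))
        for i, x in enumerate(xs):
            assert m.step(int(x)) == sorted(padded[i : i + 2 * w + 1])[w]


class TestLowFilter:
    def test_dc_gain_cancels(self):
        assert run_low([735] * 40) == [735] * 40

    def test_kernel_sum_is_16(self):
        assert KERNEL_LOW.sum() == 16 == 2**LOW_GAIN_SHIFT

    def test_unscaled_impulse_response_is_boxcar(self):
        """Feeding a unit impulse after a long zero priming exposes the
        16-long boxcar impulse response of the unscaled recursion."""
        st_ = LowFilterState()
        st_.prime(0)
        unscaled = []
        for x in [1] + [0] * 30:
            st_.step(x)
            unscaled.append(st_.xl_unscaled)
        assert unscaled == [1] * 16 + [0] * 15

    @given(st.lists(st.integers(200, 2000), min_size=1, max_size=300))
    def test_matches_fir_convolution(self, xs):
        """With replicate-priming, the recursion equals convolving the
        left-extended input with the 16-tap boxcar, then >> 4."""
        padded = np.array([xs[0]] * (LOW_TAPS - 1) + xs, dtype=np.int64)
        full = np.convolve(padded, KERNEL_LOW)[LOW_TAPS - 1 : LOW_TAPS - 1 + len(xs)]
        assert run_low(xs) == list(full >> LOW_GAIN_SHIFT)


class TestHighFilter:
    def test_dc_gain_cancels(self):
        assert run_high([812] * 150) == [812] * 150

    def test_kernel_properties(self):
        # DC gain 2048 = 2^11; peak of boxcar32*boxcar64 is 32 at lag 31;
        # symmetric kernel of length 95 -> group delay (95-1)/2 = 47
        assert KERNEL_HIGH.sum() == 2048 == 2**HIGH_GAIN_SHIFT
        assert KERNEL_HIGH[31] == 32
        assert len(KERNEL_HIGH) == 95
        assert np.array_equal(KERNEL_HIGH, KERNEL_HIGH[::-1])

    def test_low_kernel_group_delay(self):
        # symmetric 16-tap boxcar -> group delay (16-1)/2 = 7.5 beats
        assert (len(KERNEL_LOW) - 1) / 2 == 7.5

    @given(st.lists(st.integers(200, 2000), min_size=1, max_size=300))
    def test_matches_fir_convolution(self, xs):
        n_hist = HighFilterState.HIST
        padded = np.array([xs[0]] * (n_hist - 1) + xs, dtype=np.int64)
        full = np.convolve(padded, KERNEL_HIGH)[n_hist - 1 : n_hist - 1 + len(xs)]
        assert run_high(xs) == list(full >> HIGH_GAIN_SHIFT)

    def test_state_bounded_for_bounded_input(self, rng):
        xs = rng.integers(1, 10**5, size=2000)
        st_ = HighFilterState()
        for x in xs:
            st_.step(int(x))
            assert 0 <= st_.xh_prev1 <= 10**5 * 2048 < 2**63


class TestAlignment:
    def test_constant_stream_zero_delta(self):
        buf = [800] * 80
        a = align_and_delta(buf, buf, 800)
        assert a.delta_rr == 0 and a.x_prime == a.xl_prime == 800

    def test_lags_are_62_and_47(self):
        x_buf = list(range(1000, 1100))   # value 1099 - lag at the end
        xl_buf = list(range(2000, 2100))
        a = align_and_delta(x_buf, xl_buf, 5)
        assert a.x_prime == 1099 - 62
        assert a.xl_prime == 2099 - 47

    def test_configurable_raw_lag(self):
        x_buf = list(range(100))
        a = align_and_delta(x_buf, x_buf, 0, raw_lag=63)
        assert a.x_prime == 99 - 63

    def test_insufficient_history_raises(self):
        with pytest.raises(RuntimeError):
            align_and_delta([800] * 10, [800] * 10, 800)

    def test_step_transient_matches_offline_oracle(self):
        """A step change in RR produces the same delta-RR trace as aligning
        the full offline-filtered arrays by the printed per-stage delays."""
        xs = [800] * 300 + [1000] * 300
        # streaming pass
        med = MedianState(8)
        low = LowFilterState()
        deltas = []
        x_hist, xl_hist = [], []
        for x in xs:
            xl = low.step(med.step(x))
            x_hist.append(x)
            xl_hist.append(xl)
            if len(x_hist) >= 63:
                deltas.append(
                    align_and_delta(x_hist, xl_hist, 0).delta_rr
                )
        # offline oracle: pad, filter whole arrays, shift by integer lags
        off = [x_hist[i - 62] - xl_hist[i - 47] for i in range(62, len(xs))]
        assert deltas[-len(off):] == off
        # the transient is positive (raw jumps before the smoothed reference)
        assert max(deltas) > 0
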