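"""Stage 1 — streaming pre-filters for the raw RR tachogram.

Three filters run in cascade, all in exact integer arithmetic:

1. A sliding-window median filter (window ``2w + 1``, default 17) that
   suppresses outliers from mis-detected or missed R-wave peaks while
   preserving the sharp rhythm transitions at AF onsets/terminations.
   The sorted window is maintained incrementally with two binary searches
   per beat (evict the departing sample, insert the new one).
2. A 16-tap boxcar low-pass, implemented by the recursion
   ``xl[n] = xl[n-1] + y[n] - y[n-16]`` (transfer function
   ``(1 - z^-16)/(1 - z^-1)``, DC gain 16 = 2^4, group delay 7.5 beats).
   It smooths the median output and removes respiratory sinus arrhythmia
   scale fluctuations; the gain is offset with a right shift by 4.
3. A cascade of a 32-tap and a 64-tap boxcar
   (``(1 - z^-32 - z^-64 + z^-96)/(1 - z^-1)^2``, DC gain 2048 = 2^11,
   group delay 47 beats) producing the slowly varying high-scale reference
   ``xh``; gain offset is a right shift by 11.

Relative to the high-scale reference clock, the raw series lags 62.5 beats
(8 median + 7.5 low-pass + 47 high-pass) and the low-scale reference lags
47 beats. :func:`align_and_delta` applies these lags (the half-beat is
floored to 62 by default) and forms ``delta_rr = x' - xl'``, the quantity
the symbolic stage consumes.

All filter histories are primed by replicating the first input value, so a
constant input is in steady state from the first beat and every step is
defined; the detector masks the initial transient with its warm-up window.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right, insort
from collections import deque
from dataclasses import dataclass
from typing import Deque, Sequence

__all__ = [
    "MedianState",
    "LowFilterState",
    "HighFilterState",
    "AlignedBeat",
    "median_step",
    "lowpass_low_step",
    "lowpass_high_step",
    "align_and_delta",
    "MEDIAN_HALFWIDTH",
    "LOW_TAPS",
    "LOW_GAIN_SHIFT",
    "HIGH_GAIN_SHIFT",
    "RAW_LAG",
    "XL_LAG",
]

MEDIAN_HALFWIDTH = 8      # w; window 2w+1 = 17, delay w = 8 beats
LOW_TAPS = 16             # boxcar length of H_l; gain 2^4, delay 7.5
LOW_GAIN_SHIFT = 4
HIGH_GAIN_SHIFT = 11      # gain of H_h is 32*64 = 2048 = 2^11, delay 47
RAW_LAG = 62              # floor(62.5): raw-series lag behind the xh clock
XL_LAG = 47               # low-scale reference lag behind the xh clock


class MedianState:
    """Streaming median over the last ``2w + 1`` samples.

    Keeps the window in arrival order plus a sorted copy; each step evicts
    the oldest sample and inserts the new one, locating both positions by
    binary search, then reports the middle element of the sorted array.
    The first sample primes the whole window by replication.
    """

    def __init__(self, halfwidth: int = MEDIAN_HALFWIDTH):
        if halfwidth < 1:
            raise ValueError("median half-width must be >= 1")
        self.w = halfwidth
        self.size = 2 * halfwidth + 1
        self.window: Deque[int] = deque(maxlen=self.size)
        self.sorted: list[int] = []

    @property
    def primed(self) -> bool:
        return len(self.window) == self.size

    def prime(self, x0: int) -> None:
        self.window.extend([x0] * self.size)
        self.sorted = [x0] * self.size

    def step(self, x_in: int) -> int:
        x_in = int(x_in)
        if not self.primed:
            self.prime(x_in)
            return x_in
        departing = self.window[0]
        self.window.append(x_in)  # deque eviction of the oldest
        # evict any position holding the departing value (multiset: the
        # median is unaffected by which duplicate goes)
        del self.sorted[bisect_left(self.sorted, departing)]
        insort(self.sorted, x_in)  # rightmost insertion point
        return self.sorted[self.w]


def median_step(state: MedianState, x_in: int) -> int:
    """Advance the streaming median one beat; returns the window median."""
    if not state.primed:
        raise RuntimeError("median filter not primed; call prime() or step() first")
    return state.step(x_in)


class LowFilterState:
    """Recursive 16-tap boxcar low-pass (exact integer, DC gain 16)."""

    def __init__(self) -> None:
        self.y_hist: Deque[int] = deque(maxlen=LOW_TAPS)
        self.xl_unscaled = 0

    @property
    def primed(self) -> bool:
        return len(self.y_hist) == LOW_TAPS

    def prime(self, y0: int) -> None:
        self.y_hist.extend([y0] * LOW_TAPS)
        self.xl_unscaled = LOW_TAPS * y0

    def step(self, y_in: int) -> int:
        y_in = int(y_in)
        if not self.primed:
            self.prime(y_in)
            return y_in
        self.xl_unscaled += y_in - self.y_hist[0]  # y[n] - y[n-16]
        self.y_hist.append(y_in)
        return self.xl_unscaled >> LOW_GAIN_SHIFT


def lowpass_low_step(state: LowFilterState, y_in: int) -> int:
    """One step of the low-scale filter; returns the gain-corrected xl."""
    if not state.primed:
        raise RuntimeError("low-scale filter not primed")
    return state.step(y_in)


class HighFilterState:
    """Recursive boxcar cascade 32 x 64 (exact integer, DC gain 2048).

    ``xh[n] = 2 xh[n-1] - xh[n-2] + xl[n] - xl[n-32] - xl[n-64] + xl[n-96]``
    with the doubling done as a left shift. Consumes the gain-corrected
    low-scale output.
    """

    HIST = 96

    def __init__(self) -> None:
        self.xl_hist: Deque[int] = deque(maxlen=self.HIST)
        self.xh_prev1 = 0
        self.xh_prev2 = 0

    @property
    def primed(self) -> bool:
        return len(self.xl_hist) == self.HIST

    def prime(self, xl0: int) -> None:
        self.xl_hist.extend([xl0] * self.HIST)
        steady = xl0 << HIGH_GAIN_SHIFT
        self.xh_prev1 = steady
        self.xh_prev2 = steady

    def step(self, xl_in: int) -> int:
        xl_in = int(xl_in)
        if not self.primed:
            self.prime(xl_in)
            return xl_in
        h = self.xl_hist
        # h[0] = xl[n-96], h[32] = xl[n-64], h[64] = xl[n-32]
        xh_unscaled = (self.xh_prev1 << 1) - self.xh_prev2 + xl_in - h[64] - h[32] + h[0]
        self.xh_prev2 = self.xh_prev1
        self.xh_prev1 = xh_unscaled
        h.append(xl_in)
        return xh_unscaled >> HIGH_GAIN_SHIFT


def lowpass_high_step(state: HighFilterState, xl_in: int) -> int:
    """One step of the high-scale filter; returns the gain-corrected xh."""
    if not state.primed:
        raise RuntimeError("high-scale filter not primed")
    return state.step(xl_in)


@dataclass(frozen=True)
class AlignedBeat:
    """Delay-corrected signals on the high-scale reference clock."""

    x_prime: int    # raw RR, lagged raw_lag beats
    xl_prime: int   # low-scale reference, lagged 47 beats
    xh: int         # current high-scale reference
    delta_rr: int   # x_prime - xl_prime (may be negative)


def align_and_delta(
    x_buffer: Sequence[int],
    xl_buffer: Sequence[int],
    xh_now: int,
    raw_lag: int = RAW_LAG,
) -> AlignedBeat:
    """Align the raw and low-scale signals to the xh clock and form delta-RR.

    ``x_buffer`` / ``xl_buffer`` hold the raw inputs and gain-corrected
    low-scale outputs up to and including the current filter-clock beat;
    the last element is the current beat. The raw series is taken
    ``raw_lag`` beats back (the exact filter-chain delay is 62.5 beats; the
    default floors it to 62, configurable to 63), the low-scale series 47
    beats back.
    """
    if len(x_buffer) < raw_lag + 1 or len(xl_buffer) < XL_LAG + 1:
        raise RuntimeError(
            f"alignment needs >= {raw_lag + 1} raw and {XL_LAG + 1} low-scale samples"
        )
    x_prime = int(x_buffer[-1 - raw_lag])
    xl_prime = int(xl_buffer[-1 - XL_LAG])
    return AlignedBeat(
        x_prime=x_prime,
        xl_prime=xl_prime,
        xh=int(xh_now),
        delta_rr=x_prime - xl_prime,
    )
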