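"""Stage 3 — sliding-window coarse Shannon entropy with O(1) updates.

The detector's statistic is a "coarse" normalized Shannon entropy over the
last N = 127 word values. With ``k`` distinct words of probabilities
``p_i = N_i / N``:

    H(A)   = -sum p_i log2 p_i                (Shannon entropy, bits)
    H'(A)  = H(A) / log2 N                    (normalized to [0, 1])
    H''(A) = (k / N) * H'(A)                  (coarse entropy)

The ``k/N`` factor rewards pattern diversity directly: a window of 127
identical words gives 0, a window of 127 distinct words gives ~1.

Because every count is an integer in 1..127, each term
``-(p log2 p) / log2 N`` takes one of 127 values. These are pre-computed as
the integer table ``PiMap[i] = floor(Cons * (-(i/N) log2(i/N)) / log2 N)``
with ``Cons = 10**6``, so a streaming update needs only count bookkeeping
and one multiply + one divide per beat:

    H''(A) = k * sum_i PiMap[N_i] / (N * Cons) = k * s_sum / 127000000.

Only the entering and the departing word's counts change per beat, so the
running sum ``s_sum`` is adjusted with four table lookups at most.
"""

from __future__ import annotations

import math
from collections import deque
from typing import Deque, Optional, Sequence

import numpy as np

from .symbolic import WORD_MAX

__all__ = [
    "N_BINS",
    "CONS",
    "SCALE",
    "build_pimap",
    "PIMAP",
    "shannon_entropy",
    "normalized_entropy",
    "coarse_entropy",
    "EntropyWindow",
    "window_update",
]

N_BINS = 127            # window length N (and maximum distinct words)
CONS = 1_000_000        # integer scaling constant of the PiMap table
SCALE = N_BINS * CONS   # 127000000, the denominator of H''


def build_pimap() -> list[int]:
    """Pre-compute the 128-entry integer entropy-contribution table.

    ``PIMAP[i]`` for ``i`` in 1..127 is the floored, Cons-scaled value of
    ``-(p log2 p)/log2 N`` at ``p = i/127``; ``PIMAP[0]`` is fixed at 0 so
    a vanished count contributes nothing. Plain Python ints keep the
    arithmetic exact.
    """
    log2n = math.log2(N_BINS)
    table = [0] * (N_BINS + 1)
    for i in range(1, N_BINS + 1):
        p = i / N_BINS
        table[i] = math.floor(CONS * (-p * math.log2(p)) / log2n)
    return table


PIMAP: list[int] = build_pimap()


def _check_probs(probabilities: Sequence[float]) -> np.ndarray:
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0 or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in (0, 1]")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")
    return p


def shannon_entropy(probabilities: Sequence[float]) -> float:
    """Shannon entropy -sum p log2 p in bits."""
    p = _check_probs(probabilities)
    return float(-(p * np.log2(p)).sum())


def normalized_entropy(probabilities: Sequence[float], n_bins: int = N_BINS) -> float:
    """Shannon entropy divided by log2(N); equals 1 iff uniform over all N bins.

    For the degenerate single-bin space N = 1 the normalizer is taken as 1,
    so a sure outcome still yields 0.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    log2n = 1.0 if n_bins == 1 else math.log2(n_bins)
    return shannon_entropy(probabilities) / log2n


def coarse_entropy(
    probabilities: Sequence[float], k: int, n_bins: int = N_BINS
) -> float:
    """Coarse entropy (k/N) * H'(A); the float reference for the integer path."""
    p = _check_probs(probabilities)
    if k != p.size:
        raise ValueError(f"k = {k} must equal the number of probabilities ({p.size})")
    if n_bins < k:
        raise ValueError(f"n_bins = {n_bins} must be >= k = {k}")
    return (k / n_bins) * normalized_entropy(p, n_bins)


class EntropyWindow:
    """Ring buffer of the last 127 words with incremental coarse entropy.

    State: per-word counts (``counts[v]`` over word values 0..2457), the
    number of distinct words ``k``, and the running integer sum ``s_sum`` of
    ``PIMAP[counts[v]]`` over present words. Each update touches at most two
    counts (the departing and the entering word), so the entropy refresh is
    O(1) per beat regardless of window content.

    ``update`` returns ``None`` until 127 words have accumulated (the
    statistic is undefined on a partial window); afterwards it returns
    ``k * s_sum / 127000000`` as a float in [0, 1].
    """

    def __init__(self) -> None:
        self.words: Deque[int] = deque(maxlen=N_BINS)
        self.counts = np.zeros(WORD_MAX + 1, dtype=np.int64)
        self.k = 0
        self.s_sum = 0

    @property
    def full(self) -> bool:
        return len(self.words) == N_BINS

    def _bump(self, word: int, delta: int) -> None:
        c_old = int(self.counts[word])
        c_new = c_old + delta
        self.counts[word] = c_new
        self.s_sum += PIMAP[c_new] - PIMAP[c_old]
        if c_old == 0 and c_new > 0:
            self.k += 1
        elif c_old > 0 and c_new == 0:
            self.k -= 1

    def update(self, word_in: int) -> Optional[float]:
        word_in = int(word_in)
        if not 0 <= word_in <= WORD_MAX:
            raise ValueError(f"word out of range 0-{WORD_MAX}: {word_in}")
        if self.full:
            self._bump(self.words[0], -1)  # deque drops the oldest on append
        self.words.append(word_in)
        self._bump(word_in, +1)
        if not self.full:
            return None
        return self.k * self.s_sum / SCALE

    def value(self) -> Optional[float]:
        """Current H'' without advancing the window (None while filling)."""
        if not self.full:
            return None
        return self.k * self.s_sum / SCALE


def window_update(state: EntropyWindow, word_in: int) -> Optional[float]:
    """Advance the entropy window one beat; returns H'' (None while filling)."""
    return state.update(word_in)
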