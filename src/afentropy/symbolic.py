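"""Stage 2 — symbolic dynamics of delta-RR.

Each beat's ``delta_rr`` is quantized into a 10-symbol alphabet using five
thresholds derived from the current high-scale reference ``xh`` by integer
shifts, so the alphabet adapts to the running heart-rate scale and the
symbolization is invariant to rescaling the tachogram:

    thre1 = xh >> 4, thre2 = xh >> 3, thre3 = thre1 + thre2,
    thre4 = xh >> 2, thre5 = thre4 + thre1.

Symbols 0-9 partition the delta-RR axis from large negative deviations
(symbol 0, below ``-thre4``) through the neutral band around zero (symbol 4)
to large positive deviations (symbol 9, at or above ``thre5``). Three
consecutive symbols are packed into a "word" by nibble shifts,
``wv = (sy[n-2] << 8) + (sy[n-1] << 4) + sy[n]``, giving an injective code
in [0, 2457] over which the entropy stage counts pattern diversity.
"""

from __future__ import annotations

from typing import NamedTuple

__all__ = [
    "ThresholdSet",
    "WORD_MAX",
    "thresholds_from_xh",
    "symbolize",
    "word_value",
    "word_symbols",
]

#: Largest word value: symbols (9, 9, 9) -> (9 << 8) + (9 << 4) + 9.
WORD_MAX = 2457


class ThresholdSet(NamedTuple):
    """The five xh-derived symbolization thresholds (non-decreasing)."""

    thre1: int
    thre2: int
    thre3: int
    thre4: int
    thre5: int


def thresholds_from_xh(xh: int) -> ThresholdSet:
    """Derive the five symbol thresholds from the high-scale reference."""
    xh = int(xh)
    if xh < 0:
        raise ValueError(f"xh must be non-negative, got {xh}")
    t1 = xh >> 4
    t2 = xh >> 3
    t4 = xh >> 2
    return ThresholdSet(t1, t2, t1 + t2, t4, t4 + t1)


def symbolize(delta_rr: int, t: ThresholdSet) -> int:
    """Map a delta-RR value to its symbol 0-9 (first matching band wins)."""
    d = int(delta_rr)
    if d < -t.thre4:
        return 0
    if d < -t.thre3:
        return 1
    if d < -t.thre2:
        return 2
    if d < -t.thre1:
        return 3
    if d < t.thre1:
        return 4
    if d < t.thre2:
        return 5
    if d < t.thre3:
        return 6
    if d < t.thre4:
        return 7
    if d < t.thre5:
        return 8
    return 9


def word_value(s2: int, s1: int, s0: int) -> int:
    """Pack three consecutive symbols (oldest first) into one word value."""
    for s in (s2, s1, s0):
        if not 0 <= int(s) <= 9:
            raise ValueError(f"symbol out of range 0-9: {s}")
    return (int(s2) << 8) + (int(s1) << 4) + int(s0)


def word_symbols(word: int) -> tuple[int, int, int]:
    """Decode a word back to its (oldest, middle, newest) symbol triple."""
    if not 0 <= int(word) <= WORD_MAX:
        raise ValueError(f"word out of range 0-{WORD_MAX}: {word}")
    return (word >> 8) & 0xF, (word >> 4) & 0xF, word & 0xF
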