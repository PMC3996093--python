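"""End-to-end streaming detector: per-beat pipeline and classification.

Each incoming RR interval advances the filter cascade, the symbolization
and the entropy window in lock step. When a coarse-entropy value H''
becomes defined it describes a beat in the past: the word window centre
plus the filter-chain delay put H'' at filter clock ``n`` about 126.5
beats behind the raw beat it characterizes, so it is attributed to source
beat ``n - 126`` (floor; configurable to 127). A beat is labeled AF when
its H'' strictly exceeds the discrimination threshold (default 0.353, the
ROC optimum on long-term AF training records), otherwise non-AF.

Beats whose H'' never becomes defined — the initial warm-up (default 256
beats, covering filter priming, the word template and the 127-word window)
and the trailing ~126 beats of a finite record — are labeled WARMUP and
carry no entropy value.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Deque, Iterator, List, Optional

from .entropy import EntropyWindow, N_BINS
from .preprocess import (
    HighFilterState,
    LowFilterState,
    MedianState,
    RAW_LAG,
    XL_LAG,
    align_and_delta,
)
from .rr_io import AF, NONAF, WARMUP, RRSeries
from .symbolic import symbolize, thresholds_from_xh, word_value

__all__ = [
    "DEFAULT_THRESHOLD",
    "DetectorConfig",
    "DetectionRecord",
    "DetectorState",
    "init_state",
    "process_beat",
    "detect_sequence",
]

#: ROC-optimal discrimination threshold on the long-term AF training set.
DEFAULT_THRESHOLD = 0.353

#: H'' at filter clock n is attributed to source beat n - 126 (floor of the
#: 126.5-beat analytic delay of the chain).
ATTRIBUTION_LAG = 126


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable parameters of the streaming detector."""

    threshold: float = DEFAULT_THRESHOLD
    median_halfwidth: int = 8
    warmup_beats: int = 256
    raw_lag: int = RAW_LAG
    attribution_lag: int = ATTRIBUTION_LAG
    units: str = "ms"

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")
        if self.median_halfwidth < 1:
            raise ValueError("median_halfwidth must be >= 1")
        if self.warmup_beats < 0:
            raise ValueError("warmup_beats must be >= 0")
        if self.raw_lag < 0 or self.attribution_lag < 0:
            raise ValueError("lags must be >= 0")
        if self.units not in ("ms", "samples"):
            raise ValueError(f"units must be 'ms' or 'samples', got {self.units!r}")


@dataclass(frozen=True)
class DetectionRecord:
    """Classification of one source beat.

    ``h_entropy`` is None exactly when the label is WARMUP.
    """

    beat_index: int
    h_entropy: Optional[float]
    label: str


class DetectorState:
    """All per-stream state of the pipeline (create via :func:`init_state`)."""

    def __init__(self, config: DetectorConfig):
        self.config = config
        self.median = MedianState(config.median_halfwidth)
        self.low = LowFilterState()
        self.high = HighFilterState()
        self.window = EntropyWindow()
        # alignment ring buffers: raw inputs and gain-corrected xl outputs
        self.raw_buf: Deque[int] = deque(maxlen=config.raw_lag + 1)
        self.xl_buf: Deque[int] = deque(maxlen=XL_LAG + 1)
        self.symbols: Deque[int] = deque(maxlen=3)
        self.clock = -1  # filter-clock index of the last consumed beat


def init_state(config: Optional[DetectorConfig] = None) -> DetectorState:
    """Create fresh pipeline state for one RR stream."""
    return DetectorState(config or DetectorConfig())


def process_beat(state: DetectorState, rr: int) -> Optional[DetectionRecord]:
    """Advance the pipeline one beat; return a record when one completes.

    The first beat primes every filter history by value replication, so all
    stages are defined from beat 0 on. A record is returned once the entropy
    window is full and the attributed source beat is past the warm-up span;
    earlier beats produce no output here (batch callers pad them, see
    :func:`detect_sequence`).
    """
    rr = int(rr)
    if rr <= 0:
        raise ValueError(f"RR interval must be positive, got {rr}")
    cfg = state.config
    state.clock += 1

    if not state.median.primed:  # first beat: prime alignment buffers too
        state.raw_buf.extend([rr] * state.raw_buf.maxlen)
        state.xl_buf.extend([rr] * state.xl_buf.maxlen)

    y = state.median.step(rr)
    xl = state.low.step(y)
    xh = state.high.step(xl)
    state.raw_buf.append(rr)
    state.xl_buf.append(xl)

    aligned = align_and_delta(state.raw_buf, state.xl_buf, xh, cfg.raw_lag)
    sy = symbolize(aligned.delta_rr, thresholds_from_xh(aligned.xh))
    if not state.symbols:  # prime the 3-symbol template
        state.symbols.extend([sy] * 3)
    else:
        state.symbols.append(sy)
    word = word_value(*state.symbols)

    h = state.window.update(word)
    if h is None:
        return None
    beat = state.clock - cfg.attribution_lag
    if beat < cfg.warmup_beats:
        return None
    label = AF if h > cfg.threshold else NONAF
    return DetectionRecord(beat_index=beat, h_entropy=h, label=label)


def detect_sequence(
    rr: RRSeries, config: Optional[DetectorConfig] = None
) -> List[DetectionRecord]:
    """Run the full stream and return exactly one record per input beat.

    Beats never reached by a defined H'' — the head warm-up span and the
    trailing ~126 beats — are labeled WARMUP with no entropy value. Feeding
    the same series beat-by-beat through :func:`process_beat` yields the
    identical non-WARMUP records.
    """
    if len(rr) < 1:
        raise ValueError("empty RR series")
    cfg = config or DetectorConfig()
    state = init_state(cfg)
    by_beat: dict[int, DetectionRecord] = {}
    for x in rr.rr:
        rec = process_beat(state, int(x))
        if rec is not None:
            by_beat[rec.beat_index] = rec
    return [
        by_beat.get(i, DetectionRecord(beat_index=i, h_entropy=None, label=WARMUP))
        for i in range(len(rr))
    ]
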