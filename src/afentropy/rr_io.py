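"""Text-format I/O for RR-interval streams, rhythm references and results.

All formats are plain CSV so records round-trip losslessly and diff cleanly:

* RR CSV — one positive integer RR interval per line, optional header.
* Rhythm CSV — ``start_beat,end_beat,label`` rows with 0-based half-open
  ``[start, end)`` beat intervals; uncovered beats default to non-AF.
* Results CSV — ``beat_index,h_entropy,label`` per beat, entropy field empty
  while the detector is warming up.

Beat annotations from PhysioBank-style sources enter through
:func:`rr_from_beat_times`; binary annotation formats are deliberately out of
scope (use an external reader such as ``wfdb`` to obtain beat times first).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "AF",
    "NONAF",
    "WARMUP",
    "RRSeries",
    "RhythmReference",
    "read_rr_csv",
    "read_rhythm_csv",
    "rr_from_beat_times",
    "write_results_csv",
    "read_results_csv",
]

#: Per-beat rhythm / detection labels used throughout the package.
AF = "AF"
NONAF = "NONAF"
WARMUP = "WARMUP"

_UNITS = ("ms", "samples")


@dataclass
class RRSeries:
    """A sequence of RR intervals (one integer per heartbeat).

    Parameters
    ----------
    rr
        Positive integer RR intervals, in milliseconds by default or in
        ADC samples when ``units == "samples"`` (then ``sampling_rate``
        should be given).
    units
        Exactly one of ``"ms"`` or ``"samples"``.
    sampling_rate
        Sampling frequency in Hz; only meaningful for sample units.
    record_id
        Free-form identifier of the source record.
    """

    rr: np.ndarray
    units: str = "ms"
    sampling_rate: Optional[float] = None
    record_id: str = ""

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=np.int64)
        if self.rr.ndim != 1 or self.rr.size < 1:
            raise ValueError("RR series must be a non-empty 1-D array")
        if np.any(self.rr <= 0):
            bad = int(np.argmax(self.rr <= 0))
            raise ValueError(
                f"RR intervals must be positive; rr[{bad}] = {int(self.rr[bad])}"
            )
        if self.units not in _UNITS:
            raise ValueError(f"units must be one of {_UNITS}, got {self.units!r}")

    def __len__(self) -> int:
        return int(self.rr.size)


@dataclass
class RhythmReference:
    """Per-beat reference rhythm labels (``AF`` / ``NONAF``)."""

    labels: np.ndarray
    record_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(np.unique(self.labels)) - {AF, NONAF}
        if bad:
            raise ValueError(f"labels must be {AF!r} or {NONAF!r}; found {bad}")

    def __len__(self) -> int:
        return int(self.labels.size)


def read_rr_csv(path: str | Path, units: str = "ms") -> RRSeries:
    """Read an RR series from a one-column CSV (optional single header line)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    values: list[int] = []
    for lineno, raw in enumerate(lines, start=1):
        s = raw.strip().rstrip(",")
        if not s:
            continue
        try:
            values.append(int(s))
        except ValueError:
            if lineno == 1 and not values:  # header line
                continue
            raise ValueError(f"{path}: malformed RR value {s!r} on line {lineno}")
    if not values:
        raise ValueError(f"{path}: no RR values found")
    return RRSeries(np.array(values), units=units, record_id=path.stem)


def read_rhythm_csv(path: str | Path, n_beats: int) -> RhythmReference:
    """Expand ``start_beat,end_beat,label`` intervals into per-beat labels.

    Intervals are 0-based half-open ``[start, end)``. Beats not covered by any
    interval default to ``NONAF``. Overlapping intervals with conflicting
    labels, or intervals extending past ``n_beats``, raise ``ValueError``.
    """
    path = Path(path)
    labels = np.full(n_beats, None, dtype=object)
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        s = raw.strip()
        if not s:
            continue
        parts = [p.strip() for p in s.split(",")]
        if len(parts) != 3:
            raise ValueError(f"{path}: expected 3 fields on line {lineno}, got {len(parts)}")
        try:
            start, end = int(parts[0]), int(parts[1])
        except ValueError:
            if lineno == 1:  # header line
                continue
            raise ValueError(f"{path}: malformed interval on line {lineno}: {s!r}")
        label = parts[2]
        if label not in (AF, NONAF):
            raise ValueError(f"{path}: unknown label {label!r} on line {lineno}")
        if not (0 <= start <= end <= n_beats):
            raise ValueError(
                f"{path}: interval [{start}, {end}) on line {lineno} outside [0, {n_beats})"
            )
        seg = labels[start:end]
        conflict = (seg != None) & (seg != label)  # noqa: E711 -- elementwise
        if np.any(conflict):
            beat = start + int(np.argmax(conflict))
            raise ValueError(
                f"{path}: conflicting labels for beat {beat} (line {lineno})"
            )
        labels[start:end] = label
    labels[labels == None] = NONAF  # noqa: E711
    return RhythmReference(labels, record_id=path.stem)


def rr_from_beat_times(
    beat_times: Sequence[float],
    units: str = "ms",
    sampling_rate: Optional[float] = None,
) -> RRSeries:
    """Convert strictly increasing beat times (seconds) to an RR series.

    This is the adapter for PhysioBank-style beat annotations: read beat
    times with any external annotation reader, then call this to obtain the
    integer tachogram the detector consumes. Differences are rounded to
    integer milliseconds, or to integer samples when ``units == "samples"``
    (``sampling_rate`` required).
    """
    t = np.asarray(beat_times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("need at least two beat times")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0))
        raise ValueError(f"beat times must be strictly increasing (index {bad + 1})")
    if units == "ms":
        rr = np.rint(dt * 1000.0).astype(np.int64)
    elif units == "samples":
        if sampling_rate is None or sampling_rate <= 0:
            raise ValueError("sampling_rate (Hz) required for sample units")
        rr = np.rint(dt * sampling_rate).astype(np.int64)
    else:
        raise ValueError(f"units must be one of {_UNITS}, got {units!r}")
    return RRSeries(rr, units=units, sampling_rate=sampling_rate)


def write_results_csv(records: Iterable, path: str | Path) -> None:
    """Write per-beat detection records as ``beat_index,h_entropy,label``.

    The entropy field is empty for warm-up beats; floats are written with
    ``repr`` so the file round-trips bit-exactly through
    :func:`read_results_csv`.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("beat_index,h_entropy,label\n")
        for rec in records:
            h = "" if rec.h_entropy is None else repr(rec.h_entropy)
            fh.write(f"{rec.beat_index},{h},{rec.label}\n")


def read_results_csv(path: str | Path):
    """Read a results CSV back into a list of ``DetectionRecord``."""
    from .detector import DetectionRecord  # local import: avoid cycle

    path = Path(path)
    out = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        s = raw.strip()
        if not s or s.startswith("beat_index"):
            continue
        parts = s.split(",")
        if len(parts) != 3:
            raise ValueError(f"{path}: expected 3 fields on line {lineno}")
        idx = int(parts[0])
        h = None if parts[1] == "" else float(parts[1])
        out.append(DetectionRecord(beat_index=idx, h_entropy=h, label=parts[2]))
    if not out:
        raise ValueError(f"{path}: no records found")
    return out
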