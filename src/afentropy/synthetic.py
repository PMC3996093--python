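"""Synthetic RR tachograms with known per-beat rhythm labels.

The generator produces the two regimes the detector has to separate, plus
the artifacts its median stage has to absorb, so the whole pipeline can be
exercised offline:

* **NSR segments** — a regular tachogram: mean RR (default 800 ms) with a
  slow sinusoidal modulation emulating respiratory sinus arrhythmia
  (default 40 ms amplitude, 6-beat period) plus small Gaussian jitter
  (default 10 ms SD), rounded to integers and clipped at 200 ms.
* **AF segments** — i.i.d. uniform integer RR on [400, 1200] ms: the
  irregularly irregular rhythm reduced to its one property the statistic
  uses, high beat-to-beat pattern diversity. A deliberately simple test
  fixture, not a physiological AF model.
* **Artifacts** (off by default) — with probability ``artifact_rate`` a
  beat is replaced by an ectopic short/long pair (0.4 x RR then 1.6 x RR)
  or merged with its successor (a missed R-peak); reference labels follow
  the surviving beats.

Everything is reproducible from ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .rr_io import AF, NONAF, RRSeries, RhythmReference

__all__ = ["SyntheticSpec", "gen_nsr", "gen_af", "gen_record", "NSR"]

#: Segment label for normal sinus rhythm (maps to NONAF in references).
NSR = "NSR"

_MIN_RR_MS = 200  # clip floor; keeps jittered RR physiological and positive


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic record (all RR quantities in ms)."""

    segments: List[Tuple[str, int]] = field(
        default_factory=lambda: [(NSR, 1000), (AF, 1000), (NSR, 1000)]
    )
    nsr_mean_rr: float = 800.0
    nsr_rsa_amplitude: float = 40.0
    nsr_rsa_period: float = 6.0
    nsr_jitter_sd: float = 10.0
    af_rr_low: int = 400
    af_rr_high: int = 1200
    artifact_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("segments must be non-empty")
        for label, n in self.segments:
            if label not in (NSR, AF):
                raise ValueError(f"segment label must be {NSR!r} or {AF!r}: {label!r}")
            if n < 1:
                raise ValueError(f"segment length must be >= 1, got {n}")
        if self.nsr_mean_rr <= 0 or self.nsr_rsa_period <= 0:
            raise ValueError("nsr_mean_rr and nsr_rsa_period must be positive")
        if self.nsr_jitter_sd < 0 or self.nsr_rsa_amplitude < 0:
            raise ValueError("jitter SD and RSA amplitude must be non-negative")
        if not 0 < self.af_rr_low < self.af_rr_high:
            raise ValueError("need 0 < af_rr_low < af_rr_high")
        if not 0.0 <= self.artifact_rate < 0.5:
            raise ValueError("artifact_rate must be in [0, 0.5)")


def _rng(spec: SyntheticSpec, rng: Optional[np.random.Generator]) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(spec.seed)


def gen_nsr(
    n: int, spec: Optional[SyntheticSpec] = None,
    rng: Optional[np.random.Generator] = None,
) -> RRSeries:
    """Generate ``n`` beats of sinus rhythm with RSA modulation and jitter."""
    spec = spec or SyntheticSpec()
    if n < 1:
        raise ValueError("n must be >= 1")
    g = _rng(spec, rng)
    i = np.arange(n)
    rr = (
        spec.nsr_mean_rr
        + spec.nsr_rsa_amplitude * np.sin(2 * np.pi * i / spec.nsr_rsa_period)
        + g.normal(0.0, spec.nsr_jitter_sd, size=n)
    )
    rr = np.maximum(np.rint(rr).astype(np.int64), _MIN_RR_MS)
    return RRSeries(rr, units="ms", record_id="synthetic-nsr")


def gen_af(
    n: int, spec: Optional[SyntheticSpec] = None,
    rng: Optional[np.random.Generator] = None,
) -> RRSeries:
    """Generate ``n`` beats of AF-like rhythm: i.i.d. uniform integer RR."""
    spec = spec or SyntheticSpec()
    if n < 1:
        raise ValueError("n must be >= 1")
    g = _rng(spec, rng)
    rr = g.integers(spec.af_rr_low, spec.af_rr_high + 1, size=n, dtype=np.int64)
    return RRSeries(rr, units="ms", record_id="synthetic-af")


def gen_record(spec: Optional[SyntheticSpec] = None) -> Tuple[RRSeries, RhythmReference]:
    """Generate a full labeled record from the segment plan in ``spec``.

    Artifact injection (when ``artifact_rate > 0``) replaces a beat with an
    ectopic pair or merges it with the next beat, changing the record length
    by +-1 per event; the per-beat labels track the surviving beats so the
    reference stays aligned.
    """
    spec = spec or SyntheticSpec()
    g = np.random.default_rng(spec.seed)
    rr_parts: list[np.ndarray] = []
    label_parts: list[np.ndarray] = []
    for label, n in spec.segments:
        series = gen_af(n, spec, g) if label == AF else gen_nsr(n, spec, g)
        rr_parts.append(series.rr)
        label_parts.append(np.full(n, AF if label == AF else NONAF, dtype=object))
    rr = np.concatenate(rr_parts)
    labels = np.concatenate(label_parts)

    if spec.artifact_rate > 0:
        rr_out: list[int] = []
        lab_out: list[str] = []
        i = 0
        while i < rr.size:
            if g.random() < spec.artifact_rate:
                if g.random() < 0.5 or i == rr.size - 1:
                    # ectopic: premature beat plus compensatory pause
                    rr_out += [max(int(round(0.4 * rr[i])), _MIN_RR_MS),
                               max(int(round(1.6 * rr[i])), _MIN_RR_MS)]
                    lab_out += [labels[i], labels[i]]
                    i += 1
                else:
                    # missed R-peak: two beats seen as one long interval
                    rr_out.append(int(rr[i] + rr[i + 1]))
                    lab_out.append(labels[i])
                    i += 2
            else:
                rr_out.append(int(rr[i]))
                lab_out.append(labels[i])
                i += 1
        rr = np.array(rr_out, dtype=np.int64)
        labels = np.array(lab_out, dtype=object)

    return (
        RRSeries(rr, units="ms", record_id=f"synthetic-{spec.seed}"),
        RhythmReference(labels, record_id=f"synthetic-{spec.seed}"),
    )
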