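# Methods

## Model and assumptions

The detector treats AF as a property of the RR tachogram alone: during AF
the beat-to-beat sequence is irregularly irregular, so a short sliding
window of symbolized RR differences contains many distinct patterns, while
sinus rhythm — even with respiratory modulation — produces few. The
statistic is the coarse normalized Shannon entropy

    H″(A) = (k/N) · H(A) / log2 N,    N = 127 words, k distinct,

of 3-symbol words over the last 127 beats, and classification is a single
fixed threshold on H″. The method assumes R-peak times (hence RR
intervals) are already available; R-peak detection from raw ECG is out of
scope. It classifies each beat independently — no episode-level smoothing
or onset/offset post-processing.

## Pipeline stages and numerical choices

All stages run in exact integer arithmetic (Python integers, so overflow
is structurally impossible; the unscaled filter states stay below
`max_RR × 2048`, within 64 bits for any physiological input).

* **Median filter** — window 17 (half-width w = 8), delay 8 beats. The
  sorted window is a multiset maintained by two binary searches per beat
  (stdlib `bisect`); with duplicate values, any position holding the
  departing value may be evicted (the median is unaffected) and insertion
  uses the rightmost position.
* **Low-scale filter** — `xl_n = xl_{n−1} + y_n − y_{n−16}`, the exact
  recursion of the 16-tap boxcar `(1−z⁻¹⁶)/(1−z⁻¹)`; DC gain 16 offset by
  `>> 4` (floor division), group delay 7.5 beats.
* **High-scale filter** —
  `xh_n = 2·xh_{n−1} − xh_{n−2} + xl_n − xl_{n−32} − xl_{n−64} + xl_{n−96}`,
  the 32×64 boxcar cascade; DC gain 2048 offset by `>> 11`, group delay 47
  beats. It consumes the gain-corrected (`>> 4`) low-scale output — a
  dialect choice matching the sequential presentation of the two filters;
  since the symbol thresholds are ratios of `xh` itself, the alternative
  (feeding the unscaled signal) only rescales everything by 16 and leaves
  the symbols unchanged.
* **Alignment** — the raw series lags 62.5 beats behind the `xh` clock
  (8 + 7.5 + 47) and `xl` lags 47. The half-beat is floored: the raw lag
  defaults to 62, configurable to 63. The symbol bins are ±`xh/16`-wide, so
  a half-beat misalignment is absorbed by quantization.
* **Symbolization** — thresholds `thre1..5 = (xh>>4, xh>>3, t1+t2, xh>>2,
  t4+t1)`, recomputed every beat (the alphabet adapts to the running heart
  rate). The 10-branch strict-`<` cascade is applied top to bottom; the
  neutral band `[−thre1, thre1)` that contains ΔRR = 0 maps to symbol 4.
  (Descriptions of near-zero differences as the "zero symbol" refer to the
  band's role, not its index; only word *diversity* enters H″, so the
  labeling of the dominant symbol is immaterial.)
* **Entropy** — per-count contributions are pre-tabulated as
  `PiMap[i] = ⌊10⁶·(−p log2 p)/log2 127⌋` with `PiMap[0] = 0`. The window
  keeps per-word counts, the distinct count k and the running sum `s_sum`
  of `PiMap[count]` over present words; one beat changes at most two
  counts, so the refresh is O(1) and `H″ = k·s_sum / 127000000` — the one
  float in the pipeline (we divide rather than compare scaled integers;
  numerically equivalent at this precision). Flooring loses < 127×10⁻⁶ per
  window, so the integer H″ sits within 2×10⁻⁴ of the float formula.
* **Priming and warm-up** — all filter histories are initialized by
  replicating the first input, so constant input is in steady state from
  beat 0 and no startup transient leaks into the symbols. H″ is undefined
  until 127 words accumulate; records attribute H″ at filter clock n to
  source beat n − 126 (floor of the analytic 126.5-beat delay,
  configurable to 127). Beats whose H″ never becomes defined — the first
  `warmup_beats` (default 256 ≈ 62.5-beat filter delay + word template +
  127-word window + margin) and the trailing ~126 beats — are labeled
  WARMUP; evaluation counts them as non-AF (conservative: a warm-up beat
  can produce a miss but never a false alarm).
* **Classification** — AF iff `H″ > threshold` (strict; a tie is non-AF).
  Default threshold 0.353, the ROC optimum reported for long-term AF
  training records. Raising the threshold can only turn AF labels into
  non-AF, which yields the usual Se/Sp trade-off.

## Evaluation conventions

Metrics are beat-level percentages (Se, Sp, PPV, ACC); a zero-denominator
metric propagates as missing (`NA`) rather than 0 — e.g. Se and PPV on a
record with no AF beats. The ROC sweep covers 0.0–1.0 inclusive in steps
of 0.001 (1001 points) with the detector's strict-`>` rule; the operating
point minimizes the Euclidean distance from (1−Sp, Se) to (0%, 100%),
ties broken toward the larger (more specific) threshold.

## Synthetic records

The generator emulates exactly the features the pipeline stages target:

* **NSR**: `RR_i = round(800 + 40·sin(2πi/6) + N(0, 10²))` ms, clipped at
  200 ms — a regular rhythm with RSA-like 6-beat modulation and small
  jitter.
* **AF**: i.i.d. uniform integer RR on [400, 1200] ms — the
  irregularly-irregular rhythm reduced to the one property the statistic
  measures (high word diversity). This is a test fixture, not a
  physiological AF model: real AF has autocorrelated RR, atrial-rate
  structure and varying AV-node conduction.
* **Artifacts** (off by default): with probability `artifact_rate` a beat
  becomes an ectopic pair (0.4·RR then 1.6·RR) or is merged with its
  successor (missed R-peak), changing the record length by ±1 per event;
  labels follow surviving beats.

Defaults (3000 beats as NSR-1000 / AF-1000 / NSR-1000) give sustained
episodes well longer than the 127-beat window. Because artifacts change
the record length, the robustness check compares error *rates* (each run
against its own reference, outside warm-up and ±127-beat transition
bands) rather than aligning labels beat-by-beat; injected artifacts at
rate 0.02 raise the beat error rate by < 2 percentage points.

Passing on these records shows the machinery separates high from low
pattern diversity at the stated sizes and survives isolated outliers; it
does not certify clinical performance — borderline rhythms (atrial
flutter, frequent bigeminy, sinus arrhythmia in children) are absent from
the generator, and published database figures require the actual
recordings.

## Known limitations

* ~127-beat detection latency and a 256-beat warm-up: episodes much
  shorter than the window are diluted below threshold.
* Beat-level only; no episode merging or minimum-duration rule.
* The adaptive thresholds make the symbols scale-invariant, so units (ms
  vs samples) do not matter beyond integer truncation; extremely low
  sampling rates coarsen ΔRR quantization.
* Rhythms that are irregular but not AF (e.g. frequent ectopy beyond the
  median filter's reach, atrial flutter with variable block) inflate H″
  and can false-alarm, consistent with the method's reliance on RR
  irregularity alone.
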