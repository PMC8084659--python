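# Methods

This note records the scientific and numerical choices behind `ecgstream`:
what each stage assumes, which parameters matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Study design and sampling arithmetic

The pipeline is built for single-lead ECG at 360 Hz, streamed in 5-second
packets of 1800 samples.  `ecgstream.study` records the reference
train/test budgets this design is sized against: per-class sample counts of
400,000 / 400,200 / 311,600 for training (1,111,800 samples in total, drawn
from MIT/BIH-style records 205, 118 and 232) and 104,400 / 129,600 /
124,200 for testing (358,200 samples; records 115, 124, 232).  At a fixed
beat width of 200 samples the training budget corresponds to 5559 labeled
beats — the M of the M×25 training matrix.  These are arithmetic identities
of the study layout, asserted as such; they do not depend on any signal
processing.

## Synthetic ECG generator

Each beat is a sum of Gaussian bumps (P, Q, R, S, T) on a 360 Hz grid — the
standard controllable synthetic-ECG device.  Class morphology:

| class  | QRS width | P wave | rhythm (mean RR, CV) |
|--------|-----------|--------|----------------------|
| NORMAL | 0.08 s    | yes    | 0.80 s, 0.03         |
| RBBB   | 0.14 s, notched (delayed R′ bump, late S) | yes | 0.90 s, 0.05 |
| AF     | 0.08 s    | suppressed | 0.75 s, 0.20     |

AF is emulated by its two classic signatures — absent P wave plus high RR
irregularity (coefficient of variation 0.20, well above the 0.15 floor the
irregular-RR literature uses); RBBB by QRS widening and notching.  Noise
terms: white noise (default 0.05 mV in benchmarks), 0.3 Hz sinusoidal
baseline wander, optional 50 Hz powerline.  RR intervals are
`mean_rr·(1 + cv·z)` with standard normal `z`, floored at 0.3·mean_rr.  All
randomness flows through one seeded NumPy generator per call, so identical
specs are bit-identical.

Ground truth stores each beat's R sample (the discrete argmax of the
noise-free template, recorded explicitly so truth and waveform can never
disagree by a sample) and its class label; beats without 69 samples of left
or 130 samples of right context are flagged as boundary beats.

What the generator does **not** emulate: real P/QRS/T variability within a
class, ectopy mixed into a rhythm, electrode motion artefacts, fibrillatory
f-waves, multi-lead geometry, or physiologic dynamics (no
dynamical-systems model).  Consequently, passing tests demonstrate the
*mechanics* of the pipeline — windows, filters, votes, delivery semantics —
and give an optimistic bound on classification scores; they say nothing
about performance on clinical recordings.

## Denoising filter

Linear-phase FIR band-pass, 0.5–40 Hz, 101 taps, Hamming window — the
standard ECG diagnostic band, keeping QRS energy while rejecting baseline
wander and powerline interference.  The symmetric odd-length kernel is
applied as a centred convolution, which is exactly the delay-compensated
filter: output length equals input length and peaks do not shift.  One
numerical caveat: 101 taps at 360 Hz gives a transition width of roughly
12 Hz, so a true 0.5 Hz lower edge is not realisable and DC would leak
through almost unattenuated.  The taps are therefore forced to zero sum,
which nulls 0 Hz exactly while perturbing the passband by well under 1 dB.
Band edges and tap count are configurable (`filter.*` keys).

## R-peak detection

A Pan–Tompkins-style online chain: 5–15 Hz FIR band-pass (21 taps) →
five-point derivative → squaring → 150 ms causal moving-window integration
→ adaptive dual thresholds (signal/noise peak running estimates, threshold
= NPKI + 0.25·(SPKI − NPKI)) with a 0.2 s refractory period and an RR-based
search-back at half threshold when no peak arrives within 1.66× the running
RR average.  Accepted integrator peaks are snapped to the maximum of the
*denoised* signal in a `[−70, +10]`-sample window, since the R peak is by
definition the highest point of the QRS complex; a final pass enforces the
refractory separation on the snapped indices.

The scan is deliberately causal with bounded lookahead: a decision about a
peak near sample `r` never consults the signal beyond `r + 132` samples
(snap window + detection-filter and derivative half-lengths).  This is what
makes detections on a growing prefix *stable* — the property the streaming
engine's exactly-once commit rule is built on.  The thresholds are seeded
from the first second of the integrated signal; an all-zero signal yields
no detections.

## Segmentation

Windows are half-open `[r − 69, r + 131)`, 200 samples, with `samples[69]`
the R sample.  Beats lacking full context are dropped (never zero-padded —
padding fabricates morphology) and counted in `dropped_boundary`, so
`emitted + dropped == len(peaks)` always.  In streaming mode the
carry-over mechanism (below) recovers beats that straddle packet edges.

## Wavelet features

One subband level evaluates `Y_low[k] = Σ_n S[n]·L[2k−n]` and
`Y_high[k] = Σ_n S[n]·H[2k−n]` under periodic extension, downsampled by 2.
The filter origin is placed at half the filter length
(`y[k] = Σ_j f[j]·S[(2k + L/2 − j) mod N]`): any fixed origin satisfies the
defining equations up to a circular shift, and this one (a) reduces to the
pairwise Haar form `(S[2k]+S[2k+1])/√2` and (b) coincides exactly with
PyWavelets' `mode="periodization"`, which the tests use as an independent
reference (agreement < 1e-8; the equally valid detail-branch sign follows
the same convention).  Periodization is what makes every level halve
*exactly*, so the chain 200 → 100 → 50 → 25 is three halvings with no
boundary coefficients, and orthonormal filters conserve energy at each
level (Parseval, asserted to 1e-9 relative).

The feature vector is the final 25-coefficient approximation branch alone:
that is the only reading consistent with the 200→25 sample arithmetic.  The
number of halvings is counted from the lengths (three), not assumed.  The
wavelet family is a free parameter; Daubechies-4 is the default (a common
ECG choice) and Haar is used in analytic tests, so no test depends on the
default.

## Classification and metrics

Candidates: CART decision tree, multinomial (softmax) logistic regression,
and a random forest of 10 trees — scikit-learn estimators behind the module
surface, each seeded and pinned in the saved artifact.  The forest's
prediction is re-derived as a strict majority vote over its trees (vote
fractions are the score vectors and sum to 1); ties break deterministically
to the earliest class in the fixed order (NORMAL, RBBB, AF).  Model
selection maximises validation macro F1, tie-breaking on accuracy and then
declaration order.

Metrics are computed from per-class one-vs-rest confusion counts, pooled
per beat over the test stream and macro-averaged (the near-balanced class
design makes weighted and unweighted averages nearly equal; per-class
values are always emitted alongside).  Specificity is *defined* in the code
as (1 − FPR)·100, per class and in the macro average, so the complement
identity is exact rather than approximate; printed tables can therefore
show a rounded pair like 97.5% / 0.024 whose unrounded values still satisfy
the identity.  AUC is macro one-vs-rest from the score columns
(scikit-learn's `roc_auc_score` as the reference implementation).

Model artifacts are a magic header, a JSON descriptor (kind, class order,
hyperparameters, seed, feature width, format version) and a joblib payload;
corrupt files and version mismatches raise a load error, never a silent
fallback.

## Streaming engine

A single-process reimplementation of micro-batch continuous-query
semantics: processing-time trigger (default 5 s; batches run back-to-back
unless `realtime` pacing is enabled), append-mode sink, checkpointed
exactly-once recovery.  The commit protocol per batch k is: compute →
idempotent sink append keyed on the packet index → checkpoint advance.  A
crash between sink and checkpoint causes recomputation of batch k on
restart, which the sink turns into a no-op — hence exactly-once for any
crash point.  Sinks are a directory of per-batch CSV files (atomic
rename; a half-written batch is never visible) or an embedded SQLite
database (one transaction per batch); a single flat append-only CSV was
rejected because a partial append cannot be made atomic and idempotent at
once.

With carry-over enabled the engine follows the unbounded-table model
literally: raw packets accumulate and the full (cheap, desk-scale) pipeline
re-runs on the prefix each trigger.  A beat is committed in the first batch
where its R index satisfies `r + 145 ≤ prefix length` — 130 samples of
segmentation context plus the detector's bounded lookahead, with slack —
and the final batch flushes the remainder.  Prefix stability of the
detector then guarantees the committed beats are exactly those a single
batch run over the concatenated record would produce (asserted
beat-for-beat in the tests).  With carry-over disabled each packet is
processed in isolation, matching a strict per-packet reading in which
boundary-straddling beats are lost.

Unparseable packet files are quarantined (zero-substituted, flagged,
logged) so one poisoned packet cannot stall the stream; a gap in packet
offsets, by contrast, is a stream-integrity error and aborts.  The progress
reporter emits per-batch read/compute/sink/total wall times plus their
means, as CSV.

Known limitation: if two R peaks closer than the refractory period were
detected near a commit boundary, or a search-back fired retroactively into
an already-committed region, a committed fiducial could in principle differ
from the full-record run.  With physiologic RR intervals (≥ 0.4 s, more
than twice the refractory period) neither occurs; the equivalence tests
cover all three rhythm classes including high-jitter AF.

## Benchmark conditions

The synthetic benchmark trains on 60 s per class and evaluates on records
generated from disjoint seeds (mirroring the record-disjoint train/test
design), at 0.05 mV white noise and 0.1 mV baseline wander.  Detector
acceptance demands recall and precision ≥ 0.95 at 50 ms tolerance on these
conditions; the 10-tree forest is required to reach held-out macro
F1 ≥ 90% and to be preferred over the single decision tree.  Problem sizes
in the tests (tens of seconds per record, ~20-packet streams) are the
package's own desk-scale defaults; they keep the full suite around ten
seconds while exercising every contract.

## WFDB dialect

The MIT/BIH reader/writer is a small self-contained codec for `.hea`
headers, format-212 packed 12-bit signals (1–2 channels, gain/baseline
applied to yield mV) and MIT annotation files (beat codes, rhythm-change
annotations with aux strings, SKIP/AUX escape words).  Beat symbol mapping:
N → NORMAL, R → RBBB, A → AF, everything else OTHER; beats of any symbol
inside an `(AFIB` rhythm span are relabeled AF, since MIT/BIH marks
fibrillation as a rhythm rather than a beat symbol — the only reading under
which record 232 contributes an atrial class.  Records not sampled at
360 Hz are refused unless explicitly allowed (no resampling is attempted).
Which of a record's two channels feeds the pipeline is configurable; the
first channel is the default.
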