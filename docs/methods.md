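# Methods

This note records the models, conventions and design choices behind
`neuroloop`, in the order data flows through the package.

## Conventions

Time is seconds from recording start; all intervals are half-open
`[start, end)`. Wall-clock alignment (quiet hours, 12-h sleep reports)
comes from the recording's absolute start time. Signals are channels ×
samples in microvolts. Every stochastic routine is a pure function of its
inputs and an explicit integer seed.

## Preprocessing

Band-pass filtering is a zero-phase 4th-order Butterworth (0.5–100 Hz for
scalp, 0.5–250 Hz for intracranial EEG) followed by IIR notches at 60 and
120 Hz with Q = 30; the filter family is a standard choice, not a claim
about any particular clinical system. Bad channels are flagged by three
declared, configurable criteria — variance < 10⁻³ µV² (flat), 99th
percentile of |x| above 10× the cross-channel median (high amplitude), and
58–62 Hz power above 50% of broadband power (line noise). These are
surrogates for clinical artifact-rejection systems whose exact rules are
proprietary; they are not claimed equivalent to any of them. Common-average
re-referencing excludes bad channels from the reference; bipolar pairs
touching a bad channel are retained but reported as contaminated.
Prewhitening is a per-channel first difference (an AR(1) variant is
available behind a switch). Windowing is 10 s with 2 s overlap by default;
the optional robust scaler applies per-channel (x − median)/IQR with
statistics fitted once on the first 10 minutes of the recording, a proxy
for a non-ictal fit segment.

## Detection

The detector consumes a probability trace on the window grid. The adaptive
threshold k(t) uses trailing (causal) population statistics over 400 s,
recomputed every 100 s and held constant in between; before a full window
has accrued, all available history is used. Causality matters because the
detector must be usable in streaming deployment. "Exceeds" is strict
everywhere: the CUSUM flags S(t) > h, and the intracranial channel vote
requires the flagged fraction to be strictly greater than 10%. The CUSUM
threshold k(t) continues to adapt during an ongoing detection rather than
freezing at onset, matching streaming behavior; a consequence is that
detected events lag seizure onset by the accumulation time (~h/(p−k)
windows) and extend past the end until the threshold catches up. The
morphological structuring element (3 samples) is a configurable default;
smoothing operates on the window grid. Event probability summaries
(mean/max) are taken over the final interval; multichannel traces are
summarized by the per-window channel maximum.

## Weak labels

Push-button alarms expand to [t−60 s, t+120 s), clipped to the recording
and merged on overlap. Annotation responses map detected events to window
labels: confirmed events → 1, unanswered or uncertain events → NaN
(excluded from training), everything else → 0, including events the
patient rejected (hard negatives). A window overlaps an event if the two
half-open intervals intersect by any amount.

Two refinements protect training from the detector's boundary lag, both
documented in `responses_to_labels`:

* windows within 60 s *before* a confirmed event are excluded (NaN) rather
  than zeroed. The detected interval starts after the seizure does, so
  these windows are frequently ictal; labelling them 0 produces
  high-confidence hard negatives that teach the classifier to suppress
  seizure onsets. The 60-s margin reuses the preictal padding constant.
* when the probability trace that produced the detections is available,
  windows inside a confirmed event that the model itself scored below 0.5
  are excluded rather than labelled 1. These are mostly the post-event
  accumulator-drain tail; labelling plain background 1 places it in the
  rare false-negative sampler category, whose inverse-frequency
  oversampling then amplifies exactly the wrong lesson ("background is
  ictal") and inflates background probabilities.

With no margin and no trace the plain rule applies unchanged.

## Fine-tuning sessions

A session trains on one 3-h block's windows and labels. The stratified
temporal split assigns the chronologically first ⌊0.85·n⌋ samples of each
class to training (at least one when the class exists). Gates skip
sessions with no detected events, no valid labels, or deployed-model
validation AUROC above 0.98 / below 0.5; an undefined AUROC (single-class
validation split) does not block training, since the skip criteria cannot
be evaluated.

The loss is task + λ·KL(reference ‖ current) with λ = 0.5. In binary mode
the task is cross-entropy against the pooled probability — top-k pooling
(mean of the k = max(1, ⌈0.1·C⌉) largest channel probabilities, gradient
routed to the selected channels) for per-channel models. The multiclass
path uses KL against one-hot targets on a configurable detection class
(label 1) or background class (label 0); the one-hot construction is a
declared assumption. The distillation direction KL(reference ‖ current)
is configurable.

The reference model defaults to the pre-session deployed model; the replay
harness instead anchors every session to the *original* baseline. This
distinction matters: with a drifting anchor, consecutive sessions that
contain only negative labels (common when seizures go unannotated)
compound suppression geometrically — each session pushes the false-alarm
response to λ/(1+λ) of a reference that was already suppressed — and the
deployed model can collapse to the negative class over a day. A fixed
anchor turns that ratchet into a fixed point.

The sampler draws with probabilities inversely proportional to the
frequency of each sample's TP/FP/FN/TN category, computed against the
reference model's predictions at threshold 0.5. Scalp-style training
duplicates each window with channel order reversed. Optimization is
adaptive-moment with decoupled weight decay (weight decay skips frozen
groups). Checkpoints are saved on validation-loss improvement (by at least
min_delta = 10⁻³, a standard early-stopping guard the protocol leaves
unspecified) or joint AUROC+AUPRC improvement; training stops on patience
(3 epochs without a checkpoint), 20 epochs, or AUROC/AUPRC above 0.98.
Progressive unfreezing adds one conv block after 2 epochs without
significant validation-loss improvement; it is default-on but disabled in
the canonical replay conditions (below).

## Active learning

Candidate 90-s segments start at every window start (dense grid). Segment
uncertainty is the mean least-confidence score 1 − max(p, 1−p) of its
windows. Selection is greedy with earliest-start tie-breaking and overlap
exclusion; for distinct scores this equals the lexicographically optimal
(sorted-descending uncertainty vector) feasible selection, which is the
guarantee the tests verify by exhaustive enumeration — it is not in
general the maximum-sum selection. Clinician labels fine-tune the deployed
model through the same session machinery, with windows outside labelled
segments excluded.

## Evaluation

Canonicalization merges events separated by < 90 s (strict, to fixpoint),
then splits events longer than 300 s into consecutive 300-s chunks with a
short remainder (no redistribution). Merging precedes splitting. A
reference event is detected if any prediction overlaps its
[start−30 s, end+60 s) extension; false alarms are predictions overlapping
no extended reference. Sensitivity with zero reference events is reported
as absent, not 1.0. Precision counts canonical (post-split) events. The
paired comparison uses one-sided Wilcoxon signed-rank tests on per-patient
median deltas, exact null for n ≤ 25 without ties, normal approximation
otherwise.

## Biomarkers

The hypnogram mode filter uses a centred 15-epoch window, truncated at the
edges, with ties broken toward the epoch's original stage. Sleep bouts are
non-wake runs bridged across wake gaps ≤ 90 s with bouts < 300 s dropped.
The alpha–delta ratio uses Welch spectra (4-s segments, 50% overlap) on
non-overlapping 1-min windows of common-average-referenced data, averaged
over non-excluded channels. Global phase synchrony is the circular
resultant R(t) = |mean_c exp(iφ_c(t))| of Hilbert phases, averaged per
window (a pairwise phase-locking variant is available); for C independent
uniform phases E[R] ≈ √π/(2√C), which the tests verify by Monte Carlo.
Medication load superposes exponentially decaying boluses
c(t) = Σ dose·scale·exp(−ln2·Δt/t½) per drug on a 1-min grid; absorption
is instantaneous by default with an optional first-order absorption phase.
For cross-drug summation each drug is normalized by the steady-state mean
concentration of its logged maintenance regimen (D·scale/(k_e·τ) with τ
the median inter-dose interval), falling back to the single-dose peak —
the normalization convention is this package's own choice.

## Synthetic data

Background EEG is per-channel 1/f (pink) noise plus a small 60 Hz
component, so notch filtering is exercised; ictal activity is a chirp
falling from the ictal frequency to half of it with a linear amplitude
ramp, planted coherently on ⌈fraction·C⌉ channels — enough discriminative
structure to train a classifier, with no claim of physiological realism.
Optional rhythmic background bursts (constant-frequency, Hann-windowed,
all channels) emulate benign physiological rhythms such as alpha runs;
they are the out-of-distribution activity that makes a pretrained
baseline false-alarm. Patient behaviour is modelled by an answer
probability (default 0.706), a correctness probability (0.9), an
'uncertain' fraction (0.1) and lognormal latencies; unanswered alerts
produce no record. False-positive bursts in oracle probability traces are
15-s plateaus, Poisson-placed by default with an evenly-spaced
deterministic mode for exact tests.

The surrogate classifier is a small 1-D CNN implemented directly in numpy
(forward, manual backprop, AdamW): a 15-tap stride-4 stem, two further
conv blocks, global average pooling and a dense head; 16 filters, 32
hidden units. The long stem kernel is deliberate: it gives ~2 Hz frequency
resolution at the 32 Hz input rate, so nearby rhythm bands are separated
*before* any strided subsampling can alias them together. With a short
stem, a 9 Hz burst and an 8 Hz ictal rhythm alias onto the same
post-subsampling frequency, the network falls back on an amplitude cue,
and fine-tuning it away from bursts collaterally suppresses the (higher
amplitude) seizure response. Layer groups (stem / block1 / block2 / head)
support freezing, progressive unfreezing, cloning and exact JSON
serialization.

## Canonical replay conditions

`pipeline.emu_study_conditions()` fixes the synthetic EMU stay used by the
replay experiments: 24 h, 4 channels at 64 Hz, twelve 3-min seizures (one
per 2 h, 6→3 Hz chirp at 180 µV RMS on half the channels), 20 µV pink
background, seven 9-Hz 50 µV 60-s bursts per hour, 70% patient response
rate. The deployed baseline is a fixed artifact — `make_baseline(seed=1)`,
trained on 100 windows per class of chirp-vs-background at 32 Hz — standing
in for a fixed pretrained clinical model; stay seeds vary the recording
noise, burst placement and patient behaviour, not the baseline. Because
the baseline never saw rhythmic bursts, it false-alarms on them
(≥ 0.5 FA/h), which is the regime patient-in-the-loop fine-tuning is
designed to correct. Session optimization in these conditions runs at
learning rate 10⁻⁴ — scaled to this ~20k-parameter surrogate, where the
literature rates used for large pretrained networks produce no measurable
update — with the trainable subset fixed to stem + head (progressive
unfreezing disabled: in weakly supervised negative-only sessions,
unfreezing the remaining blocks of so small a model resumes collateral
drift and erodes sensitivity).

## What the synthetic bench does and does not show

Passing tests demonstrate that the detection algebra is exact, that the
protocol's gates, splits, losses and selection rules behave as specified,
and that under the canonical conditions the closed-loop direction is
right: sequential weak-label fine-tuning lowers the false-alarm rate on
held-out future data without losing event sensitivity. They do not
demonstrate performance on real EEG: the synthetic ictal morphology is a
single parametric family, artifacts beyond line noise and flat channels
are absent, patient behaviour is a three-parameter caricature, and the
surrogate is orders of magnitude smaller than clinical models. Known
limitations: the supplementary-grade artifact rejection is replaced by
three declared thresholds; the six-class path is exercised by unit tests
only; per-iteration replay evaluation uses all data strictly after the
boundary (the exclusive reading); and weak-label noise (a patient
rejecting a true seizure) can still cost sensitivity in an unlucky stay —
the gates bound, but do not eliminate, that risk.
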