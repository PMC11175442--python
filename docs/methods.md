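# Methods

`ecgdelin` delineates single-lead ECG signals: it locates the onset and
offset of every P wave, QRS complex and T wave, with particular attention
to arrhythmias that break the assumptions of classical delineators (absent
P waves in atrial fibrillation and flutter, wide QRS in bundle branch
block and ventricular tachycardia, prolonged PR in first-degree AV block,
short RR in tachycardias). This note records the model, the algorithms,
the defaults and why, and what the synthetic experiments do and do not
demonstrate.

## Problem framing

Delineation is cast as dense semantic segmentation of the voltage trace:
every sample at the 500 Hz working rate is assigned a probability over the
four classes {none, P, QRS, T}. A post-processing stage converts the
probability map into non-overlapping typed intervals, whose endpoints are
the delineation proper. An optional two-way rhythm classifier (AFIB/AFL
vs. anything else), trained jointly with the segmentation objective,
gates a hard suppression of the P channel: when the record is classified
as fibrillation or flutter, no P wave can be emitted. All inputs are
resampled to 500 Hz before segmentation (polyphase FIR for rational rate
ratios, linear interpolation otherwise; the signal mean is removed and
restored around the filter so constant signals are exact fixed points).

## Segmentation network

A 1D encoder–decoder with full-scale skip connections (a U-Net3+-style
design):

- **Encoder**: five convolutional blocks (two convolutions each, kernel 9,
  padding 4, so length is preserved), max pooling by 2 between levels;
  the deepest feature map has 1/16 of the input resolution. Default
  channel widths 32/64/128/256/512.
- **Decoder**: at each of the four shallower levels the stage receives one
  feature from *every* encoder level and every deeper decoder level,
  resampled to the stage's resolution (average pooling downward, linear
  interpolation upward), reduced to 64 channels per source by a
  convolution, concatenated (5 x 64 = 320 channels) and fused by a
  convolutional block.
- **Head**: a kernel-1 convolution to 4 channels and a per-sample softmax.
- **Activations** are leaky ReLU with negative slope 0.01 everywhere;
  convolution weights use He-normal initialization from a caller-supplied
  seed; batch normalization uses batch statistics during training and
  running averages at inference, so inference is deterministic.
- **Classifier branch** (optional): the five encoder feature maps are
  average-pooled to the deepest resolution, concatenated, passed through
  two wide convolutions (512 filters, kernel 17, batch norm, dropout 0.2),
  globally average-pooled and mapped by a fully connected layer to a
  two-way softmax: P(AFIB or AFL) vs. P(other).

The default configuration has 14.9 million trainable parameters
(comfortably below the 2e7 budget the design targets); a reduced
configuration with widths 4/8/16/32/64, 8 aggregation channels and a
single fused convolution per decoder stage has ~0.18 million (0.26 million
with the scaled-down classifier branch, 32 filters) and is the workhorse
for CPU-scale experiments.

Channel widths, the exact block composition (conv-norm-activation twice)
and the pre-FC global pooling are this package's own choices where the
high-level design leaves them open; they are fixed in `ModelConfig` and
recorded in every checkpoint.

Inputs of arbitrary length >= 16 samples are right-padded by edge
replication to a multiple of 16 and the output cropped back, so output
length always equals input length.

The network, its losses and the Adam/cosine training loop run on a small
reverse-mode automatic-differentiation engine written in numpy
(`ecgdelin.nn`), with every primitive's backward pass verified against
central finite differences in the test suite. Working precision is
float32; convolutions are evaluated as one transpose to time-major layout
plus one strided GEMM per kernel tap.

## Losses and training

The segmentation loss is the multi-class focal loss
`-(1/N) sum_n (1 - p_n)^gamma log p_n` over time stamps, where `p_n` is
the predicted probability of the true class; `gamma = 1` by default
(gamma = 0 recovers plain cross-entropy, which the tests verify to 1e-10
against an independent computation). Log arguments are clamped at 1e-7.
The classifier branch adds a two-class cross-entropy weighted by
`alpha = 1`. Training uses Adam (default moments), initial learning rate
1e-3 annealed to 0 by a single cosine cycle over all steps, seeded
shuffling, and per-epoch augmentation. Records are cropped to their
central window — the first and last 2 s are excluded, so 10-s records
train on 6-s windows — because boundary annotations near record edges are
unreliable in practice and edge-truncated waves are ambiguous. Batch size
32 and 50 epochs are defaults; the synthetic benchmark uses batch 10 and
12 epochs, sized so the full experiment (200 training records) runs in a
few minutes on one CPU.

Augmentation applies, each with probability 0.5 per record per epoch:

- baseline wander: 50 cosines at k x 0.01 Hz, amplitudes U[0,1) scaled by
  0.05 mV, phases U[0, 2 pi) — band-limited to 0.5 Hz by construction;
- powerline noise: 3 cosines at 50/100/150 Hz sharing one random phase
  (a config switch gives independent phases), amplitudes U[0,1) scaled by
  0.02 mV;
- random resize by exp(alpha), alpha ~ U[log 0.5, log 2]; the signal is
  linearly interpolated and the label mask resized nearest-neighbour, the
  only transform that touches labels;
- Gaussian noise, sd 0.01 mV;
- constant baseline shift ~ N(0, 0.1 mV) (the shift scale is a package
  default; it is not prescribed anywhere).

Resize runs first so additive noise scales are not rescaled. The mV
scales on wander/powerline amplitudes are package choices (the amplitude
coefficients themselves are dimensionless U[0,1) draws).

## Post-processing

1. Per-sample argmax (ties broken none > QRS > P > T, a fixed order chosen
   only for determinism; ties have measure zero for trained networks),
   then run-length encoding into maximal constant-label runs.
2. Runs shorter than 40 ms are resolved iteratively, shortest first
   (leftmost on ties): if the two neighbours share a label the short run
   is relabelled to it and the three runs merge (this can cascade);
   otherwise the short run becomes `none`. Edge runs have one neighbour
   and take the second branch. A short `none` run between differing
   labels is already a fixed point. The iteration terminates when no
   wave-labelled run under 40 ms remains. The processing order is not
   canonical — different orders can give different results — so the
   chosen order is fixed, documented, and verified against a brute-force
   reference on an exhaustive enumeration of short sequences.
3. Every QRS run becomes an interval; between consecutive QRS runs only
   the single longest P run and longest T run survive (earliest on ties).
   By default waves before the first and after the last QRS are dropped —
   appropriate for records whose edge annotations are incomplete; the
   `include_edge_waves` option keeps the longest P before the first QRS
   and longest T after the last, and is used when scoring synthetic
   records, whose ground truth is complete.

P suppression: when a rhythm probability is supplied and
P(AFIB or AFL) >= 0.5, the P channel is zeroed and each row renormalized
over the remaining classes (a row that was pure P falls back to `none`).
The final delineation then provably contains no P interval. The 0.5
threshold on a two-way softmax is equivalent to the argmax rule.

Known limitations, inherent to this scheme: at most one P wave per RR
interval (second/third-degree AV block with independent atrial rhythm is
out of scope) and non-overlapping waveforms.

## Synthetic data generator

The generator emulates 10-s, 500 Hz (or 250 Hz), single-lead recordings
with exact boundary ground truth. Beats are parametric templates — a
Gaussian P bump, a piecewise-linear Q-R-S deflection, a skewed-Gaussian T —
placed on an RR schedule; each template is confined to its labelled
interval. Defaults: P 80–110 ms / 0.05–0.2 mV; QRS 80–110 ms (wide
120–160 ms) / 0.5–2.0 mV; T 120–200 ms / 0.1–0.5 mV; PR 120–200 ms.
Class-separating constraints: NSR 60–100 bpm; ST 100–180 bpm; AVB1 PR
200–320 ms; BBB and VT QRS 120–160 ms; VT 120–220 bpm; AFIB has
lognormal-jittered RR (sigma 0.2), no P waves, and a band-limited 4–9 Hz
fibrillatory baseline of 0.02–0.08 mV; AFL has a 4–5 Hz sawtooth flutter
wave (0.1–0.2 mV) with fixed 2:1 or 4:1 conduction, no P waves. Neither
atrial background is ever labelled. These thresholds are conventional
clinical values; arrhythmia definitions are not prescribed quantitatively
anywhere, so the generator's ranges are the package's own study
conditions.

At fast rates the nominal T duration cannot fit between a wide QRS and
the next beat; the generator clamps the T duration (floor 60 ms, skipping
the T below 40 ms) and the ST-segment gap to the available space instead
of rejecting draws, preserving the class constraints that matter.

Waves are labelled only when they lie fully inside the record together
with their beat's QRS complex; edge-truncated deflections remain in the
signal as unlabelled background. This keeps three properties exact: the
mask equals the rasterized interval list; every labelled interval is
>= 40 ms, so ground truth passes post-processing unchanged; and wide-QRS /
prolonged-PR class constraints hold for every labelled wave.

What the generator does *not* emulate: beat-to-beat morphology variation,
PAC/PVC ectopy, rhythm changes within a record, electrode motion
artifacts, muscle noise, QT-rate adaptation, or multi-lead projections.
Passing the synthetic benchmark therefore demonstrates that the pipeline
(training, segmentation, post-processing, suppression, scoring) is
correct and learnable end-to-end — not that the model reaches clinical
accuracy on real ECGs, which requires training on expert-annotated data.

## Evaluation

A predicted onset/offset is a true positive when a ground-truth boundary
of the same kind lies within 150 ms (inclusive), the AAMI-style
tolerance. Matching is one-to-one and optimal: maximum cardinality,
minimum total |deviation| among maximum matchings, computed as a
rectangular assignment problem. (A greedy pairing by increasing deviation
is not maximal on crossing configurations; the tests verify maximality
against an independent bipartite-matching routine.) Reported per boundary
kind, overall and per rhythm: Se = TP/(TP+FN), PPV = TP/(TP+FP), their
harmonic mean F1, and the mean and population standard deviation of the
signed deviations (prediction minus truth, positive = late). Cells with a
zero denominator are undefined and render as `-`.

Two conventions handle annotation dialects: boundary kinds absent from a
truth dialect (T onsets in QTDB-style annotations) are skipped, and a
*partial* mode excludes from FP counting any prediction with no
ground-truth annotation of any kind within 400 ms (default, configurable)
— absence of an annotation in a sparsely annotated reference does not
mean absence of the wave. With multiple predicted leads, the lead with
the lowest error contributes per boundary point, and the FP count is the
minimum across leads.

## The synthetic benchmark

`ecgdelin.pipeline.run_synthetic_benchmark` generates 200 training and 50
held-out records (40% NSR, 30% ST, 30% AFIB), trains the reduced model
with its classifier branch for 12 epochs, and scores the held-out
records. Expected behavior, asserted by the test suite: F1 >= 0.95 for
QRS boundaries and >= 0.85 for P and T boundaries; and on the held-out
AFIB records, strictly fewer P-wave false positives with
classifier-gated suppression on than off. Problem sizes (200/50 records,
12 epochs, reduced widths) are chosen so the full experiment completes in
minutes on a single CPU while leaving the qualitative conclusions intact.

## Numerical and interface choices

- Sample indices are 0-based; intervals are closed `[onset, offset]` —
  both boundaries are labelled samples, as in fiducial-point annotation
  practice. Voltages are mV throughout.
- Annotation dialects: complete per-lead on/offsets ("ludb"), or
  QTDB-style streams whose T waves carry only offsets; the latter yield
  partial intervals (onset = absent) that are never rasterized or scored
  on the missing boundary.
- WFDB support is a minimal subset written for this package:
  single-segment format-16 records and the binary annotation stream with
  `(` symbol `)` grouping; round-trips are tested against the package's
  own writer.
- Checkpoints (.npz) embed the model configuration, init seed, running
  normalization statistics and the configuration hash; every CLI artifact
  carries the config hash and seed that produced it.
- All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; identical seeds give bitwise-identical
  datasets, training runs and delineations.
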