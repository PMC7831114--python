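# Methods

This note documents the models, numerical choices, and limitations of the
`scalobeat` pipeline: what each stage computes, which parameters matter,
and what the synthetic-data tests do and do not demonstrate.

## Data model and class mapping

Input is a single-lead ECG (the ML II lead of MIT-BIH-style recordings,
360 Hz, 11-bit over 10 mV) with per-beat annotations: an R-peak sample
index and a one-character beat symbol. Symbols collapse into AAMI
super-classes: {N, L, R, e, j} → N, {A, a, J, S} → SVEB, {V, E} → VEB,
{F} → F, {Q, f, /} → Q. Q-class beats are excluded from classification
(they are vanishingly rare in non-paced records), as are the four paced
records 102/104/107/217. An unrecognized symbol raises — it is never
silently treated as normal, since that would contaminate the majority
class with unknowns.

The inter-patient partition (DS1 for training, DS2 for testing, 22 records
each, disjoint patients) follows the de Chazal convention; both lists are
plain data in `scalobeat.records` and can be overridden.

Because the `wfdb` Python package is not a dependency here, the package
carries its own minimal WFDB reader/writer (text `.hea` headers, format-212
packed 12-bit signals, MIT-format `.atr` annotations, including the SKIP
escape for long gaps). The writer uses the MIT-BIH digitization convention
(200 adu/mV, baseline 1024), so synthetic fixtures round-trip through the
same reader that serves real records, with quantization error at most one
5 µV LSB.

## Baseline correction

The wander estimate is `median200ms → median600ms`, i.e. the 600 ms filter
is applied to the output of the 200 ms filter, and the estimate is
subtracted from the raw signal. Window widths in samples are
`round(width·fs/1000)` forced odd (71 and 215 at 360 Hz) so the median is
an order statistic, not an average of two. Edges use reflect padding,
which keeps the output length equal to the input length and avoids biasing
the ends toward zero; the first/last ~0.3 s of the estimate is still less
trustworthy, which is harmless because the first and last beats of a
record are dropped anyway (see below). The cascade tracks drifts below
about 1 Hz while stepping over QRS complexes, which are narrow outliers to
a 200 ms median. Powerline and EMG noise are deliberately left in: the
scalogram transform and the network tolerate them, and aggressive filtering
risks distorting morphology.

## Segmentation and RR features

Each beat is the fixed window `[r−90, r+110)` (200 samples; ≈250 ms before
to ≈306 ms after the R peak at 360 Hz), which covers P-QRS-T at normal
rates. Beats whose window crosses a record boundary are dropped and
counted, never errors.

Four rhythm features accompany each segment:

| feature     | definition                          | adjustment |
|-------------|-------------------------------------|------------|
| previous-RR | (r_i − r_{i−1}) / fs                | − mean RR  |
| post-RR     | (r_{i+1} − r_i) / fs                | − mean RR  |
| ratio-RR    | previous-RR / post-RR (raw)         | none       |
| local-RR    | mean of ≤10 preceding RR intervals  | − mean RR  |

The mean RR is computed **per record** over all consecutive annotated
beats (after Q removal): the point of the subtraction is to cancel each
patient's resting heart rate, so a per-patient normalizer is the right
scope. RR intervals are computed on the full annotated beat sequence
before any segmentation drops, so a boundary-dropped beat still
contributes its intervals to its neighbours. The first and last beat of a
record have no previous/next interval and are excluded (≤2 beats per
record). When fewer than ten preceding intervals exist, local-RR uses
however many are available rather than discarding the first ten beats of
every record.

## Continuous wavelet transform

The CWT is discretized as correlation of the zero-extended signal with the
sampled, scale-dilated wavelet, normalized by 1/√a, with time (and hence
scale) measured in samples. The wavelet is truncated at |t| ≤ 8, where all
four supported wavelets are below ~10⁻¹³ of their peak. The test suite
pins this discretization to a brute-force trapezoidal quadrature of the
defining integral (agreement ~10⁻¹³) and cross-checks against PyWavelets,
whose cumulative-integral discretization is equivalent up to a half-sample
delay.

Supported mother wavelets and their center frequencies (cycles per sample,
the conventional values): Mexican hat 0.25 (default), real Morlet
cos(5t)e^(−t²/2) 0.8125, and the L2-normalized 4th/8th derivatives of a
Gaussian at 0.5 and 0.6. The scale↔frequency map is F = F_c·f_s/a.

Scales are the integers 1…100 — a linear grid is the simplest choice that
yields exactly 100 scale rows, and with the Mexican hat at 360 Hz it spans
≈0.9–90 Hz, generously covering the 0–50 Hz band that carries essentially
all ECG energy. The 100×200 scalogram is decimated along time to 100×100
by averaging adjacent column pairs (exact on constants, symmetric under
time reversal). Coefficients stay signed (no magnitude), then are min-max
normalized to [0, 1] per heartbeat; normalization is a config switch, and
the network's first batch-norm layer removes residual scale effects either
way.

## Network and training

The classifier is a three-unit CNN on the 100×100 scalogram fused with the
4 RR features:

conv 7×7×16 → BN → ReLU → maxpool 5/5 → conv 3×3×32 → BN → ReLU →
maxpool 3/3 → conv 3×3×64 → BN → ReLU → global max pool → 64 features →
concat RR (68) → dense 32 → ReLU → dense 4.

Convolutions are valid (padding 0, stride 1) and carry **no bias** — the
following batch-norm shift makes one redundant, and the parameter counts
(784 = 7·7·1·16 exactly) pin this down. Dense layers carry bias
(2208 = 68·32 + 32). Pooling extents use floor division (94→18 at 5/5,
16→5 at 3/3). The final "3×3" pool is a true global pool: its 1×1×64
output forces global behaviour over the 3×3 map. Counting batch-norm as 4
values per channel (scale, shift, two tracked statistics), the totals per
layer are 784/64/4608/128/18432/256/2208/132 = 26,612. A ReLU between the
two dense layers is this package's choice; it adds no parameters and is
standard for an MLP head.

Training: softmax cross-entropy (weighting available but off by default —
no resampling or class weights are part of the reference configuration),
Adam with standard moments (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸), He-initialized
conv/dense weights, learning rate 10⁻³ multiplied by 0.1 every 5 epochs
(epoch e uses 10⁻³·0.1^⌊e/5⌋), batch size 1024, up to 30 epochs, no
validation split or early stopping — the final-epoch model is kept.
Prediction is argmax over raw scores; ties resolve to the lowest class
index (N < SVEB < VEB < F). Softmax is applied only inside the loss and
for optional probability output.

The network is implemented directly in NumPy with hand-written backprop
(im2col convolutions backed by BLAS, scatter-based pooling gradients,
standard batch-norm gradients). Gradients are verified against central
finite differences in float64; training defaults to float32 for speed.
Everything is CPU-only and bit-deterministic for a fixed seed.

## Evaluation

Per class i, one-vs-rest counts are TP = cm[i,i], FP = column − TP,
FN = row − TP, TN = total − row − column + TP, and

PPV = TP/(TP+FP), SE = TP/(TP+FN), ACC = (TP+TN)/total,
F1 = 2·PPV·SE/(PPV+SE).

Overall figures are unweighted arithmetic means across the four classes of
the *unrounded* per-class values; the overall "accuracy" is the macro
average of the one-vs-rest accuracies (with heavily imbalanced classes
this is far higher than plain multiclass accuracy — a reporting convention
to be aware of when comparing numbers). Zero denominators (a class never
predicted, or absent) yield 0 with a warning; the F class, with only a few
hundred examples against ~44k normals, routinely exercises this path.

## Synthetic data: what it emulates, and what it does not

The generator produces 360 Hz single-lead records of Gaussian-bump
P-QRS-T complexes with per-beat annotations, sinusoidal baseline wander,
and white noise. Defaults: 60 s records at 72 bpm with 3% RR jitter,
mixture 80% normal / 10% PVC-like / 10% APB-like, 0.1 mV wander at 0.3 Hz,
0.02 mV noise — unremarkable values for resting sinus rhythm with light
respiration-band drift. PVC-like beats are wide (≈3× QRS width), tall,
P-free, with discordant T; APB-like beats are near-normal in shape with an
early flattened P. Both premature classes shorten their preceding RR to
0.70× and stretch the following interval by 1.35× (a compensatory pause).
Each synthetic "patient" draws its own multiplicative template
perturbations (10% sd) so the inter-patient split is meaningful: test
patients have morphology the model never saw.

APB-vs-normal separation rests almost entirely on rhythm, so the synthetic
task genuinely exercises the RR-fusion path, not just the convolutional
trunk; PVC-vs-normal rests on morphology. What the generator does *not*
emulate: realistic P/T-wave variability, atrial fibrillation and other
non-stationary rhythms, electrode artifacts, muscle noise, fusion (F)
beats, or the extreme class imbalance of real Holter data. Passing the
synthetic end-to-end test therefore demonstrates that every stage is wired
correctly and that the model can generalize across patients when the
classes are separable at desk scale — it does not predict performance on
real recordings, which requires the real database (supported through the
same CLI on a downloaded WFDB directory).

## Desk-scale experiment sizes

The shipped end-to-end experiment uses five 60 s synthetic patients
(three train, two test; ≈345 beats total), 15 epochs, and batch size 8.
The small batch is deliberate: with ~200 training beats, batch 1024 would
collapse each epoch into a single optimizer step, and the aggressive decay
schedule would end training after a handful of updates; batch 8 restores
an optimizer-step count per unit data comparable to the full-scale
configuration while leaving every other training rule (loss, optimizer,
schedule, epoch budget) unchanged. Under these conditions the pipeline
reaches ≥95% held-out accuracy in about a minute on one CPU core.

With only three training patients, run-to-run variability is substantial:
an unlucky draw of patient templates can leave a test patient's morphology
outside the training span, and held-out accuracy drops well below the
typical value even though training accuracy is high. This is the
inter-patient problem in miniature, and it is why the end-to-end check is
specified at a fixed seed rather than as an average over runs.

## Known limitations

* Format 212 is the only WFDB signal format supported (it is the MIT-BIH
  format); multi-segment records and other formats are out of scope.
* The CWT is real-valued only; complex wavelets and the inverse transform
  are not implemented.
* Scale placement (linear 1…100) and per-heartbeat min-max normalization
  are conventions chosen here; both are exposed in the API, and the
  wavelet itself is selectable (`mexh`, `morl`, `gaus4`, `gaus8`).
* Training is single-threaded NumPy: fine at desk scale, slow for the
  ~51k-beat full database (hours, not minutes — practical, but not quick).
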