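# Methods

## Problem setting

Clinical full-field electroretinography (ERG) compares a patient's waveform
parameters against laboratory reference ranges. Reference cohorts are often
imbalanced — here, sex-imbalanced, with male recordings the minority — which
biases downstream classifiers. `ergsynth` implements and evaluates one remedy:
a conditional generative adversarial network (CGAN) that synthesizes
minority-class waveforms, compared against doing nothing and against random
oversampling with replacement, on a held-out unbalanced test split.

The package works with two light-adapted ISCEV stimuli: the single-flash LA3
response (a-wave trough, b-wave peak, oscillatory potentials) and the 30 Hz
flicker steady-state response.

## Waveform simulator

No public generative model of the pediatric LA3 waveform exists, so the
package defines a minimal phenomenological kernel in continuous time:

    v(t) = −A_a exp(−(t−t_a)²/2σ_a²) + A_b exp(−(t−t_b)²/2σ_b²)
           + A_op exp(−(t−t_op)²/2σ_op²) sin(2π f_op (t−t_op))

a negative Gaussian lobe for the a-wave, a positive lobe for the b-wave, and a
Gaussian-windowed sinusoid for the oscillatory potentials on the ascending
limb. The flicker kernel is a 30 Hz fundamental plus 2nd/3rd harmonics, with
harmonic k carrying phase k·φ so that a phase change translates the periodic
waveshape rigidly in time.

Defaults (µV, ms): a-wave 10 µV at 15 ms (width 4 ms), b-wave 25 µV at 32 ms
(width 8 ms), OPs 2 µV at 120 Hz centered at 24 ms, white noise SD 2 µV.
These are plausible pediatric light-adapted magnitudes; all are configurable.
Sampling is 1 kHz with 0.25 s LA3 records and 0.30 s flicker records (nine
full cycles) — long enough to contain every light-adapted component, short
enough to keep the GAN small.

### Study-emulation fixture

`make_study_fixture` reproduces the reference cohort's composition exactly:
170 LA3 waveforms (60 male / 110 female, 85 per eye) and 67 flicker waveforms
(18 male / 49 female, 33 left / 34 right). Only the marginals of that table
are known; the joint sex×eye allocation is the simplest consistent one (males
30/30 and 9/9 per eye; females take the remainder, 55/55 and 24/25). Subject
identifiers are shared across the two eyes of a subject to mimic
within-subject replicates.

Two kinds of variation are simulated:

* **Between-subject variability** — each subject draws its own kernel
  parameters around the base values: multiplicative lognormal factors with
  CV 0.15 on amplitudes and CV 0.08 on widths, additive Gaussian jitter with
  SD 1.5 ms on peak times, SD 0.2 rad on flicker phase. Without it every
  waveform of a class would be identical up to noise and any classifier would
  saturate; the chosen CVs reflect typical inter-individual spread of
  light-adapted ERG amplitudes and implicit times.
* **Within-record noise** — additive white Gaussian noise (SD 2 µV).

The **sex effect** is a configurable per-parameter shift applied to one
class. Default: male b-wave amplitude ×0.9 and b-wave time +1.5 ms (flicker:
amplitude ×0.9, phase +0.2 rad) — a modest, detectable difference. The true
magnitude of the sex difference in real cohorts is not established; this
default is a stand-in and the identity effect gives a null configuration for
calibration.

What the simulator does **not** emulate: electrode/skin artifacts, blink
residuals, luminance-response (photopic hill) nonlinearity, age effects,
inter-device filter differences, or any correlation between LA3 and flicker
responses of the same subject beyond shared identifiers. Tests passing on
simulated data demonstrate the pipeline's internal correctness and the
direction of its behaviour under a known class effect — not performance on
any real cohort.

## Feature extraction

The clinical time-domain parameters are extracted by peak detection:

* `ta`, `la` — time and amplitude of the a-wave trough: global minimum within
  a search window of 5–25 ms; `la` is measured from the baseline (mean of the
  first 5 ms) to the trough.
* `tb`, `lb` — time and amplitude of the b-wave peak: global maximum within
  15–60 ms constrained to t > ta; `lb` is trough-to-peak by default (the
  usual clinical convention), with a baseline-to-peak switch since published
  descriptions are often ambiguous on this point.
* Flicker `lb` — mean peak-to-adjacent-trough amplitude over steady-state
  cycles (the first cycle is discarded as onset transient); flicker `tb` —
  latency of the first steady-state peak within its own 1/30 s cycle. The
  steady-state convention is a package decision; peak detection uses a
  minimum inter-peak distance of 80 % of the stimulus period.

Ties in extremum location break to the earliest sample. Records with flat or
monotone search windows raise a flagged extraction error and are excluded
(and counted) rather than silently imputed. Tests hold extraction to within
one sample in time and 1 % in amplitude of a dense-grid oracle evaluated on
the continuous kernel, for kernels whose a-wave trough is actually
measurable (trough depth ≥ 85 % of the nominal a-wave amplitude; a broad
b-lobe can otherwise swallow the trough entirely, which the extractor
correctly reports as an error).

## Conditional GAN

Generator: latent vector (64 dims, standard normal) concatenated with a
one-hot class label → fully connected 128 → 256 → signal length, leaky-ReLU
hidden activations, tanh output on a normalized scale. Discriminator is the
mirror image ending in one logit. Waveforms are normalized by a per-dataset
min–max map to [−1, 1] and de-normalized on sampling. Training is
alternating non-saturating binary cross-entropy with Adam (learning rate
2·10⁻⁴, β₁ = 0.5), batch 16, 300 epochs; one generator per stimulus. The
forward/backward passes are written directly in numpy, which keeps training
bit-reproducible from a single seed on any platform.

**Matching-aware conditioning.** With plain input concatenation the one-hot
label (2 dimensions) carries almost no gradient next to a 250-dimensional
signal, and the two conditioned distributions collapse onto each other. The
discriminator is therefore also trained on (real waveform, wrong label)
pairs as fakes (weight 0.5) — the matching-aware scheme from the
conditional-generation literature — which forces it to score label–waveform
consistency and restores the class-conditional separation of generated
samples. This term can be disabled in `GanConfig`.

Failure modes: a non-finite loss aborts training with a diagnostic; mode
collapse is visible in the per-epoch loss log but is not automatically
detected. A morphology plausibility gate (trough in 5–25 ms, later peak in
15–60 ms, bounded peak-to-peak) is used as a test-harness quality metric and
is available as optional rejection sampling, off by default.

## Post-processing

Generated signals carry broadband generator noise. The smoothing operator
takes the real FFT, zeroes every bin strictly above the cutoff (default
150 Hz — below the recording band edge of 300 Hz but above the OP band), and
inverts. Hard truncation was chosen over a tapered filter because it is the
simplest bit-reproducible operator that is exactly linear, idempotent and
energy-non-increasing; the cutoff is configurable. By default it is applied
to synthetic waveforms only.

## Augmentation policies

Two selectable policies (their coexistence reflects a genuine ambiguity in
how such pipelines are described):

* `synth_fraction` (default 0.20 of the **initial** pre-split dataset size,
  e.g. 34 synthetic records for a 170-record dataset);
* `balance_to_parity` — exactly the count that equalizes class totals.

Augmentation appends; it never mutates or drops real records.

## Classification protocol

Random forest on (ta, la, tb, lb) for LA3 and (tb, lb) for flicker, tuned by
grid search (trees ∈ {100, 300}, depth ∈ {∞, 5, 10}, features per split
∈ {all, √p}) with stratified 3-fold cross-validation selecting on balanced
accuracy, then refit on the full training rows. The protocol description
this mirrors names both three folds and an 80:20 inner ratio, which are
mutually inconsistent; the folds are implemented, the ratio is only echoed
in the configuration. Metrics are computed from the package's own confusion
counts with **male (the minority) as positive class**:

    precision = TP/(TP+FP)   recall = sensitivity = TP/(TP+FN)
    specificity = TN/(TN+FP)
    balanced accuracy = (sensitivity + specificity)/2
    F1 = 2·precision·recall/(precision+recall)

Zero denominators raise an explicit undefined-metric error, never a silent 0.

Three conditions are evaluated per stimulus — original, oversampled (random
oversampling of minority feature rows with replacement to parity), and
synthesized (GAN augmentation + low-pass + feature extraction) — all scored
on the identical untouched, unbalanced real test rows; the report carries a
SHA-256 hash of those rows to prove it.

## Splitting

Stratified by sex; default unit is the subject (all eyes/replicates of a
subject stay together, preventing replicate leakage), with a record-level
option. Held-out count per stratum is round(fraction × units). A record-level
20 % split of the 170-record LA3 set holds out exactly 34 records.

## Reproducibility

A root seed fans out through a deterministic string-keyed mapping into named
child seeds (fixture, split, gan, sample, oversample, classifier,
embedding), all below 2³¹. Identical configuration and seed give
byte-identical reports. t-SNE embedding (scikit-learn) is visualization-only
and deliberately excluded from every quantitative claim.

## Problem sizes used in the shipped analyses

The package's own evaluation runs use the fixture at its natural size
(170 LA3 / 67 flicker waveforms), 300 GAN epochs, and five root seeds for
the repeated-seed analyses; the null-calibration and direction analyses use
the LA3 stimulus, whose larger sample makes it the informative case.

## Known limitations

* The simulator's Gaussian-lobe kernel reproduces morphology, not retinal
  biophysics; parameter recovery results do not transfer to pathological
  waveforms (e.g. electronegative ERGs), where the search windows and the
  trough-prominence assumption fail.
* At ~136 training waveforms the CGAN's conditional fidelity varies
  noticeably with the training seed even with matched conditioning; the
  evaluation therefore reports medians over seeds.
* Balanced accuracy on a ~30-record test split is quantized in steps of
  several percent; small condition differences are not resolvable at this
  scale.
* The optional adapter for the originating study's deposited data files is
  not implemented (their exact layout is undocumented); real datasets can be
  supplied via the package's own CSV dialect.
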