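# Methods

## Problem setting

Collar-mounted recorders capture continuous mono audio from individual
giant pandas. Clips of fixed length (nominally 60 s at 44,100 Hz) are
labelled with one of a small set of behaviours (eating, resting, moving,
nursing, drinking). The classifier must generalise to individuals absent
from training, so all evaluation is leave-one-individual-out (LOIO): one
fold per animal, testing on every clip of the held-out animal.

## Noise reduction

Spectral gating on the STFT (Hann window, 2048 samples, hop 512 —
standard values for 44.1 kHz audio; the window satisfies COLA so the
inverse transform is exact to machine precision). Per frequency row, the
magnitude spectrogram is smoothed with a first-order recursive filter
`y[t] = a·y[t−1] + (1−a)·x[t]` run forward then backward (zero phase),
initialised at the boundary sample so constants are fixed points;
`a = 0.9` by default. Two noise estimators:

* **non-stationary** (default): `N = thresh_factor · Ssmooth_slow`, where
  the slow smoother uses `a = 0.99`. Transient events rise above the
  slowly varying floor and pass; drifting background (wind, rubbing) is
  gated. `thresh_factor = 1.0`.
* **stationary**: `N(f) = μ_f + n_std·σ_f` from the row's time
  statistics; `n_std = 1.5`.

Gain `G = max(1 − N/Ssmooth, 0)`, with `G := 0` where `Ssmooth = 0` (the
"no signal → fully gated" limit). The gain multiplies the complex STFT;
phase is untouched. Consequences worth knowing: the gate never amplifies,
increasing the noise estimate can only reduce output magnitudes, and a
*steady* tone is treated as background by the non-stationary estimator —
the design assumes behaviourally informative sound is transient
(chews, footfalls, squeaks), which holds for this domain.

## Mel features

Pre-emphasis `y[n] = x[n] − 0.97·x[n−1]` (field-standard coefficient),
centred framing with a 0.16 s Hann window, FFT at the next power of two
(8192 bins at 44.1 kHz), power spectrum, 64 triangular mel filters
between 0 Hz and Nyquist, log compression `10·log10(max(M, 1e−10))`, and
per-clip standardisation (zero mean, unit variance) before the network.

The frame hop is **0.06 s**. With centred framing (zero-padding by half a
window on both sides) the frame count is `1 + floor(n_samples/hop)`, so a
60 s clip yields exactly 1001 frames and the network input is
`(1, 64, 1001)`. A 0.6 s hop would give ~101 frames and cannot produce
that tensor shape; the downstream-verified shape is the binding
constraint, so the hop is fixed at 0.06 s.

## Model

Backbones are expressed in a small NumPy layer toolkit written for this
package (grouped/depthwise convolutions, batch norm, residual and
shuffle blocks, squeeze-and-excitation; analytic backward passes verified
against finite differences). The registry mirrors the standard
architectures — ResNet50, VGG16, MobileNetV1/V2/V3, ShuffleNetV2 (×1.0),
EfficientNetB0 — with the classifier removed and the first convolution
taking one input channel. `tinycnn` (four conv–BN–ReLU–maxpool blocks,
8→16→32→64 channels) is the desk-scale backbone used for trained tests.

Each head is a bias-free 1×1 convolution, so the class activation map
`M_j(x,y) = Σ_k W_{j,k} F_k(x,y)` is exact and `GAP(M_j) = S_j` holds
identically; bias-free heads keep the CAM decomposition clean at
negligible parameter cost. The single-branch inference model (backbone +
one head, 1-channel input, 5 classes) has 23,512,000 trainable parameters
for ResNet50 and 1,258,292 for ShuffleNetV2 — 23.51 M and 1.26 M.
Since the two heads converge by the end of training, branch 1 is the
default at inference; `mean` is also available.

## Objective

* **Focal loss** on the softmax of the mean branch scores, γ = 2.
  Class weights are inverse class frequency normalised to sum to C, so a
  balanced set reduces to the α-free form. The exact α formula is a
  design choice (only "from the class distribution" is prescribed);
  inverse frequency is the conventional reading.
* **Overlap penalty** `L_oap`: the spatial *sum* (not mean) of the
  product of the two branches' sigmoid masks, averaged over classes. The
  value therefore scales with the feature-map area h·w, which makes the
  effective competition strength backbone-dependent — kept as printed,
  and worth remembering when comparing backbones.
* **Balance penalty** `L_bsp`: mean absolute difference of the branch
  score vectors; unweighted in the total, exactly as the formulation
  prescribes.
* Total: `L_fl + λ·L_oap + L_bsp`, with λ decaying **linearly** from 1
  (first epoch) to 0 (last epoch). Only "gradual decay" is prescribed;
  linear is the default and a cosine schedule is available
  (`loss.lambda_schedule`).

All three terms reach the network only through the CAM tensors (scores
are spatial means of the maps), so the implementation computes
`∂L/∂M1, ∂L/∂M2` analytically and backpropagates from there; the
gradients are finite-difference-checked in the tests. Sub-gradient 0 is
used at the `|S1 − S2|` tie, and logs are clamped at 1e−12.

## Training and evaluation

Defaults follow the method's recipe: batch 16, Adam at 1e−4 with cosine
annealing, 40 epochs, final-epoch model (no early stopping). One master
seed fans out to per-fold model and shuffling seeds; runs are exactly
reproducible (pure NumPy, no threading nondeterminism). Accuracy is
fraction-correct; per-class precision/recall are one-vs-rest from the
confusion matrix; the single reported F1 is support-weighted by default
(macro via option) — with heavy imbalance the weighted F1 tracks accuracy
closely, matching how the headline numbers behave. Fold aggregates are
mean ± population standard deviation.

Desk-scale conditions used by trained tests: the two-cue dataset (below),
`tinycnn`, 20 epochs, Adam at 3e−3. The raised learning rate is the
appropriate counterpart of 1e−4 for a network four orders of magnitude
smaller trained on ~10² rather than ~10⁴ clips; 20 epochs keeps one
training run near 15 s so the multi-seed mechanism checks fit in a normal
CI run.

## Synthetic data: what it emulates, and what it does not

Behaviours are Poisson-timed mixtures of basic acoustic events (band-pass
noise bursts for chewing, low-frequency damped sinusoids for footfalls,
slow band-limited noise for breathing, AM harmonic stacks for gurgles,
high harmonic stacks for cub squeaks); individuals apply bounded pitch
(≤ 4 semitones), timing-jitter and gain perturbations; recordings add
friction bursts, AM wind-like coloured noise, and a white floor, then
peak-normalise to 0.9. The default class mix is imbalanced the way
captive-panda data is (resting ≫ eating ≫ moving ≫ nursing ≫ drinking),
and nursing is deliberately a resting base plus sparse squeaks so the
nursing↔resting confusion of real data has a synthetic counterpart. The
squeak rate (0.8/s) is set so a 6 s clip almost surely contains at least
one squeak — the class is hard, not undefined. By design the default
five classes are linearly separable (> 95 %) on oracle band-energy/event-
count features, so failures to learn indict the model, not the data.

The **two-cue** variant gives every class two spectrally disjoint
diagnostic tones (one low-band, one high-band, class bands
non-overlapping). Either cue alone identifies the class, which makes
competitive fusion falsifiable: the only way both branches can classify
while avoiding mask overlap is to split the cues between them. The
mechanism tests confirm (i) under fixed λ = 1 the branch-mask overlap
falls below its initialisation value, (ii) the full objective's mean
LOIO accuracy over five seeds is at least the no-penalty baseline's, and
(iii) after λ decay, single-branch and mean-branch predictions agree on
≥ 95 % of held-out clips.

Desk-scale generation defaults to 6 s clips at 8 kHz — one-tenth scale
through identical code paths; full-length 60 s / 44.1 kHz generation uses
the same functions. What passing these tests does **not** show: synthetic
events are stationary-in-kind and spectrally clean, with no reverberation,
no MP3 compression artefacts, no off-collar conspecific sounds, and
individual variation far simpler than real vocal-tract differences.
Results here validate the implementation and the mechanism, not
field-deployment accuracy.

## Known limitations

* Training the full-size backbones in the NumPy toolkit is supported but
  impractically slow beyond toy inputs; trained experiments use
  `tinycnn`. Parameter accounting and forward inference work for all
  registered backbones.
* MP3 decoding is not supported (WAV only); the original recordings'
  compression artefacts are out of scope.
* ImageNet-style pretraining is not available; all training is from
  random initialisation, which at full scale would likely change
  absolute accuracies.
* The non-stationary noise estimator attenuates steady tonal signals;
  for domains with sustained vocalisations the stationary mode or a
  smaller `thresh_factor` is preferable.
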