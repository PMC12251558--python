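# gpbr — audio-based giant panda behaviour recognition

`gpbr` implements an end-to-end pipeline for recognising the behaviour of
giant pandas (*Ailuropoda melanoleuca*) from collar-microphone audio:
non-stationary spectral-gating noise reduction, log-mel spectrogram
features, and a dual-branch class-activation-map (CAM) classifier trained
with **competitive fusion learning**. It is written for bioacousticians
and ML researchers who want to study the method itself; because real
collar datasets are rarely shareable, the package ships a synthetic
bioacoustic data generator so that every stage — including the learning
mechanism — is testable end to end on a laptop CPU.

## The method

**Denoising.** On the STFT spectrogram `S(f,t)`, a zero-phase first-order
recursive smoother per frequency row gives `Ssmooth(f,t)`; a noise
estimate `N(f,t)` (a slow-smoothed spectrogram by default, or
per-frequency `μ_f + n·σ_f` in stationary mode) sets the gain

```
G(f,t) = max(1 − N(f,t)/Ssmooth(f,t), 0),   X = S · G,
```

and the inverse STFT returns the denoised waveform. Gains live in
`[0, 1]`, so the gate only ever attenuates.

**Features.** Pre-emphasis, Hann-windowed frames (0.16 s window, 0.06 s
hop), FFT power spectrum `P(f)`, and 64 triangular filters equally spaced
on the mel scale `mel(f) = 2595·log10(1 + f/700)`:
`M(m) = Σ_f P(f)·H_m(f)`, then log compression. A 60 s clip at 44.1 kHz
becomes a `(1, 64, 1001)` tensor.

**Classifier.** A CNN backbone (ResNet50 by default; several lightweight
alternatives and a `tinycnn` desk-scale backbone are registered) maps the
input to a feature grid `F ∈ R^{h×w×d}`. Each head is a bias-free 1×1
convolution: the class activation map is
`M_j(x,y) = Σ_k W_{j,k} F_k(x,y)` and its global average pool is the
class score `S_j` — identical to an FC layer on pooled features.

**Competitive fusion learning.** Two heads share the backbone and are
trained with

```
L = L_fl + λ·L_oap + L_bsp
```

where `L_fl` is class-balanced focal loss on the softmax of the mean
scores, `L_oap = (1/C)·Σ_j Σ_{x,y} a¹_j ⊙ a²_j` penalises overlap of the
heads' sigmoid masks (forcing them to attend to *different* acoustic
events), and `L_bsp = (1/C)·Σ_j |S¹_j − S²_j|` keeps the competition
balanced. λ decays linearly from 1 to 0 over training, so the branches
compete early, then converge — one branch suffices at inference, at no
extra cost. Evaluation is leave-one-individual-out: each fold tests on an
animal the model never heard.

The network layers (convolutions, batch norm, pooling, backprop, Adam
with cosine annealing) are implemented directly on NumPy arrays inside
the package, so there is no deep-learning-framework dependency.

## Worked example

Generate a small "two-cue" synthetic dataset (each class carries two
spectrally disjoint diagnostic tones), train the desk-scale backbone with
leave-one-individual-out cross-validation, and label a clip:

```bash
gpbr simulate --out demo/data --individuals 3 --per-class 4 --two-cue --seed 7
# wrote 60 clips (5 classes, 3 individuals) to demo/data

printf 'train:\n  lr: 3.0e-3\n  epochs: 20\n  seed: 7\n' > demo/desk.yaml
gpbr train --manifest demo/data/manifest.csv --out demo/run --config demo/desk.yaml
# {"mean_accuracy": 0.6, "std_accuracy": 0.187, "mean_f1": 0.574, "std_f1": 0.201}

gpbr infer --ckpt demo/run/model.npz --wav demo/data/panda_0_twocue_0_000.wav
# {"label": "twocue_0", "probabilities": {"twocue_0": 0.41, "twocue_1": 0.31, ...}}
```

The train command prints the cross-validated mean ± standard deviation of
accuracy and F1 over the three held-out individuals (here 60 % ± 19 % on
a deliberately tiny 60-clip set — far above the 20 % chance level, with
the spread reflecting individual differences) and writes per-fold
confusion matrices, per-epoch loss curves, the resolved config, and a
final model checkpoint into `demo/run/`. `infer` reports the predicted
behaviour with per-class probabilities; above, a held-out `twocue_0` clip
is labelled correctly.

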