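# snnface

Shallow convolutional models of the primate **subcortical face-processing
pathway** (superior colliculus → pulvinar → amygdala), built for studying why
that pathway classifies facial expressions quickly but inaccurately, and how
it encodes spatial frequency (SF).

The package is aimed at computational-neuroscience work: it provides the
model family, the stimulus machinery and the analyses as reusable, tested
library code that runs at desk scale on synthetic face-like imagery, so no
access-restricted face database is needed to exercise any stage.

## What is modelled

The base shallow network (SNN) mirrors three properties of the subcortical
pathway:

1. **Shallow processing** — two convolution + pooling stages and two fully
   connected layers (Layer 1: 11×11 conv stride 4 → 55×55×32; 5×5/stride-4
   ceiling-mode max pooling → 14×14; Layer 2: 5×5 conv → pooling → 4×4×64;
   FC1 = 32 units; FC2 = 7 expression classes).
2. **Concentric receptive fields** — the first layer is a fixed, analytic
   bank of 32 difference-of-Gaussians filters
   `DoG(r) = ±A₁·exp(−r²/2σ₁²) ∓ A₂·exp(−r²/2σ₂²)` with A₁ ∈ {0.4, 0.67,
   0.8, 1.0}, A₁ − A₂ = 0.4, and ON/OFF polarity pairs. It is never trained.
3. **Wide spatial pooling** — 5×5 pooling windows with stride 4.

Each property can be replaced by its cortical counterpart — Gabor filters
`g(x,y) = A·exp(−(x²+y²)/2σ²)·exp(2πif(x cosθ + y sinθ))` (32 kernels:
2 frequencies × 8 orientations × even/odd), two added 3×3 convolutions, or
narrow 3×3/stride-2 pooling — yielding 9 named variants (`snnface.PRESETS`).

Two analyses probe the trained models:

* **SF reference frames** — each FC1 unit's tuning curve over 61 bandpass
  center SFs (1–64 cycles/object, 0.1 log₂ steps) at face sizes 198 and
  99 px gives the *peak shift* `(log₂ p_large − log₂ p_small)/log₂(size
  ratio)`: 1 for retina-based coding, 0 for object-based (size-invariant)
  coding. Population peak-shift distributions are summarized by Gaussian-KDE
  mode locations and a bootstrap-calibrated excess-mass multimodality test.
* **Pooling and size invariance** — the dissimilarity index
  `D(x,y) = ‖x−y‖/(N·M)` between population responses to large and small
  stimuli, before (conv1) and after (pool1) max pooling, shows how pooling
  builds size-invariant low-SF responses; wide pooling does so more than
  narrow pooling.

## Worked example

```python
import snnface as sf
from snnface.training import TrainConfig, initialize_weights, train, evaluate_confusion

bank = sf.enumerate_dog_bank()            # 32 analytic DoG kernels
model = sf.build_model(sf.preset("snn"), bank)
initialize_weights(model, seed=11)

data = sf.generate_dataset(40, seed=11)   # 280 synthetic faces, 7 expressions
augmented = sf.augment_dataset(data)      # 70× sizes/positions/flips -> 19,600
train_set, val_set, test_set = sf.split_by_individual(
    augmented, (0.75, 0.05, 0.2), seed=11
)
trace = train(model, train_set, val_set,
              TrainConfig(iterations=20_000, eval_interval=5_000, seed=11))
cm, rate = evaluate_confusion(model, test_set)
print(f"mean correct rate: {rate:.3f} (chance 0.143)")
```

This prints

```
mean correct rate: 0.657 (chance 0.143)
```

— the shallow model learns the 7-way expression task on held-out synthetic
identities well above the 1/7 chance level, while staying far from perfect,
the qualitative regime the architecture is designed to study. The 7×7
row-normalized confusion matrix is in `cm.rates`.

The reference-frame machinery runs on planted synthetic units:

```python
from snnface.synthetic_data import SyntheticUnitSpec, generate_synthetic_unit_responses
from snnface.sf_analysis import peak_shift

large, small = generate_synthetic_unit_responses(SyntheticUnitSpec(lam=1.0))
print(peak_shift(large, small).shift)   # 1.0  (pure retina-based unit)
```

## Module map

| module | contents |
| --- | --- |
| `filter_banks` | DoG/Gabor kernel formulas and the two 32-filter banks |
| `architectures` | NumPy conv/pool/LRN/FC layers, the 9 model presets |
| `stimuli` | augmentation, identity splits, input formatting, bandpass probes |
| `training` | SGD protocol, initialization, confusion-matrix evaluation |
| `sf_analysis` | tuning curves, peak shifts, KDE modes, excess-mass test |
| `pooling_effect` | dissimilarity index/curves, before–after pooling ratios |
| `synthetic_data` | procedural faces and planted SF-tuned unit populations |

See `docs/methods.md` for modelling assumptions, parameter choices and
numerical details.
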