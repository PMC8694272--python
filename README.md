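# fspet

Adversarial segmentation of the frontal-cortex band in brain FDG-PET
sections, with a convolutional auto-encoder (CAE) anatomical shape
prior.

## The problem

¹⁸F-FDG PET images glucose metabolism and is a standard research
criterion for Alzheimer's disease, where the frontal cortex shows
progressive metabolic decline. Segmenting that region in PET is hard
for exactly the reasons that make PET clinically interesting: low
contrast, low resolution, blurred tissue boundaries, and very small
expert-annotated corpora. Plain supervised networks produce fragmented
or anatomically implausible masks in this regime.

`fspet` is for researchers who want a tested, reproducible
implementation of the fused adversarial + shape-prior training scheme,
exercisable end to end on CPU with a built-in synthetic phantom
benchmark that mimics the statistical difficulty of the task (a thin,
curved, low-contrast cortex ribbon with blurred boundaries).

## The model

A U-net generator G maps a slice x to a soft mask G(x). A conditional
discriminator D scores (x, mask) pairs as annotation vs. generation. An
auto-encoder with encoder f and decoder g is first trained on a
population of expert mask shapes by minimizing BCE(y, g(f(y))), then
frozen. The generator minimizes the three-term objective

    L_G = E[−log D(x, G(x))] + λ₁ E[L_dice(G(x), y)] + λ₂ E[(f(G(x)) − f(y))²]

with λ₁ = 10⁻², λ₂ = 10⁻⁴, while the discriminator minimizes

    L_D = E[−log D(x, y)] + E[−log(1 − D(x, G(x)))]

in alternating Adam steps. Setting λ₂ = 0 gives the cGAN-Unet ablation;
removing the adversarial term as well gives plain U-net training.
Masks are evaluated with Dice, Jaccard, sensitivity, specificity and
the Hausdorff distance, reported per case as mean ± sample std.

Everything — including the convolution/backprop engine in `fspet.nn` —
is implemented in NumPy and validated against numerical gradients; see
`docs/methods.md` for architectures, desk-scale training presets and
design rationale.

## Worked example

```python
from fspet import FSPET, PhantomParams

# 250 seeded low-contrast phantoms: 200 train / 50 test, 128x128
model = FSPET.from_phantom(PhantomParams(), n_train=200, n_test=50, seed=0)
results = model.fit()      # CAE phase, then adversarial phase (~10 min CPU)
print(results.summary())
```

prints

```
FSPET fit summary
=================
variant:          fspet (adversarial=True, lambda1=0.01, lambda2=0.0001)
seed:             0
training pairs:   200
image size:       128
gan epochs:       10 (lr 0.002)
cae:              latent_dim 64, 30 epochs, final BCE 0.0063
final losses:     Ld 4.5180 | Lu 0.4428 | Le 8.5501 | LG 4.5233 | LD 0.0306
test metrics:     dice: 89.35 ± 0.90 | jaccard: 80.77 ± 1.48 | sensitivity: 94.84 ± 1.16 | specificity: 99.37 ± 0.07 | hausdorff: 5.12 ± 7.02
```

Reading the output: the auto-encoder reconstructs held-out mask shapes
almost perfectly (final BCE 0.006 ≈ a ~0.96 reconstruction Dice), and
the fused model recovers the cortex ribbon on unseen low-contrast
slices with ~89 % Dice and a mean worst-case boundary error (Hausdorff)
of ~5 px on a 128-px image whose ribbon/tissue contrast (0.15) is three
times the noise level — a boundary that is not visually resolvable
pixel-by-pixel.

The same pipeline is scriptable from the shell:

```bash
fspet simulate  -c run.yaml     # phantom corpus + manifest
fspet train-cae -c run.yaml     # phase 1: shape prior
fspet train     -c run.yaml     # phase 2: adversarial training
fspet evaluate  -c run.yaml     # per-case metric CSV/JSON
fspet report    -c run.yaml     # mean ± std table across variants
```

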