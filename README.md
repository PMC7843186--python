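# glioseg

Segmentation of glioma sub-regions in multi-contrast MRI-like images,
built as a fully offline, seeded toolkit. The pipeline chains four
stages, each usable on its own:

1. **Variational denoising** with a stochastic directional local search:
   minimize `Ω(I) = Σ √(1 + β²|∇I|²) + (λ/2)(I − I₀)²` by adaptive
   gradient descent, then propose seeded reconstruction operators
   (Gaussian blur, mean filter, global intensity scaling) on detail
   regions found by row/column/anti-diagonal scans, accepting only
   objective-lowering proposals.
2. **A spiking random-projection segmentation network**: channels are
   rate-coded by a deterministic integrate-and-fire rule, passed through
   a fixed seeded conv(9×9) → avg-pool(7×7) → conv(9×9) → max-pool(5×5)
   stack, mapped by an immutable random hidden layer `h = g(Wx + b)`,
   and read out by a closed-form minimum-norm generalized-inverse solve
   `β = H⁺Y` against one-hot targets (extreme-learning-machine style —
   no weight updates during training). Softmax scores give per-pixel
   class probabilities.
3. **Fully-connected CRF refinement**: Potts energy
   `E(y) = Σᵢ ψᵤ(yᵢ) + Σ_{i≠j} [yᵢ≠yⱼ](w⁽¹⁾k⁽¹⁾ + w⁽²⁾k⁽²⁾)` with a
   bilateral appearance kernel and a spatial smoothness kernel, inferred
   by dense mean field (with an exact brute-force oracle for tiny
   instances and a truncated-neighborhood pass for full slices).
4. **An artificial-immune-system optimizer** (negative selection, clonal
   selection, directed mutation, memory dynamics, and an annealed
   global-best schedule with inertial weight 0.9 → 0.1 and exploration
   coefficient `C_best = 2(1 − J/MI)`) that tunes the decision layer: a
   bit mask over hidden units plus per-class score offsets, maximizing
   validation Dice of the whole-tumor region.

Everything is exercised on synthetic multi-contrast brain phantoms
(FLAIR/T1/T1ce/T2-like channels; edema bright on FLAIR/T2, enhancing
core prominent on T1ce) with the standard five-class taxonomy and the
nested evaluation regions ET ⊆ TC ⊆ WT. No external dataset is needed;
real data can enter through PNG or NIfTI slices.

## Who this is for

Researchers who want a desk-scale, fully reproducible reference
implementation of this denoise → random-projection-classify → CRF →
immune-tune pipeline, with exact oracles (exhaustive CRF MAP, exhaustive
mask search, grid minimization) wired into the test suite.

## Worked example

```python
from glioseg.pipeline import RunConfig, run_pipeline

results = run_pipeline(RunConfig())   # 40 simulated slices, seed 7
print(results.summary())
```

prints

```
Tumor segmentation pipeline
===========================
images: 40 at 128x128, noise gaussian:10, seed 7
stages: denoise=True crf=True tune=True
test images: 10
mean dice_WT: 0.9999 (sd 0.0003)
mean dice_TC: 0.9988 (sd 0.0007)
mean dice_ET: 0.9610 (sd 0.0097)
mean accuracy: 0.9983 (sd 0.0004)
mean auc: 1.0000 (sd 0.0000)
mean psnr_denoised: 35.0029 (sd 0.0665)
tuning val_dice_WT_untuned: 1.0000
tuning val_dice_WT_tuned: 1.0000
tuning val_dice_WT_search_best: 1.0000
```

Reading: 40 phantoms are generated, degraded with Gaussian noise
(σ = 10), denoised, and split 75/25; the network is fitted on the train
split and evaluated (after CRF refinement) on the 10 held-out slices.
Dice is the overlap of the predicted and true region masks (WT = whole
tumor, TC = tumor core, ET = enhancing tumor); accuracy is pixelwise
over all five classes; AUC scores the summed tumor-class probability
against the true tumor mask; PSNR is measured against the clean
phantom. The tuning rows show the validation whole-tumor Dice before
and after the immune search — the untuned configuration is seeded into
the search population, so tuning can never make it worse. Identical
config + seed reproduces this report byte for byte.

The same stages are available as a CLI:

```sh
glioseg simulate --seed 7 --size 128 --n-images 4 --out data/
glioseg denoise --in noisy.png --seed 0 --out restored.png
glioseg train --data data/ --seed 1 --out model.npz
glioseg segment --model model.npz --in stack.nii --out prob.nii
glioseg refine --probmap prob.nii --image guide.png --out refined.nii
glioseg run --n-images 40 --seed 7
```

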