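# Methods

This note records the models implemented in `glioseg`, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical decisions a maintainer would want to know.

## Synthetic phantoms (`glioseg.phantom`)

Each phantom is a 2-D slice with four 8-bit intensity channels
mimicking the contrast behaviour of FLAIR, T1, T1ce and T2 sequences,
plus a five-class label map (background, normal tissue, edema,
enhancing core, necrosis). The brain is an ellipse; the tumor is three
nested blobs sharing one smooth angular boundary profile, so the
compartments nest exactly and the evaluation regions satisfy
ET ⊆ TC ⊆ WT by construction. Class-mean intensities are fixed so that
edema exceeds normal tissue by ≥ 40 units on the FLAIR/T2-like channels
and the enhancing core is the brightest tissue on the T1ce-like
channel; a smooth Gaussian texture (σ = 5 after band-limiting) is added
before quantization to 8 bits. Default geometry: 128×128 slices, tumor
area fractions 0.14 / 0.055 / 0.02 of the brain for edema / core /
necrosis — large enough that every class is represented by hundreds of
pixels at the default size, small enough to leave a normal-tissue
majority. Degenerate requests (tumor too large for the brain, a class
with zero pixels) raise instead of silently returning.

Noise models: additive Gaussian (σ = `level`), Rician as the magnitude
of the signal plus a complex Gaussian — the standard MRI magnitude
model — and salt-and-pepper with `level` as the corruption fraction.
All are seeded and clipped to [0, 255].

What the phantoms do **not** emulate: anatomy (no tissue atlas, no
skull, no partial-volume effects), multi-slice 3-D context, bias
fields, and inter-patient variability beyond seeded geometry jitter.
Passing tests therefore demonstrate algorithmic correctness and
reproducibility at desk scale, not clinical-grade performance: the
class-conditional intensity distributions here are far better separated
than in real MRI, which is why the pipeline's Dice scores saturate near
1.0.

## Variational denoising (`glioseg.denoise`)

The objective per plane is

    Ω(I) = Σ_px √(1 + β² |∇I|²) + (λ/2) (I − I₀)²

with forward-difference gradients and replicate borders; the smooth
edge term behaves like total variation at large gradients but is
differentiable everywhere, so plain gradient descent applies. Defaults:
β = 1 (the edge term then weighs gradient magnitude directly), λ = 0.05
— chosen from the usual fidelity-vs-regularization balance λ ~ 1/σ for
noise σ ≈ 20 on the 8-bit scale — step 0.2 (safely inside the explicit
diffusion stability limit), at most 150 iterations or a relative
objective change below 1e-6. Steps that would increase the objective
are rejected and the step halved, so the recorded trace is
non-increasing and the output never scores worse than the input; this
guard, not a line search, is the divergence policy.

The local-search phase traverses the image in three scan orders (row,
column, anti-diagonal bands), soft-thresholds the 1-D high-pass
residual along each scan (9-tap running mean, threshold τ = 5 intensity
units) to get a detail mask, and proposes one seeded reconstruction
operator per scan: Gaussian blur with the kernel size drawn from
{3×3, 5×5}, mean filter with the same size draw, or a global intensity
scaling drawn from U[0.7, 1.3]. A proposal is accepted only when it
lowers Ω *and* a seeded uniform draw falls below the local-search rate
(default 0.1); the best accepted image is kept. With the rate at 0 the
output equals the plain descent result. On the default phantoms at
σ = 20 the descent contributes essentially all of the ≈ 9 dB PSNR gain;
the local search is a cheap, strictly non-harmful polish because of the
elitist acceptance rule.

`check_admissibility` reports the energy and mean of a filter stencil —
the discrete analogue of the finite-energy and zero-mean conditions an
oscillatory analysis kernel must satisfy; it is diagnostic only.

## Segmentation network (`glioseg.network`)

Channels are rate-coded by a deterministic integrate-and-fire rule:
`count = floor(intensity · T / (255 · threshold))` over `T = 16`
timesteps, capped at `T`. This keeps the spiking interpretation (a
membrane potential charged linearly, spiking each time the threshold is
crossed) while remaining exactly reproducible; counts are normalized to
[0, 1] before the convolutional stack.

The feature stack is fixed and seeded, not learned: conv 9×9 (8
filters, Gaussian init scaled by fan-in) → average pool 7×7 → conv 9×9
(8 filters) → max pool 5×5, all stride 1 with replicate padding so
every pixel keeps a feature vector. The window sizes follow the layer
geometry the pipeline is specified with; filter counts are desk-scale.
The rate-coded raw channels are appended to the final maps (12 features
per pixel in total) so plain channel contrast remains directly visible
to the readout — the mapping from stack output to classifier input is
an implementation choice and is recorded in `NetConfig`.

The classifier is an extreme-learning-machine-style solve: an immutable
random hidden layer `h = g(Wx + b)` (default 64 sigmoid units, W and b
drawn once per seed) and a one-shot minimum-norm least-squares readout
`β = H⁺Y` against one-hot targets, ridge-stabilized at 1e-8. Training
pixels are subsampled 4× per image to keep the design matrix small; the
75/25 train/test split is a seeded shuffle at the image level. The
softmax of the per-pixel output scores supplies the class probabilities
the CRF consumes. An optional sign-based resilient-propagation refiner
of the readout (`refine_output_weights`, capped at 7000 epochs or MSE
1e-5) exists for the iterative training mode; the closed-form solve is
the default and the tested path, since it is already the least-squares
optimum.

The normal-equation blocks `HᵀH` and `HᵀY` from the fit are cached on
the model so the decision layer can later be re-solved under a
hidden-unit mask without revisiting any training data.

## Dense CRF (`glioseg.crf`)

Energy of a labeling, summed over *ordered* pixel pairs:

    E(y) = Σᵢ ψᵤ(yᵢ) + Σ_{i≠j} [yᵢ ≠ yⱼ] (w⁽¹⁾ k⁽¹⁾(fᵢ,fⱼ) + w⁽²⁾ k⁽²⁾(fᵢ,fⱼ))

with unaries ψᵤ = −log P(yᵢ | I) clamped at 1e-10, the bilateral
appearance kernel `k⁽¹⁾ = exp(−|sᵢ−sⱼ|²/θα² − (eᵢ−eⱼ)²/θβ²)` and the
spatial smoothness kernel `k⁽²⁾ = exp(−|sᵢ−sⱼ|²/θγ²)`. The ordered-pair
convention is fixed deliberately and carried through inference: the
mean-field update derived from this energy doubles the symmetric
message (pixel i appears in both (i, j) and (j, i) terms), i.e.

    Qᵢ(l) ∝ exp{ −ψᵤ(i,l) − 2 Σ_j K_ij (1 − Qⱼ(l)) }.

Omitting the factor makes inference fight half the coupling the energy
scores and measurably degrades agreement with the exact MAP.

Inference is naive dense mean field — an O(N²) message pass, exact at
desk scale — run for 5 synchronous sweeps by default. The returned
distribution is the unit-temperature fixed point (with zero kernel
weights it is exactly the input probability map). MAP labels are read
out by continuing the same update for 8 sweeps while annealing the
temperature to 0.05: as T → 0 the update hardens into a
conditional-modes step, which resolves near-tied marginals toward a
local energy minimum instead of an arbitrary argmax tie-break. A
brute-force enumerator (N ≤ 12, C ≤ 3, lexicographic tie-break) serves
as the exact oracle in the tests.

The benchmark instance distribution for the oracle comparison
(`random_patch_instance`) emulates the CRF's actual job: a 3×3 patch of
classifier output whose true labels split along a random half-plane,
intensities clustered by class, confident unaries (true-class
probability 0.92–0.99) and exactly one weak noisy pixel (0.35–0.48),
with moderate coupling (w⁽¹⁾ = w⁽²⁾ = 0.3, θα = 2 px, θβ = 60, θγ = 1.5
px). Instances with i.i.d.-uniform unaries were deliberately not used:
they make near-tied pixels the typical case, where the argmax of an
approximate marginal is not a meaningful correctness signal.

For full slices a truncated-neighborhood variant restricts the pair sum
to a disc (default radius 4–5 px); the Gaussian kernels make farther
pairs negligible. Default image-scale parameters: w⁽¹⁾ = w⁽²⁾ = 1,
θα = 8 px, θβ = 16 intensity units, θγ = 3 px, 5 sweeps, with the
denoised FLAIR-like channel as the bilateral guide. CRFs here are 2-D
per slice only.

## Immune optimizer (`glioseg.immune`)

Detectors are bit-string antibodies carrying a concentration p, a
tolerance counter t, an age and a match count, partitioned into
immature / mature / memory sets. Affinity is the matching-bit fraction;
a match requires affinity strictly above γ. The cycle: negative
selection deletes immature detectors matching any self pattern and
matures survivors after α tolerance steps; mature and memory detectors
clone in proportion to `round(ξ(1 − rank/N))` with rank 0 the highest
affinity (the rank interpretation makes better detectors clone more);
clones mutate only on bits that disagree with the guiding antigen, each
with probability 0.1; mature detectors whose match count strictly
exceeds the activation threshold are promoted to memory with p reset to
η₁; re-matched memory detectors reinforce p ← η₁ + η₂p; concentrations
decay as p ← p(1 − 1/(θ − age)) and collapse to zero at the horizon.
Constants (η₁ = 1, η₂ = 0.5, θ = 20, α = 3, activation threshold 5,
γ = 0.7) are package defaults chosen to keep every mechanism active
within a 10-cycle run; the clone constant maps from the clone rate as
ξ = max(1, round(rate · population)).

Continuous variables use a global-best attraction with the linearly
annealed inertial weight w(J) = 0.9 − 0.8·J/MI and a random step scaled
by C_best(J) = 2(1 − J/MI) times the mean bound width; positions are
clipped to bounds. The published position-update recurrence is
degenerate as printed (the updated state appears on both sides), so the
standard gbest form above is used and documented as the interpretation.
The optimizer is elitist in both encodings: the best-so-far never
worsens and the per-cycle trace is non-increasing.

`tune_decision_layer` couples both encodings: a bit mask over hidden
units (readout re-solved from the cached normal equations) plus
per-class additive score offsets in [−1, 1], scored by mean validation
whole-tumor Dice. The identity candidate (all units on, zero offsets)
is seeded into the population, so the tuned model can never score below
the untuned one on the validation set. With default settings
(population 200, clone rate 0.04, 10 cycles) a tuning run costs a few
thousand objective evaluations, each a masked solve plus a validation
prediction.

## Pipeline and evaluation (`glioseg.pipeline`, `glioseg.metrics`)

Stages run in order (noise → denoise → fit → predict → CRF → tune) with
every stochastic stage fed from the run seed; identical configuration
and seed reproduce the aggregate report byte for byte. "Accuracy" is
pixelwise classification accuracy over all five classes — stated
explicitly because the term is often reported without a definition.
Dice of two empty masks is defined as 1.0 (the usual convention when a
sub-region is absent from a slice); AUC uses the Mann–Whitney rank
statistic with averaged ties and is undefined (reported as NaN) for
single-class truth. Aggregation over test images is the unweighted
mean; per-image records are kept so any other aggregation can be
recomputed.

Problem sizes used by the test suite and the acceptance script — 40
phantoms of 128×128 for the cohort run, 20 phantoms for the denoising
gain, 50 patch instances for the CRF oracle, 100 seeded runs for the
optimizer calibration — are the package's documented desk-scale study
conditions: large enough for stable medians and rates, small enough
that the whole suite runs in about a minute on one CPU.

## Known limitations

- Dice/accuracy saturate on the phantoms; relative comparisons between
  stages (e.g. CRF on/off) are meaningful, absolute values do not
  transfer to real MRI.
- The dense mean-field implementation is O(N²) and intended for
  analysis at patch scale; full slices go through the truncated
  neighborhood, which is an approximation (controlled by the radius).
- The feature stack is random and fixed; there is no representation
  learning, by design — the readout solve is the only fitted component.
- The immune optimizer is a stochastic heuristic; its guarantees here
  are elitism and the schedule shape, not convergence rates.
- 3-D volumes are handled slice-wise only.
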