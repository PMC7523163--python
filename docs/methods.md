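# Methods

## The audit in one paragraph

A classifier trained on a dataset whose positive and negative images come
from different sources can reach high held-out accuracy by recognizing the
*source* rather than the disease. The audit quantifies this three ways:
(i) the generalization gap between internal and external test AUROC,
(ii) attribution maps that show *where* in the image the model's evidence
lives, and (iii) causal perturbation tests that move or swap a suspected
shortcut feature and measure the change in the model's log-odds against a
Monte-Carlo null. Because real radiographic repositories are large and
their confounds only partially known, the pipeline runs on a synthetic
generator in which every confound is planted deliberately and every
ground-truth region mask is available.

## Synthetic generator

Each image is a schematic 2-D "radiograph" in [0, 1]: a soft-tissue
background (0.32), two elliptical lung fields (−0.18), a cardiac
silhouette (+0.10), a diaphragm shelf (+0.12), and a bright shoulder band
(+0.22) whose top edge sits at row ⌊0.14·S⌋ minus a source-specific
offset. Source-specific spurious features, all parameterized by
`SourceProfile`:

- **laterality marker** — a binary glyph (an "L" or "R" form) stamped at a
  canonical corner position with ±1 px jitter at intensity 0.95;
- **border band** — an additive frame of configurable width and intensity
  (a proxy for positioning/projection-driven border radiopacity);
- **shoulder offset** — vertical displacement of the shoulder band
  (positive = nearer the top edge, as in supine/portable acquisition);
- **annotation stamps** — an arrow glyph added with probability
  `annotation_rate`, emulating figure-scraped images.

Genuine pathology (`PathologySpec`) is rendered as Gaussian opacity blobs
(default 3 per lung, σ = 3.5 px at 64 px, amplitude 0.30) strictly masked
to the lung fields, bilaterally by default. Pixel noise is Gaussian
(σ = 0.04) and images are clipped to [0, 1].

**Confound coupling.** The dataset holds equal numbers of latently
positive and negative cases. A record lands in its label-determined source
(positives → B, negatives → A) with probability (1 + ρ)/2, so
`confound_correlation` ρ = 0 means source ⊥ label and ρ = 1 the worst case
in which source identity predicts the label perfectly.
`pathology_penetrance` < 1 renders the genuine signal in only a fraction of
latent positives; combined with the `radiographic_evidence` labeling rule
(label = signal actually rendered) versus `latent_status` (label = latent
state), this reproduces concept shift between figure-derived and
PCR-derived labels.

All randomness flows from one integer seed; each record renders from its
own `default_rng([seed, index])` substream, so datasets are bit-reproducible
and individual records can be regenerated in isolation.

**What the generator does not emulate:** rib/vascular texture, scanner
physics, DICOM windowing, anatomical variability, multi-image patients
(each record is its own patient by default). Passing tests therefore
demonstrate that the *audit machinery* behaves correctly on data with known
ground truth — not that any particular real-world dataset is or is not
confounded.

## Assembly

The view filter keeps PA and upright-AP records only. Labels map into the
14 ChestX-ray14 categories plus a 15th COVID node; unmapped vocabulary is
dropped and logged. Folds are assigned per patient: patients are shuffled
by seed and accumulated into test until the record quota (`test_frac · N`)
is met, then into validation (`val_frac` of the remainder), remainder
train. Fractions are interpreted over records with patients atomic, so
achieved fractions deviate from targets by at most the largest per-patient
record count. An optional `fixed_test_ids` set pins an upstream frozen test
partition; a patient straddling the boundary raises an integrity error.

## Classifiers and training

Three architectures (all numpy, manual backprop, finite-difference
verified):

| id | structure | role |
|----|-----------|------|
| `dense-cnn` | 4 conv blocks (16–64 ch) + dense head | higher-capacity model |
| `simple-cnn` | 3 conv blocks (8–32 ch) + dense head | small CNN |
| `logistic-embedding` | frozen random 3-block conv embedding (1024 features at 64 px) + trainable linear head | logistic regression on deep features |

All end in a fully connected head over the flattened final feature map.
This is deliberate: the planted confounds are position-coded (corner
glyphs, band rows), and a global-average-pool head erases position, making
the shortcut nearly unlearnable at this depth — whereas the full-scale
architectures this family stands in for retain positional pathways (dense
classifier stages, deep stacks with large receptive fields).

Optimization is mini-batch SGD exactly as configured by
`TrainHyperparams`: batch 16, momentum 0.9, weight decay 1e-4, lr 0.01
decayed 10× every 5 epochs, up to 30 epochs. The loss is binary cross
entropy per output node, averaged over the batch and **summed** over
nodes, so the COVID node's gradient scale does not depend on whether the
head is `multi15` or `single1`. Model selection keeps the epoch with the
highest validation AUROC on the COVID node, ties broken toward the later
epoch: on separable synthetic data the validation AUROC saturates at 1.0
almost immediately, and among tied epochs the later one is the more
converged model (empirically, its saliency is far more concentrated on the
features it actually uses). ImageNet pretraining is out of scope; random
initialization is the tested path, and no data augmentation is applied.

AUROC is computed as the normalized Mann–Whitney U statistic (average
ranks, ties ½); scikit-learn's implementation serves as an independent
cross-check in the tests only.

## Generalization auditing

`evaluate_generalization` scores one trained model on a held-out internal
test fold and an external manifest and reports both AUROCs and the gap.
The headline mechanism is asserted as a property: with worst-case
confounding and no genuine signal, external AUROC returns to chance, so at
least half of the above-chance performance is lost
((AUROC_ext − 0.5) ≤ ½(AUROC_int − 0.5)). "Above-chance" normalization is
used because AUROC has a floor of 0.5, making raw ratios misleading.

`confound_transfer_audit` probes the complementary trap — a confound that
generalizes does *not* produce a gap, so external validation alone cannot
certify a model. It relabels the data by an attribute (projection or the
sex analogue), trains fresh single-node classifiers (default 5 replicates,
seeds = base + index) and reports internal/external AUROC as mean ± sd.
The generator supports rendering the attribute cue identically in both
domains (transferable) or with disjoint styles (non-transferable).

## Expected Gradients

The estimator draws (x′, α) jointly — a uniformly chosen background
reference and an independent α ~ U(0,1) — and averages
(x − x′) ⊙ ∇f(x′ + α(x − x′)) over `n_samples` draws (default 200 per
image). Gradients are taken with respect to the **pre-sigmoid COVID-node
output**, so attributions are additive in the same log-odds space used by
the behavioral tests. Completeness (Σφ = f(x) − E_D f(x′)) holds in
expectation; every map records its realized gap as a convergence
diagnostic, and the tests verify the ~1/√n shrinkage on a smooth model.
Integrated Gradients uses a midpoint α grid with a single reference;
passing the same grid to the EG estimator with a singleton background
reproduces IG exactly, which the tests assert. Percentile display maps are
the average-rank transform of |φ| (or signed φ) scaled to [0, 100]; an
all-equal map displays flat at ≈50. Background sensitivity is summarized
as the Spearman correlation between maps computed under two backgrounds.

## CycleGAN

Generators are residual: G(x) = x + δ(x) with δ bounded in (−1, 1) by a
tanh output layer initialized near zero, so training starts from the
identity map. Discriminators are shallow conv stacks whose patch-logit map
is pooled by a dense positional head. Both networks receive two appended
coordinate channels; without absolute position information a shallow
translation-equivariant net cannot add or remove a glyph at a fixed corner
(the original architectures are not printed and come from an external
codebase, so the desk-scale architecture is this package's own).

The reported losses are exactly the printed forms: non-saturating log
adversarial terms and the cycle term as the per-image L1 **norm** (sum
over pixels) averaged over the batch, with the total their plain unit-weight
sum — no identity loss. The generator's parameter update uses the
standard non-saturating realization (minimize −log D(G(x))); a
least-squares variant is available via `loss_type="lsgan"`. Training
alternates one discriminator and one generator update per batch with Adam
(β₁ = 0.5); desk-scale defaults are 32 px images, batch 8, lr 1e-3, 50–60
epochs. Discriminator outputs are clamped to (1e-7, 1−1e-7) before logs,
with a warning. A constant-generator-delta detector logs a mode-collapse
warning.

Counterfactual evaluation uses the batch-averaged signed difference map
G(x) − x, a mass-in-mask localization score against the generator's
ground-truth marker regions, and the classifier flip rate — the fraction
of transformed images the audited classifier assigns to the target class
(log-odds crossing 0), reported with the mean signed Δ log-odds. An
oracle marker transform (erase one source's glyph region, stamp the
other's) provides a GAN-independent upper reference for the flip rate.

## Behavioral tests

`run_swap_test` exchanges the positive-source marker region *at the same
coordinates* in a positive and a negative image (the negative image
contributes background content), the desk-scale analog of swapping
laterality markers; the positive image is tested for a log-odds decrease
and the negative for an increase. `run_reposition_test` copies the
shoulder-band region to the top corners, duplication rather than
cut-paste. Null distributions come from n (default 1000) random
modifications of identical geometry: uniformly placed patch pairs (which
may overlap the true marker — an unbiased null) or random source patches
copied to the same targets. p = (r + 1)/(n + 1) with r counting null
effects strictly beyond the observed one in the stated direction; ties are
not counted, so p ∈ [1/(n+1), 1] and is monotone in the observed effect.

One calibration subtlety: if the audited model is completely insensitive
to the *target* region of a reposition test, observed and null effects are
all exactly zero and the strict count collapses p to its floor — a
degenerate, not a significant, outcome (asserted in the tests). The
meaningful calibration is targeting a random, non-confound region, which
lands p in the body of the null distribution.

## Average images

Per-source pixel-wise means (bilinear resize to a common size first)
expose the planted confound phenomenology: the glyph appears at its
canonical corner and border-band contrast survives averaging, while
noise cancels as 1/√n. Linearity over concatenated manifests is exact and
tested.

## Problem sizes and numerical choices

Test and acceptance runs use 64 px images with 400 images per source for
classifier experiments (10 training epochs; the validation trace is
saturated well before that) and 32 px with 64 images per domain and 60
epochs for the CycleGAN. Attribution uses 200 (x′, α) samples per map and
averages mass fractions over 8 positives; behavioral tests use the full
n = 1000 null. These sizes were chosen as the smallest at which every
planted mechanism is comfortably detectable; all of them are package
choices, configurable by the caller.

Degenerate inputs are handled explicitly: one-class label vectors raise an
undefined-metric error, a one-class validation fold a model-selection
error, constant attribution maps a warned NaN correlation, empty domains
and zero-sized nulls parameter errors, and out-of-bounds glyph jitter is
clamped to the border (keeping dataset size exact) and logged.

## Known limitations

- The schematic anatomy makes several distinct real-world confounds
  (projection, positioning, processing) collapse onto a small set of
  planted features; interactions among confounds are not modeled.
- The ρ = 0.5 regime couples source and label only weakly per record;
  quantitative gap sizes at intermediate ρ should not be read as
  predictions for any real dataset.
- The desk-scale CycleGAN demonstrates localization of a planted
  difference, not photorealistic translation; its transformed images do
  not reliably flip an independently trained classifier the way the
  oracle transform does.
- Empirical p-values inherit the discreteness of (r + 1)/(n + 1); at
  n = 1000 the smallest reportable value is 1/1001 ≈ 9.99 × 10⁻⁴.
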