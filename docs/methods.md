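# Methods

This note documents the models and procedures implemented in `spectrafuse`,
the parameter choices that matter, what the synthetic cohort does and does
not emulate, and the numerical decisions a maintainer should know about.

## Data model

A *sample* is one serum draw with a paired FTIR absorbance spectrum and a
36-indicator biochemical panel; a *subject* may contribute several samples.
Spectra live on a uniform wavenumber grid, by default 400–4000 cm⁻¹ at
2 cm⁻¹ (1801 points).  Each sample's spectrum is the mean of at least five
instrument replicates; averaging is idempotent and replicate indices are
dropped on output.  Grid harmonization uses linear interpolation and
refuses to extrapolate — absorbance outside the measured range is unknown,
not zero.

Splits are performed over subjects, never samples, so that no individual
appears in more than one of train/validation/test.  The split is
class-stratified: the 7 : 0.5 : 2.5 ratio is applied independently within
the positive (AML) and negative (other-disease + healthy) subject pools, so
the small validation and test sets always contain both classes.  Integer
counts use largest-remainder apportionment within each pool, with
fractional ties resolved in train → val → test order.  This rule keeps the
validation partition non-degenerate for the cohort sizes used here (e.g. a
94-subject cohort with a 36/58 class split partitions as 66/5/23 subjects);
at least roughly ten subjects per class are needed before every partition is
guaranteed non-empty.

## Synthetic cohort

No clinical data ship with the package, so a generator provides a
statistically controlled stand-in with the same shape as the screening
study: 36 AML, 24 other-disease (hyperuricemia, gout, rheumatoid
arthritis) and 24 healthy subjects; 1–3 samples per subject (a declared
free parameter — per-subject sample counts are not fixed by the study
design); 5 replicates per sample.

**Spectra** are sums of Gaussian vibrational bands on the grid — amide I
(~1650 cm⁻¹), amide II (~1540), amide A (~3290), CH stretches (2870–2960),
carbohydrate C–O (~1050) and minor bands — plus a random quadratic baseline
(coefficients ~ N(0, 0.02) absorbance units per sample) and white replicate
noise (sd 0.01 absorbance).  Positive-class subjects multiply band
amplitudes by per-band factors between 0.92 (amide II) and 1.18
(carbohydrate); subject-level amplitude factors ~ N(1, 0.05) make samples
from one subject correlated.  A broad ~3350 cm⁻¹ O–H band can optionally be
injected to mimic non-lyophilized (wet) serum; it defaults to off because
the reference measurement protocol freeze-dries serum precisely to remove
it.  Absorbance is *not* clipped at zero: noise and baseline excursions may
go slightly negative, as baseline-subtracted instrument output can.

**Panels** model 36 indicators with plausible adult reference means and
dispersions.  The class structure follows the screening setting's
description: albumin (−2.0 sd), total protein (−1.6 sd) and LDH (+2.5 sd)
separate strongly; all other indicators shift by at most 0.5 sd, with
potassium and uric acid nearly null (≤ 0.2 sd).  The other-disease subgroup
carries its own small shifts (urate +1.5 sd, CRP +0.8 sd), making the
negative class heterogeneous and the unimodal-vs-fused comparison
non-trivial.  Right-skewed analytes (enzymes, bilirubin, CRP) use a
lognormal parameterized to match the requested mean and sd.

What passing tests on this cohort do **not** show: real serum spectra have
correlated, non-Gaussian band structure, scatter and atmospheric artifacts;
real panels have measurement-batch effects and missing values; the clinical
separability of the real cohort is unknown here.  Results on the synthetic
cohort validate the machinery and the *relative* behavior of the modality
arms, not clinical performance.

## Encoder

Per attention head and per modality, three affine maps produce Q, K and V
(widths d₁ = 32 for FTIR, d₂ = 8 for chemistry), each batch-normalized.
There is deliberately no LayerNorm on the inputs: the modalities keep their
own physical scales and normalization happens after the affine maps.
Attention treats each of the d₁+d₂ = 40 concatenated coordinates as a token
of dimension 1, so the softmax weight matrix is 40×40 per sample, its
diagonal blocks intra-modal and off-diagonal blocks inter-modal.  With
scalar tokens, the conventional scaling gives d_k = 1; it is exposed in the
config.  Head outputs are averaged — this preserves the 40-wide latent
contract without an extra projection — and a final per-feature batch
normalization produces the latent vector.  Head count (default 4), the
averaging rule and the choice of batch normalization as the final
normalizer are reconstructions where the design was genuinely open; all are
configurable, and one head reproduces the single-head architecture exactly.

Batch-norm uses the biased (1/m) batch variance, matching the defining
equations, with ε = 1e-5 and an EMA momentum of 0.1 for running statistics.
In eval mode only running statistics are used, so a sample's encoding is
independent of its batch companions — verified element-wise in tests.
Weights initialize as uniform fan-in (±1/√d_in), seeded; the seed is part of
the config so repeated-initialization protocols are reproducible.

Chemistry inputs are z-scored per indicator using training-partition
statistics (clinical units are heterogeneous); spectra enter as measured
after replicate averaging.  Unimodal encoders are their own parameter sets
(`ftir_only` / `chem_only`): attention runs over that modality's
coordinates only, and the final normalizer has the matching width (32 or
8), so fused parameters cannot be silently reused for unimodal encoding.

The forward and backward passes are hand-written numpy.  Gradients through
the affine/batch-norm/softmax-attention/loss chain are validated against
central finite differences at 1e-4 relative tolerance on a toy
configuration; gradients that are mathematically zero (e.g. a bias ahead of
batch normalization, which centering removes) are excluded from the
relative comparison.

## Contrastive objective and optimization

Within each mini-batch, all unordered pairs contribute: same-class pairs
their squared latent distance D², different-class pairs a margin hinge with
ε = 0.5.  The default hinge is max(0, ε − D)² — the canonical
margin-contrastive form; a literal variant max(0, ε − D²) is one flag away
(`loss_variant="hinge_on_squared_distance"`).  Pairs are aggregated by
mean, not sum, so the loss scale does not grow with batch size and a
batch-size sweep compares like with like.  At coincident different-class
points the distance gradient direction is undefined; the subgradient 0 is
used (guard at D < 1e-12).  Only within-batch pairs feed the loss; the
distance matrix is defined per batch.

Optimization is Adam (β₁ = 0.9, β₂ = 0.999, eps = 1e-8) at lr 1e-3 with
step decay ×0.5 every 60 epochs, 240 epochs by default and no early
stopping.  The default batch size is 100 — the value a batch-size sweep
selects — with 300 retained as an alternative preset.  A trailing batch is
kept when it has ≥ 2 samples (one sample has no pairs and no batch
statistics) and dropped otherwise.  The validation partition is encoded in
eval mode each epoch for monitoring only; it never contributes gradients.

## Classification and metrics

LDA is fitted on training latents with the within-class scatter shrunk
toward a scaled identity; the default shrinkage is the analytic Ledoit-Wolf
rule, which is deterministic and keeps the fit well-posed when the latent
dimension (40) is not far below the training count.  Priors default to
equal, putting the threshold midway between class means; decision ties go
to the negative class.  Metrics are accuracy, sensitivity and specificity
from the test-partition confusion counts, computed per sample (per-subject
aggregation is deliberately not the default; the spread across subjects is
captured by the repeated-split protocol instead).  A metric with an empty
denominator is reported as `None`, never as 0.

## Evaluation protocol

The ablation runs `n_splits` (default 10) subject-level splits ×
`n_inits` (default 5) initializations = 50 trials per modality arm, with
all arms sharing the identical split/seed sequence so comparisons are
paired.  Unimodal arms route through the same encoder machinery by default
(the symmetric choice); `unimodal_path="raw"` feeds raw features straight
to LDA as an alternative baseline.  The AML-vs-healthy-only control is a
cohort filter, not a separate pipeline.  The batch-size sweep runs the same
protocol at each size in increments of 50 up to the training-set size,
reporting the accuracy argmax with ties to the smaller size.

All randomness derives from explicit integer seeds; sub-seeds are spawned
through a seed sequence and kept below 2³¹.  Repeated runs with the same
seeds are byte-identical at the metric-JSON level.

## Problem sizes used in automated checks

The test suite and `scripts/acceptance.py` use the full 36/24/24-subject
cohort on the 1801-point grid, with pre-training shortened to 60 epochs
(the schedule's first decay step) and the ablation scaled to 5 splits × 2
initializations; unit tests additionally use a narrowed 900–1800 cm⁻¹ grid
with a 12/8/8-subject cohort.  These sizes were chosen so the whole
verification cycle completes in minutes on a single CPU while preserving
every qualitative effect checked (separation recovery, fusion benefit,
variance reduction).

## Known limitations

- The network backend is plain numpy; it is fast at these problem sizes but
  not GPU-capable.
- The synthetic generator is a statistical stand-in, not a physical model
  (no Beer–Lambert mixing, no ATR penetration-depth effects).
- Only binary screening (AML vs. pooled negatives) is implemented;
  multi-class subtyping is out of scope.
- Clinical headline figures cannot be reproduced without the original
  (non-deposited) cohort; all quantitative claims here are about the
  synthetic study conditions.
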