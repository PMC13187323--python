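# Methods

This note documents the models implemented in `bccxai`, the design of the
synthetic data that exercises them, the numerical choices, and what the
passing tests do and do not establish.

## Label codification and clinical decision rule

A lesion label is an ordered binary 7-vector over the dermoscopic patterns
`(PN, U, ON, MG, ML, SW, AT)`.  The pigment network (PN) is a negative
criterion; the other six are BCC-positive.  `encode_diagnosis` returns
BCC (1) iff at least one BCC-positive flag is set; the all-zero vector and
the PN-only vector are non-BCC.  When PN co-occurs with a BCC-positive
pattern the default rule still returns 1 (one positive pattern suffices
clinically); a `pn_veto=True` variant is provided because the co-occurrence
case is not covered by the canonical worked examples.  The rule is verified
exhaustively over all 128 vectors against its OR formulation.

## Multi-rater consensus (Standard Reference)

Pattern presence is subjectively assessed, with known low inter-rater
agreement, so a Standard Reference (SR) is inferred from several raters
with a per-pattern two-class Dawid–Skene model: latent truth
T ∈ {0,1} with prevalence π; rater r votes conditionally independently with
sensitivity α_r = P(v=1|T=1) and specificity β_r = P(v=0|T=0).  EM
alternates a Bayes-rule E-step with closed-form M-step re-estimates.
Choices:

* **Per-pattern independence.**  Each of the 7 patterns is fitted
  separately; cross-pattern correlation in rater errors is out of scope.
* **Initialization.**  Majority vote (ties → positive) by default.  The
  *uniform* initialization is implemented as 0.5 plus a 10⁻³ pull toward
  each image's mean vote: a perfectly flat posterior is an exact fixed
  point of EM (it forces α_r = 1 − β_r, so the E-step carries no evidence).
* **Convergence.**  Absolute log-likelihood improvement < 1e-6 (default),
  max 500 iterations; the observed-data log-likelihood trace is
  non-decreasing to 1e-9 (tested property).
* **Degeneracy.**  M-step estimates are clipped to [1e-6, 1−1e-6]; missing
  votes (NaN) are skipped in both steps (ignorable missingness); a pattern
  with no votes at all is flagged unestimable (NaN posteriors).
* **Hard labels.**  SR = 1 iff posterior ≥ 0.5.

A caveat the tests quantify: with four *good, homogeneous* raters
(α = 0.85, β = 0.90) the tie-positive majority vote is already close to the
Bayes rule, and at n = 500 the EM's finite-sample parameter noise makes its
per-pattern advantage small (+0.001 to +0.01 accuracy).  EM reliably beats
majority voting on *overall* accuracy, but simultaneous dominance on all
seven patterns on a single draw is a coin-flip event — it fails even for
the Bayes rule evaluated with the true parameters on typical draws.  The
corresponding strict per-pattern assertion in the acceptance suite
documents this with the measured margins.

## Clinically-inspired metrics

Beyond per-pattern recall/specificity/precision/accuracy (with unweighted
fold means and across-fold variance when folds are supplied), the toolkit
reports: `no_pattern_accuracy` (all-zero reference images predicted
all-zero), the PN column's confusion metrics, and the
`bcc_pattern_hit_rate` — among images whose reference carries ≥1
BCC-positive pattern, the fraction whose predicted positive set intersects
the reference set.  Empty subgroups yield NaN with an explicit count,
never a silent zero.  Folds in which a pattern has no positives are
excluded from that metric's average and counted.

## Saliency-map agreement

For a normalized activation map z(x,y) ∈ [0,1] and a binary expert mask
(foreground Fg = union of the per-pattern masks, background Bg):

* **Conditional PDFs** — equal-width histograms on [0,1], 50 bins by
  default; each density integrates to 1 within 1e-9.  The intersection
  area is Σ_b min(f_b, g_b)·w_b ∈ [0,1].  "Mean over Fg" always means the
  mean of z over foreground pixels, not a mean of density values.
* **Energy-domain test** — a Welch-style two-sample z-test comparing the
  mean of z² over Fg vs Bg (two-sided by default, `fg_greater` available).
  Degenerate images (both regions constant) return p = 1 when the means
  are equal and p = 0 otherwise, with a warning.  Pixels are treated as
  independent; spatial autocorrelation inflates the effective sample size,
  so per-image p-values are anti-conservative on smooth maps — this is
  documented, not corrected.
* **Effect size** — Cohen's d on z² with the pooled standard deviation;
  undefined (NaN) when the pooled variance is zero.
* **Multiplicity** — Bonferroni and Benjamini–Hochberg are applied across
  the images of a cohort (m = number of analyzable images), via
  statsmodels.  Bonferroni rejections ⊆ BH rejections ⊆ uncorrected
  rejections, a tested invariant.
* **Exclusions** — images with an empty Fg or Bg (e.g. pattern-free
  lesions) are excluded from the cohort report with a recorded reason.
* Dice/Jaccard overlap coefficients are provided only as optional
  diagnostics: saliency maps are systematically coarser than expert
  contours, so they under-represent agreement.

Null calibration is verified by simulation (1000 null maps, two-sided
rejection rate within 3 Monte-Carlo standard errors of α = 0.05); power
and effect direction by a separated-law simulation (fg mean 0.6 vs bg 0.1,
sd 0.1 → all images BH-significant, mean d ≫ 1.5).

## Multi-task model and three-stage training

The classifier is a deliberately small, CPU-trainable stand-in for the
lightweight mobile architectures used in dermoscopic triage, written in
plain numpy with exact hand-derived backward passes (verified against
finite differences):

* backbone: three 3×3 stride-2 conv+ReLU blocks (16/32/96 channels);
* pooling: global average pooling (avg+max and flatten variants exist);
* a frozen-statistics per-feature standardization between pooling and the
  classifier — the inference-mode counterpart of batch normalization,
  with statistics refreshed at stage boundaries;
* classifier: a shared dense trunk (96 units, ReLU, optional dropout) and
  two parallel output layers — 1-logit binary head, 7-logit pattern head.

Two initialization details matter and are deliberate.  First, conv biases
are set to −(Σ weights)·u with u ~ U(0,1) per channel, so each channel's
response to a flat patch of intensity u bends at a uniformly distributed
point of [0,1]; with zero biases the whole rectified stack is positively
homogeneous in intensity and cannot form intensity-band-selective
channels, which the pattern task needs.  Second, the pooled-feature
standardization keeps the trunk's optimization well-conditioned across
stages.

**Loss.**  Focal loss −w(1−p_t)^γ log p_t with γ = 2 and α-balanced
per-class weights (positive and negative terms weighted by inverse
frequency, clipped to [0.05, 0.95]); γ = 0 with unit weights reduces
exactly to binary cross-entropy (tested to 1e-9).  Optimizer: AdamW with
decoupled weight decay; a fresh optimizer state per stage restricted to
that stage's trainable scope makes freezing bit-exact.

**Stages** (defaults, fixed by pilot runs on the synthetic generator;
learning rates are non-increasing by construction):

| stage | task | trainable scope | epochs | lr | weight decay |
|---|---|---|---|---|---|
| classifier | binary | trunk + binary head | 40 | 2e-3 | 0 |
| finetune | binary | blocks 2–3 + trunk + binary head | 150 | 5e-4 | 0 |
| pattern | pattern | pattern head only | 2000 | 3e-4 | 1e-3 |

Stage 2 deliberately spares the first block: in full-scale transfer
learning only the deepest blocks of a many-block backbone are fine-tuned,
and the early generic filters are preserved; in the toy model block 1
carries the band-selective filters, and fine-tuning it on the binary task
was observed to destroy them.  Stage 3 keeps the backbone *and* trunk
frozen, so the binary head is bit-identical before and after; because the
backbone is frozen and stage-3 augmentation is off, its features are
computed once and cached, which is why 2000 epochs are cheap.  The absolute
rates and epoch counts have no counterpart in a pretrained full-scale
setting and were chosen so the randomly initialized toy converges.

**Two diagnosis routes.**  After training, the binary diagnosis can be read
from the binary head or derived by the clinical decision rule from the
predicted pattern flags (threshold 0.5).  Both are always reported and may
disagree; the pattern-derived route is the system's clinical decision
logic (no pattern → no BCC; PN negative; any BCC pattern → BCC).  On the
synthetic construction the pattern-derived route is consistently the
stronger and more stable of the two.

**Folds.**  Iterative multilabel stratification (rarest-label-first greedy
assignment with demand/capacity tie-breaks, seeded): folds partition the
images and track global label proportions (within 0.05 on the tested
700-image 7-label sets).  The canonical stratification labels are the 7
pattern flags plus the derived binary diagnosis.

**Augmentation.**  Seeded rotation (±30°), random perspective (corner
jitter 6%) and Gaussian blur (σ ∈ [0.2, 1]); identity when all toggles are
off.  The default schedule disables augmentation: bilinear interpolation
creates intermediate intensities that smear the generator's disjoint
intensity bands (see below), and blur does so by design.  For other data
the per-stage `augment` flag and the global toggles re-enable it;
frozen-backbone stages then cache features of a few augmented copies
instead of re-augmenting per epoch.

**Class activation maps.**  Grad-CAM reads the last conv block: channel
weights are the spatially averaged gradients of the chosen head logit
(computed by the model's own backward pass in inference mode), the map is
the rectified weighted sum, bilinearly upsampled and min-max normalized;
constant maps are returned as all-zeros with a warning and excluded from
cohort analysis.  With a GAP backbone the gradients are spatially uniform
and Grad-CAM coincides with CAM; the implementation does not rely on this.

## Synthetic data: what it emulates, what it does not

The generator emulates the *structure* a dual-explanation pipeline needs,
not photorealistic dermoscopy:

* 7-pattern multilabel with configurable prevalence (default
  0.35/0.30/0.25/0.15/0.15/0.12/0.30, mimicking a screening cohort with
  under-represented MG/ML/SW);
* per-pattern spatial masks;
* raters with per-pattern sensitivity/specificity;
* activation maps with separately controllable foreground/background laws
  (clipped-normal draws; the clipped-normal mean has a closed form used by
  the tests; optional Gaussian smoothing).

Each pattern is a stylized procedural texture (reticular grid for PN,
dark patch for U, bright blobs for ON, scattered globules for MG,
lobulated arcs for ML, radial spokes for SW, branching polylines for AT)
painted in its own intensity band: the eight bands (7 patterns +
background at 0.42) are evenly spaced on [0,1] with gaps ≈ 0.13, an order
of magnitude above the pixel noise (sd 0.015).  Present patterns are dealt
to distinct angular sectors around the image centre, and rendering is
first-come-wins: a pattern's mask is exactly the set of pixels where it is
visible, which is what an expert segmenting that pattern would outline.
Background is flat skin tone with smooth low-amplitude noise.  Everything
is bit-reproducible from one integer seed through documented
`SeedSequence` spawn keys per component.

This construction is *separable by design* — pattern identity is decidable
from intensity-band occupancy — which is what makes a desk-scale model
trainable to high accuracy.  Consequences for interpretation: passing the
end-to-end training check shows the three-stage protocol, losses, freezing
and evaluation plumbing work and can exploit a clean signal; it says
nothing about accuracy on real dermoscopy, where patterns share intensity
ranges and differ by morphology.  Likewise the rater model draws
independent errors, so consensus results do not speak to correlated rater
biases.

## Pipeline

`run_pipeline` chains simulate → consensus → train → evaluate → xai at a
default scale of 300 images (64×64), 4 raters (α = 0.85, β = 0.90), 5
folds with fold 0 held out, and validates Grad-CAM maps of the trained
model against the integrated (union) masks of the held-out images,
splitting cohort summaries by binary-head correctness.  The manifest
records seed, config snapshot and hash, per-step timings and artifact
paths; a rerun with matching hash resumes from existing artifacts, and
deterministic artifacts are byte-identical.  The full default run takes a
few minutes on one CPU.  Training inside the pipeline uses the EM SR
labels (the realistic setting); the acceptance check of the trainer itself
uses the generator's ground-truth labels, since it tests the trainer on
the separable construction rather than the consensus step.

## Known limitations

* The energy-domain test ignores spatial autocorrelation (documented
  anti-conservativeness on smooth maps).
* The per-pattern EM is blind to cross-pattern structure.
* The binary head degrades if the shared trunk is retrained for patterns
  (the default schedule therefore freezes the trunk in stage 3); the
  pattern-derived diagnosis route is unaffected.
* Histogram PDFs make the intersection exactly computable but are
  bin-width dependent; 50 bins is a compromise documented in the API.
* The synthetic construction's separability caps what the tests can say
  about real images (see above).
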