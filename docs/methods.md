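# Methods

`woundtriage` models remote postoperative wound monitoring: patients
submit structured symptom reports (PROMs) and wound photographs during
postoperative days 1–30, a clinician (or a model) triages each response,
and responses judged low risk of surgical-site infection (SSI) are not
seen in person. The package implements the full analysis chain — a
synthetic cohort generator, unimodal and multimodal risk models, and the
simulation that converts model probabilities into triage decisions,
diagnostic accuracy, failure rates, staff-hours and full-time-equivalent
(FTE) workload.

## Synthetic cohort generator

Real patient-generated wound data are access-restricted, so the
generator reproduces the *statistical structure* of such a cohort and is
the substrate for every test. Its defaults encode the published cohort's
structure:

| parameter | default | meaning |
|---|---|---|
| `nonusage_rate` | 0.25 | enrolled patients who never submit a response |
| `mean_responses_per_patient` | 5.0 | responses per active patient (1 + Poisson) |
| `p_ssi48` | 0.037 | per-response probability of confirmed SSI within 48 h |
| `p_no_symptoms` | 0.719 | overall symptom-free response fraction |
| `p_isolated_symptom` | 0.168 | overall single-symptom response fraction |
| `triage_calibration` | (0.014, 0.240) | P(SSI48) given low / high clinician triage |
| `images_per_response` | (0.30, 0.40, 0.20, 0.10) | distribution over 0–3 attached images |
| `skin_tone_range` | (0.05, 0.95) | uniform base-colour parameter per patient |

**Symptoms.** Eight binary items (pain, erythema, oedema, warmth,
discharge/pus, fever, wound opening, general unwellness), each optionally
carrying a trend answer (new / worse / same / better) when present. SSI
responses draw each item independently with probability
`expit(logit(baseline) + effect)`; the per-item log-odds shifts default to
the clinical picture (discharge and erythema strongest). Non-SSI
responses draw from a three-component mixture (symptom-free / one
isolated symptom / two or more), with weights solved in closed form so
the *overall* symptom-free and isolated fractions hit their targets in
expectation after accounting for the SSI responses' contribution.

**Triage labels.** A latent severity score
`s = w·SSI + c·(effect-weighted symptom burden) + N(0, 1)` is cut at two
thresholds. The thresholds are calibrated numerically: a fixed-seed
reference sample of severity *means* is drawn from the same law, the
noise term is integrated analytically (normal CDF), and `brentq` solves
`P(SSI | s ≤ t_low) = 0.014` and `P(SSI | s > t_high) = 0.240`. The
latent weights (w = 0.8, c = 0.30) were chosen once so that the emergent
suspected-SSI (moderate + high) fraction sits near the observed ~15% of
responses; the moderate band's conditional rate (~6–9%) then follows
from consistency with the overall 3.7% event rate rather than being set
directly.

**Images.** Each image is rendered procedurally from three ground-truth
parameters: a dark curvilinear (quadratic Bezier) incision on a uniform
skin-tone background, an erythema halo (red shift with Gaussian falloff,
scaled by `erythema_intensity`), and yellow purulent spots. Erythema
intensity is drawn Beta(7, 2.5) for SSI responses versus Beta(1.6, 7)
otherwise; pus counts Poisson(1.5) versus Poisson(0.08). The renderer
also returns the incision + periwound mask (1–40% of pixels) used to
score heatmap localisation. Pixels are rendered lazily from a stored
per-image seed, so large cohorts without image modelling are cheap and
output remains byte-reproducible.

**What the generator does not emulate:** real wound appearance (sutures,
dressings, lighting, camera pose), informative missingness of images,
repeat-response correlation within patient beyond shared skin tone, and
operative covariates. Passing tests therefore demonstrate that the
pipeline's machinery is correct and well-calibrated on data with this
structure — not that the models would reach the same discrimination on
real photographs.

## Risk models

**PROM encoding.** Missing symptom answers are imputed as *absent*
before encoding (the clinical-practice assumption). Items are collapsed
to presence/absence by default — one column per item, keeping the
canonical 8-wide input; the per-trend-level expansion is available via
`PromEncoder(collapse_trends=False)`. Columns are centred and scaled
with statistics learned on the training split only.

**Tabular models.** The default classifier is a sequential MLP
(8 → 16 → 8 → 1, ReLU, sigmoid output) trained with Adam (lr 0.01,
batches of 32, ≤200 epochs) with inverse-prevalence class weights and
plateau early stopping (patience 10 epoch-level evaluations). The
comparator is an unweighted maximum-likelihood logistic regression on
the same inputs, so its coefficients estimate the usual odds ratios;
tests verify it against a hand-written IRLS oracle to 1e-6.

**Image model.** A four-block CNN (3×3 convolutions with edge padding,
ReLU, 2×2 max pooling; channels 12-24-32-32), global average pooling and
a sigmoid output, trained from scratch with RMSprop in batches of 10 for
up to 30 epochs. Early stopping monitors the training binary
cross-entropy every ten optimisation steps with a patience of ten;
because batch-level losses at batch size 10 are far too noisy to compare,
the loss is evaluated on a fixed subset (≤128 samples) of the training
data, giving stable comparisons, and the best-seen weights are restored.
Training-time augmentation uses similarity transforms only —
translation, rotation, isotropic scaling, flips — never shear or elastic
warps, preserving wound shape; evaluation is always augmentation-free. A
saved checkpoint of the same architecture can be fine-tuned with the
blocks below a configurable pooling stage frozen (the transfer-learning
configuration); no weights ship with the package. The whole network
stack (layers, optimisers, backprop) is implemented in numpy inside the
package (`woundtriage._engine`) with gradients verified against finite
differences.

**Class-activation heatmaps.** Gradient-weighted CAM from the
post-activation feature map of the last convolutional block: channels
are weighted by their average gradient of the risk logit, summed,
mean-subtracted, rectified, bilinearly upsampled and max-normalised. Two
numerical choices matter for a *binary* sigmoid head: (1) the
contribution map carries an image-wide constant component that shifts
the logit uniformly and carries no spatial information — without
removing it the ReLU step frequently clips the whole map to zero; (2)
convolutions use edge (replicate) padding because zero padding creates
an artificial high-contrast frame whose activations dominate the map.
On synthetic cohorts, trained-model CAM mass inside the dilated wound
mask is roughly 0.5 versus 0.3 for an untrained network of the same
architecture.

**Late fusion.** Each response's PROM probability is fused with each of
its image probabilities; with several images the highest fused risk is
kept, and with no image the PROM probability passes through unchanged
(provenance `proms_only`). The default head is a two-input logistic
stacker on the unimodal probabilities with slope coefficients
constrained non-negative (L-BFGS-B with bounds), which makes the fused
risk monotone in each modality by construction and pins a no-signal
modality's weight at zero; a parameter-free averaging head and a small
trained network head are alternatives. The max rule is applied to fused
per-image scores (not raw image scores); both orderings give identical
results for monotone heads.

## Evaluation

Responses are split 4:1 by patient (repeat responses never straddle the
boundary), stratified on the patient-level outcome (any SSI response)
with greedy allocation of shuffled patients until each stratum's test
share of responses reaches 20%. AUC is the rank-statistic concordance
with ties counted half; its 95% CI uses the DeLong asymptotic variance,
with a seeded bootstrap fallback when a class has fewer than two
members. Discrimination bands are lower-inclusive: [0.5, 0.6) poor,
[0.6, 0.7) moderate, [0.7, 0.8) good, ≥0.8 excellent.

## Pathway simulation

Three strategies route responses to "low risk" versus "in-person
review", scored against confirmed SSI within 48 h:

* **full clinical** — every response clinician-reviewed; the decision is
  the recorded triage label (moderate/high → review);
* **hybrid** — responses with fused risk ≤ threshold are ruled out
  automatically and never seen by a clinician; the remainder are
  clinician-reviewed and decided by the recorded triage label;
* **full automation** — decision purely by threshold; no clinician time.

"Low risk" means predicted probability *at or below* the threshold.
Failure rate is the share of low-risk-classified responses with
confirmed SSI, identically 1 − NPV; proportions get Wilson CIs. A
clinical review is costed at 2 minutes and automated assessment at 0;
one FTE is 1950 h/year (37.5 h/week × 52). The published table prints
25.8 staff-hours for 1545 reviews, which corresponds to 1 minute per
review, while the methods text and abstract give 2 minutes and 51.5 h;
this package follows the stated 2-minute costing. The annual-FTE-per-
caseload figure is not derivable from the stated inputs alone, so every
scaling factor (annualization of response volume, study patient count,
reference caseload) is an explicit `StaffingModel` parameter rather
than a hard-coded constant.

Note one deliberate property of the hybrid pathway: because responses
surviving rule-out are decided by the recorded (fallible) clinician
label — which is how the published counts are constructed — a perfectly
informative model cannot force the failure rate to zero on its own; it
guarantees only that the automated rule-out discards no true SSI. The
failure rate is exactly zero when, additionally, clinician triage is
concordant on the reviewed remainder. Tests assert exactly this.

The threshold sweep evaluates a strategy over a sorted grid in [0, 1],
reporting the full outcome row (counts, metrics with CIs, staff-hours,
FTE) per threshold, with an optional two-panel plot (failure rate and
FTE against threshold).

## Problem sizes and reproducibility

Desk-scale runs use 64×64-pixel synthetic images (the preprocessing
default for external images remains 256×256), cohorts of 150–400
patients for model training, and 2000 patients for generator-calibration
checks; these sizes were chosen so the whole suite runs comfortably on a
single CPU while leaving every statistical check well-powered. All
randomness flows through explicit integer seeds (data, split, model);
identical configuration reproduces byte-identical cohort files and
output tables. Known limitations: the renderer's simplicity means image
AUCs on synthetic cohorts are optimistic relative to real photographs;
the MLP and CNN are deliberately small; and the FTE figures are only as
meaningful as the user-supplied annualization and caseload parameters.
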