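# Methods

## Task geometry

One situation is a payoff configuration (p_A, p_B, bonus, context) with
p_A, p_B ∈ {2, 4, 6, 8, 10} and bonus ∈ {2, 4, 6}. The payoff levels
are the even integers of the 2–10 range: the 5 × 5 × 3 factorial then
yields exactly the 75 distinct situations per context that the paradigm
presents. Two derived, model-free features summarize each situation:
the efficiency of the prosocial choice, p_B − b, and the worst-off
score, min(p_A, p_B). Judgment stimuli cross each situation with the
two possible decisions (150 per context). Canonical row order is
lexicographic in (context, p_A, p_B, bonus[, decision]) so exported
tables are byte-stable; presentation order, when needed, is randomized
downstream under a seed.

## Utility families

The core family is the extended Charness–Rabin utility difference

ΔU = bias + γ·μ·min(p_A, p_B) + γ·(1−μ)·(p_B − δᵢ·b) − (1−γ)·δᵢ·b,

with δᵢ = δ₁ in the Destroying context and 1 in Helping. Registry
variants toggle the bias and a free δ₁. The alternatives share the
transfer functions:

- **Fehr–Schmidt**: U(π) = π_A − α·max(π_B−π_A, 0) − β·max(π_A−π_B, 0),
  evaluated at the prosocial outcome (p_A, p_B) minus the selfish
  outcome (p_A + b, 0), optional bias.
- **Harm-aversion trade-off**: ΔU = bias + w·p_B − δᵢ·b, the simplest
  form that balances the bonus against Player B's payoff; the
  "trade-off" variant is this family with a free bias.
- **Krupka–Weber**: ΔU = [bias] − b + φ·[N(prosocial) − N(selfish)],
  where N(a) is the mean appropriateness rating of action a in that
  situation, linearly rescaled from [1, 6] to [−1, 1], computed at group
  level (averaged over all judges) or per individual. No δ₁ variant is
  offered: empirical norms already differ between contexts, so a
  discount would be collinear.

Actions use a two-option softmax, P(prosocial) = logistic(β·ΔU).
Judgments use an ordered probit: signed utility s = +ΔU when the judged
decision is prosocial, −ΔU when selfish (one parameter set predicts
both stimulus types), and P(rating ≤ k) = Φ(t_k − scale·s).

**Identification.** With free thresholds, the judgment bias and the
threshold location are confounded; we constrain the five thresholds to
sum to zero and estimate the bias, keeping it interpretable as an
unbounded intercept. Thresholds are parameterized as a base point plus
four log-gaps, guaranteeing monotonicity.

**Numerical floors.** Per-trial log-probabilities are floored at
log(1e−12) so likelihoods stay finite under extreme parameters.

## Hierarchical estimation

Participant parameters live on unconstrained scales — bias raw,
γ/μ/δ₁ via logit, β/scale via log — and are modeled as draws from
diagonal normal population distributions. The fitter is an
empirical-Bayes EM:

1. **E-step.** Per participant, a penalized MAP (L-BFGS, multi-start on
   the first iteration, warm-started afterwards) under the current
   population normal, plus a diagonal Laplace variance from a
   central-difference Hessian.
2. **M-step.** Population means update as precision-weighted averages
   shrunk by a N(0, 5) hyperprior; population variances as moment
   updates including the Laplace variances, regularized toward a
   half-normal(2.5) scale and clipped to [0.05, 5].

Six to eight iterations suffice at the default problem sizes (the EM
shift drops below 1e−3). A non-hierarchical "map" mode (one pass under
a fixed N(0, 2.5) prior) is available for quick screening.

Participant-level posteriors are then approximated around the MAP. For
pointwise log-likelihood draws we do **not** use raw Laplace draws: in
flat-likelihood directions (e.g. the temperature of a participant who
always chooses the same action) the Gaussian approximation is poor and
produced heavy-tailed PSIS importance ratios. Instead draws come from
sampling-importance-resampling: an overdispersed Gaussian proposal
(Laplace covariance scaled 1.4, ≥5× oversampling) weighted by the exact
unnormalized participant posterior. This cut the Monte-Carlo
variability of elpd between identical refits from tens of nats to
under one, and sharply reduced Pareto-k flags.

Because the participant-level approximation is Gaussian, the mode of
each marginal equals the MAP, so per-participant estimates are the
transformed modes directly (no kernel-density step is needed).

**Diagnostics.** Each fit reports optimizer failures, Hessian
regularizations, and split-R̂ / bulk-ESS computed on the draws (for
independent SIR draws these sit near 1 and the draw count). The gate
R̂ ≤ 1.05, ESS ≥ 100, zero optimizer failures flags — but does not
suppress — a non-converged fit. Degenerate participants (constant
responses) are fitted anyway; their estimates are boundary-attracted
and shrunk toward the population, and a warning lists them.

**Priors.** The defaults above are weakly informative and
domain-respecting; they are echoed into every results directory
together with the seed so any fit is regenerable.

## Model comparison

`psis_loo`/`compare` wrap `arviz.loo` on the pointwise log-likelihood
draws; models are ranked by elpd with pairwise differences and
difference SEs computed from the pointwise elpd contributions against
the best model, plus counts of observations with Pareto k > 0.7.
Comparisons refuse datasets that do not match observation-for-
observation. For Krupka–Weber fits on synthetic runs the norm table is
built from the simulated judgment dataset at group level, mirroring the
use of one sample's judgments to model another sample's actions.

## Synthetic cohorts

The generator encodes four motivational profiles as normal
distributions on the unconstrained scale (so domains hold by
construction). Profile means are package constants — no participant
data are deposited for this paradigm, so they are design choices
validated against the qualitative per-type action patterns the
typology describes:

| profile | bias | γ | μ | β | signature |
|---|---|---|---|---|---|
| unconditionally selfish | −6.0 | 0.14 | 0.50 | 0.8 | never prosocial |
| cost-sensitive | +2.5 | 0.17 | 0.50 | 1.3 | prosocial until the bonus grows |
| efficiency-sensitive | 0.0 | 0.90 | 0.10 | 2.2 | prosocial iff p_B > b |
| harm-sensitive | 0.0 | 0.90 | 0.86 | 1.3 | selfish only when harm is small |

Within-profile SDs are 0.8 (bias), 0.6 (logits), 0.5 (log β). The
inverse-temperature spread reflects the large between-person
variability typical of softmax fits; its between-type differences refer
to the cleaner value signal of outcome-driven types. The default
composition is 20/25/39/16 out of 100. Judgment-model parameters are
near-consensual across profiles (harm-leaning, γ≈μ≈0.75, δ₁≈0.6,
probit scale ≈ 0.35, shared thresholds ±2.5/±1.25), reflecting the
empirical consensus on appropriateness despite divergent actions.

What the generator does **not** emulate: sequential/order effects,
within-session learning or fatigue, response times, the point-earning
game, and any dependence of judgments on one's own actions. Passing
tests therefore certify the estimation and typing machinery under the
model's own assumptions, not robustness to real-data misspecification.

Simulated prosocial rates by type (bonus 2→6): selfish ~0 throughout;
cost-sensitive 0.88→0.32; efficiency 0.90→0.57; harm 0.88→0.78; cohort
mean ≈ 0.58.

## Exposure environments and change model

Donor ranking: A− takes the 11 participants with the highest
selfish-action frequency, A+ the lowest; J+ the 11 strictest mean
raters of selfish actions, J− the most lenient (ties break by
participant id). Feedback per situation: for A±, the donor selfish
count 0–11 mapped by round-half-up(1 + 5·count/11) onto 1–6 (the
simplest monotone surjection consistent with a 1–6 answer scale); for
J±, the modal donor rating with ties resolved to the lower rating.

Ground-truth exposure effects for testing are additive shifts on the
unconstrained scale (per profile or global), so shifted parameters
remain in-domain automatically. The change model refits each
participant jointly across phases with θ_post = θ_pre + Δ, Δ restricted
to bias, logit γ and logit μ (temperature, discount and thresholds
shared across phases) under zero-centered N(0, 1) priors; participants
missing a phase are skipped with a warning.

## Typing

Clustering features are the fitted action-model bias, γ, μ and the
inverse temperature, the latter entered on its log scale — the scale on
which the hierarchy is normal — which stabilizes the variance of a
positive, right-skewed parameter; all features are z-scored with
training-set statistics that are stored for later assignment. k is
chosen by mean silhouette over k ∈ {2..8} with 50 k-means restarts per
k. When k = 4, clusters are named by centroid signature (most negative
bias → unconditionally selfish; then lowest γ → cost-sensitive; of the
remaining two, higher μ → harm-sensitive); otherwise labels stay
generic and a best silhouette below 0.25 triggers a weak-structure
warning — on structureless (single-blob) data the silhouette profile is
flat rather than peaked at any particular k, so the flag, not the
selected k, is the informative output. New cohorts are assigned by
nearest centroid in the stored normalization space, ties to the lowest
cluster index.

## Problem sizes and determinism

Default analyses use 100 participants × 75 trials (actions) and × 150
stimuli (judgments); recovery and cluster-count studies at these sizes
run in seconds per replicate, and the bundled pipeline demo (16
participants, 2 families) in well under a minute. Every stochastic
step takes an explicit seed; pipeline artifacts are byte-identical
across reruns of the same config and seed.

## Known limitations

- The hierarchical posterior is approximate (MAP + SIR-corrected
  Laplace), not MCMC; population-level uncertainty is not propagated
  into participant intervals.
- δ₁ is only identifiable with both contexts present; single-context
  fits fix it at 1, and the recovery study accordingly reports bias, γ,
  μ and β.
- The inverse temperature recovers less sharply than the value
  parameters (r ≈ 0.5–0.7 vs ≥ 0.75 at default sizes), a generic
  limitation of softmax temperature estimation for extreme responders.
- Ordered-probit bias and scale are weakly identified for judges whose
  ratings rarely leave one category.
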