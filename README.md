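# prosocial-motives

A computational framework for dissecting the motives behind prosocial
behavior. It models two kinds of responses to the same payoff
situations — binary prosocial/selfish **actions** and 1–6
**appropriateness judgments** — with a shared utility core, fits the
models hierarchically, compares utility families by approximate
leave-one-out cross-validation, clusters fitted motives into
behavioral types, and analyzes how those types adapt after exposure to
social environments with shifted norms. Because no participant-level
dataset is publicly deposited for this paradigm, the package ships a
first-class synthetic-cohort generator that emulates the task design
and the four motivational profiles, so every analysis is runnable and
testable end to end.

It is written for computational cognitive scientists and behavioral
economists who want to fit these models to their own trial-level CSVs,
or to prototype norm-intervention designs in simulation.

## The model

In each situation Player A earned `p_A` points and Player B `p_B`
(both in {2,4,6,8,10}); A may take a bonus `b` in {2,4,6}, leaving B
with 0 (selfish), or forgo it so B keeps `p_B` (prosocial). The framing
is either *Destroying* (actively erase B's points) or *Helping* (decline
to restore them). The utility difference of acting prosocially is

```
ΔU = bias + γ·μ·min(p_A, p_B) + γ·(1−μ)·[p_B − δᵢ·b] − (1−γ)·δᵢ·b
```

- `bias` — stake-independent baseline preference for prosocial responding;
- `γ ∈ [0,1]` — weight on prosocial outcomes versus the own bonus;
- `μ ∈ [0,1]` — goal spectrum from pure efficiency (μ=0, total wealth
  `p_B − b`) to pure harm-aversion (μ=1, worst-off score `min(p_A, p_B)`);
- `δ₁ ∈ [0,1]` — bonus discount in the Destroying context (δ=1 in Helping).

Actions follow a softmax, `P(prosocial) = logistic(β·ΔU)`; judgments
follow an ordered probit over the six ratings with signed utility `+ΔU`
for judging the prosocial act and `−ΔU` for the selfish act,
`P(rating ≤ k) = Φ(t_k − s·ΔU±)`, thresholds `t` constrained to sum to
zero. Alternative families (Fehr–Schmidt inequity aversion, a
harm-aversion trade-off model, and Krupka–Weber norm-following driven
by empirical rating tables) plug into the same transfer functions for
model comparison.

Fitting is empirical-Bayes EM (per-participant MAP under normal
population priors on unconstrained scales, Laplace variances, moment
updates), with sampling-importance-resampling posterior draws feeding
PSIS-LOO via `arviz`. Typing is silhouette-optimized k-means on the
fitted (bias, γ, μ, log β) features. See `docs/methods.md` for
assumptions, priors, and numerical choices.

## Worked example

`examples/04_fit_and_recovery.py` simulates the default 100-participant
cohort (20 unconditionally selfish, 25 cost-sensitive, 39
efficiency-sensitive, 16 harm-sensitive), one action per situation of
the 75-trial Destroy grid, refits the model, and prints:

```
100 participants, 75 trials each
generating vs recovered Pearson r:
  bias      r = 0.776
  gamma     r = 0.935
  mu        r = 0.787
  inv_temp  r = 0.529
minimum r = 0.529
fit converged: True, optimizer failures: 0
```

Every motive correlates well above chance between truth and recovery,
i.e. each parameter leaves an identifiable signature in 75 choices.
`examples/06_motivational_types.py` then clusters recovered parameters:
the silhouette criterion selects k = 4 and 96% of participants are
assigned their generating profile. The other examples cover the grids,
the response functions, cohort simulation, PSIS-LOO comparison (the
generating family wins by several SE), and norm-exposure analysis.

A configuration-driven pipeline is also available from the shell:

```bash
prosocial-motives all --seed 3 --out results/demo
```

which writes data tables, fits, the comparison table, the cluster
model, change tables and a markdown report into `results/demo/`.

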