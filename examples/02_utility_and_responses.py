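"""Compute utilities and response probabilities for one decider.

The extended Charness-Rabin utility difference dU (prosocial minus
selfish) feeds two transfer functions sharing the same motives: a
softmax for the binary action and an ordered probit for the 1-6
appropriateness rating.
"""

import pandas as pd

import prosocial_motives as pm

situation = pd.DataFrame(
    {"context": ["destroy"], "p_a": [2], "p_b": [10], "bonus": [6]}
)

params = pm.CRParams(bias=0.0, gamma=0.5, mu=0.5, delta1=1.0, inv_temp=1.0,
                     scale=0.4, thresholds=(-2.5, -1.25, 0.0, 1.25, 2.5))

du = float(pm.delta_u(params, situation)[0])
p = pm.prob_prosocial(du, params.inv_temp)
print(f"dU = {du:+.2f}  (negative: the bonus outweighs this decider's "
      "outcome concerns here)")
print(f"P(prosocial action) = {p:.3f}")

for decision in ("prosocial", "selfish"):
    probs = pm.rating_probs(du, decision, params.thresholds, params.scale)
    pretty = " ".join(f"{q:.2f}" for q in probs)
    print(f"rating distribution when judging the {decision:9s} act: [{pretty}]")
# The same negative dU that makes the selfish act likely also shifts the
# judged appropriateness of the selfish act upward (ratings 1=very
# inappropriate ... 6=very appropriate).
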