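"""Hierarchical fit and parameter recovery of the action model.

Simulates the default cohort, refits the extended Charness-Rabin model
with the empirical-Bayes EM, and correlates generating with recovered
parameter values - the standard check that the model's motives are
identifiable from 75 trials per person.
"""

import warnings

import prosocial_motives as pm

warnings.filterwarnings("ignore", category=UserWarning)

report = pm.recovery_study(seed=0, fit_mode="hierarchical", n_em=6)

print(f"{report.n_participants} participants, 75 trials each")
print("generating vs recovered Pearson r:")
for param, r in report.correlations.items():
    print(f"  {param:9s} r = {r:.3f}")
print(f"minimum r = {report.min_r:.3f}")
print(f"fit converged: {report.fit.converged}, "
      f"optimizer failures: {report.fit.diagnostics['n_optim_failures']}")
# r comfortably above 0.44 for every parameter means each motive leaves
# a recoverable signature in choices at this trial count.
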