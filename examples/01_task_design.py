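"""Build the factorial trial grids and inspect their model-free features.

Every situation pairs Player A's points, Player B's points (2-10) and a
bonus (2-6) that A can take by acting selfishly, leaving B with nothing.
"""

import prosocial_motives as pm

actions = pm.build_action_grid(["destroy", "help"])
judgments = pm.build_judgment_grid(["destroy", "help"])

print(f"action situations:  {len(actions)} (75 per context)")
print(f"judgment stimuli:   {len(judgments)} (each situation x 2 decisions)")

destroy = actions[actions["context"] == "destroy"]
print(f"\nprosocial action is efficient (p_b > bonus) in "
      f"{(destroy['efficiency'] > 0).sum()}/75 situations,")
print(f"wealth-neutral (p_b == bonus) in {(destroy['efficiency'] == 0).sum()}/75.")

print("\nfirst rows with derived features:")
print(destroy.head(4).to_string(index=False))
# efficiency = p_b - bonus is what a total-wealth maximizer cares about;
# worst_off = min(p_a, p_b) is what a harm-averse decider protects.
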