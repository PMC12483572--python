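"""Simulate the kin-term generalisation task and code the choices.

Simulates two cohorts — uniform-random responders and greedy entropy
minimisers — on the eight system types (one trial each). Every choice is
coded 1 if it produced the greatest possible decrease in symmetric
conditional entropy among the four candidate labels, given the choices made
so far. Chance is 25% when a single candidate is optimal; a greedy minimiser
is predictive by construction. Completed systems are also z-scored against
1,000 shuffles of their own labels.
"""

import numpy as np

from kinstruct import (
    AgentPolicy,
    code_trial_run,
    cooccurrence_matrix,
    participant_system_z,
    proportion_predictive,
    simulate_participants,
)
from kinstruct.permutation import derive_seed

for policy_kind in ("random", "predictive_greedy"):
    runs = simulate_participants(AgentPolicy(policy_kind, seed=7), 10, seed=7)
    coded = [c for run in runs for c in code_trial_run(run)]
    overall = proportion_predictive(coded)
    unique = proportion_predictive(coded, unique_argmin_only=True)
    zs = [
        participant_system_z(
            run, n_permutations=1000,
            seed=derive_seed(7, f"{run.participant_id}:{run.trial.trial_id}"),
        ).z
        for run in runs
    ]
    print(f"policy = {policy_kind}")
    print(f"  proportion predictive (all choices):        "
          f"{overall['proportion_predictive'].iloc[0]:.3f}")
    print(f"  proportion predictive (unique-argmin only): "
          f"{unique['proportion_predictive'].iloc[0]:.3f}")
    print(f"  mean participant-system z: {np.mean(zs):+.2f}")

runs = simulate_participants(AgentPolicy("predictive_greedy", seed=7), 10, seed=7)
type_i = [r.completion() for r in runs if r.trial.system_type.type_id == "I"]
mat = cooccurrence_matrix(type_i)
print()
print("Type I co-occurrence, greedy agents (1 = always share a term):")
print(mat.loc[["B", "Z", "MZS", "MZD"], ["B", "Z", "MZS", "MZD"]].to_string())
print()
print("Greedy minimisers categorise all cousins together and both siblings")
print("together (the maximally predictive Type I solution); random responders")
print("hover at chance and their completed systems stay near z = 0.")
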