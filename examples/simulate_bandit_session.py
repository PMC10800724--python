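"""Simulate one two-armed-bandit session and inspect the agent's learning.

Builds the standard 100-trial schedule (70/30 win probabilities, reversed
after trials 30 and 70, rewards of +10/-10 points), forward-simulates an
agent at the cohort-mean traits, and prints its earnings and a few trial
traces.
"""

from insightrl import ModelParameters, make_standard_schedule, simulate_agent, tab_performance
from insightrl.model import advantageous_accuracy, traces_to_frame

schedule = make_standard_schedule()
params = ModelParameters(beta=0.85, mu=0.48, nu=0.52, alpha_pos=0.42,
                         alpha_neg=0.59, lam=0.51, phi=0.0)

record, traces = simulate_agent(params, schedule, seed=42)

print(f"trials simulated : {len(record)}")
print(f"total points     : {tab_performance(record):+.0f}")
print(f"accuracy         : {advantageous_accuracy(record, schedule):.2f} "
      "(fraction of choices on the currently 70% box)")
print()
print("first five trials (delta = prediction error, p_right = softmax prob):")
print(traces_to_frame(traces).head().round(3).to_string(index=False))
# A positive total means the agent earned points overall; accuracy above 0.5
# means it tracked the advantageous box through the two reversals.
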