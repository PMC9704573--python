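"""Simulate the two-step environment and one agent's session.

Builds the default task (70/30 transitions, four drifting reward
probabilities bounded in [0.25, 0.75]) and a hybrid agent, then prints
summary statistics of one 150-trial condition.
"""

import numpy as np

from twostep import AgentParams, TaskConfig
from twostep.agent import simulate_condition
from twostep.task import generate_walks, walks_to_frame

rng = np.random.default_rng(0)
config = TaskConfig()

traj = generate_walks(config, rng)
print("walk trajectory:", traj.shape, "min %.3f max %.3f" % (traj.min(), traj.max()))
print(walks_to_frame(traj).head())

params = AgentParams(alpha=0.6, beta_mb=1.4, beta_mf=1.5, beta_2=1.6, rho=1.0)
sim = simulate_condition(params, config, rng)
common = np.mean(sim["transition"] == "common")
stay = np.mean(sim["choice1"][1:] == sim["choice1"][:-1])
print(f"common transitions: {common:.2f} (environment rate 0.70)")
print(f"reward rate: {sim['reward'].mean():.2f} (walks live in [0.25, 0.75])")
print(f"stage-1 stay rate: {stay:.2f} (perseveration rho pushes this above 0.5)")
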