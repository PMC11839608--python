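"""Personalize activity parameters for one participant with Q-learning.

The simulated participant prefers skill-based activities at moderate
intensity.  The learner discovers this from reward feedback alone; the
learned greedy policy is compared to uniform-random prescription.
"""

import numpy as np

from apeo.rl import ActionGrid, ParticipantEnv, train_policy

grid = ActionGrid(n_intensity=3, n_duration=1)
env = ParticipantEnv(grid=grid, preferred_modality="skill",
                     preferred_intensity=0.5, seed=0)
Q, returns = train_policy(env, episodes=150, seed=0)

best = Q.greedy(env.reset())
act = grid.action(best)
print(f"learned action: modality={act.modality}, intensity={act.intensity}")


def rollout(policy):
    s, total, done = env.reset(), 0.0, False
    rng = np.random.default_rng(1)
    while not done:
        s, r, done = env.step(policy(s, rng))
        total += r
    return total


greedy = rollout(lambda s, rng: Q.greedy(s))
random = rollout(lambda s, rng: int(rng.integers(env.n_actions)))
print(f"episode return: greedy {greedy:.2f} vs random {random:.2f}")

# The greedy policy discovers the participant's preferred modality (skill)
# and an intensity that trades task score against effort cost, collecting
# a higher episode return than random prescription.
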