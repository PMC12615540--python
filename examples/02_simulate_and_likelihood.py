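"""Simulate one PP-ORL agent and evaluate its choice likelihood.

The agent carries four parameters: reward and punishment learning rates
(a_rew, a_pun), win-frequency sensitivity (beta_f) and response bias
(beta_b).  A high punishment learning rate makes the agent abandon deck B
quickly after its -$1150 card.
"""

import numpy as np

from pporl import ORLParams, simulate_agent, subject_log_likelihood, task_components

_, schedule, sequences = task_components()

cautious = ORLParams(a_rew=0.11, a_pun=0.60, beta_f=3.1, beta_b=1.2)
subject = simulate_agent(cautious, schedule, sequences, seed=7)

plays = sum(r.choice for r in subject.trials)
print(f"agent played {plays}/120 trials")
for deck in "ABCD":
    rate = np.mean([r.choice for r in subject.trials if r.deck == deck])
    print(f"  deck {deck}: play proportion {rate:.2f}")

ll = subject_log_likelihood(subject, cautious, sequences)
print(f"log-likelihood of its own data: {ll:.2f} "
      f"({ll / subject.n_trials:.3f} per trial; chance is "
      f"{np.log(0.5):.3f})")

# a mismatched parameterization should explain the data worse
greedy = ORLParams(a_rew=0.5, a_pun=0.02, beta_f=0.5, beta_b=2.0)
print(f"log-likelihood under a play-happy agent: "
      f"{subject_log_likelihood(subject, greedy, sequences):.2f}")
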