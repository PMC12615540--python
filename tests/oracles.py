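"""Independent brute-force reference implementations used only by tests.

Deliberately naive: plain-Python trial-stepped recursions and direct
scipy.stats density sums, coded from the model definition without reference
to the package's optimized paths.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import cauchy, halfnorm, norm

DECKS = "ABCD"


def reference_log_likelihood(trials, a_rew, a_pun, beta_f, beta_b,
                             outcome_scale=100.0):
    """Naive PP-ORL recursion over (deck_letter, choice, outcome_dollars) triples."""
    ev = {d: 0.0 for d in DECKS}
    ef = {d: 0.0 for d in DECKS}
    total = 0.0
    for deck, choice, outcome in trials:
        v = ev[deck] + ef[deck] * beta_f + beta_b
        p = 1.0 / (1.0 + math.exp(-v))
        total += math.log(p) if choice == 1 else math.log(1.0 - p)
        if choice == 1:
            x = outcome / outcome_scale
            sgn = (x > 0) - (x < 0)
            if x >= 0:
                a_self, a_other = a_rew, a_pun
            else:
                a_self, a_other = a_pun, a_rew
            ev[deck] = ev[deck] + a_self * (x - ev[deck])
            ef[deck] = ef[deck] + a_self * (sgn - ef[deck])
            for other in DECKS:
                if other != deck:
                    ef[other] = ef[other] + a_other * (-sgn / 3.0 - ef[other])
    return total


def reference_log_prior(beta, sigma, z):
    """Direct scipy.stats evaluation of the joint prior log density."""
    lp = norm.logpdf(np.asarray(beta)).sum()
    lp += halfnorm.logpdf(np.asarray(sigma)[:2], scale=2.0).sum()
    # half-Cauchy(0, 1): twice the Cauchy density on the positive half-line
    lp += (np.log(2.0) + cauchy.logpdf(np.asarray(sigma)[2:], scale=1.0)).sum()
    lp += norm.logpdf(np.asarray(z)).sum()
    return float(lp)


def reference_joint_log_posterior(subject_trials, X, beta, sigma, z,
                                  outcome_scale=100.0):
    """Prior + summed subject likelihoods at probit-transformed parameters."""
    lp = reference_log_prior(beta, sigma, z)
    beta = np.asarray(beta)
    sigma = np.asarray(sigma)
    for i, trials in enumerate(subject_trials):
        gamma = X[i] @ beta.T + z[i] * sigma
        lp += reference_log_likelihood(
            trials, norm.cdf(gamma[0]), norm.cdf(gamma[1]),
            gamma[2], gamma[3], outcome_scale)
    return lp


def random_trial_sequence(rng, n_trials=120, play_prob=0.5):
    """A random but internally consistent trial list on the 4x30 card task.

    Decks are presented 30 times each in shuffled order; played trials
    consume cards from fixed random card orders per deck.
    """
    card_pools = {
        "A": [100.0] * 15 + [-50.0, -100.0, -150.0, -200.0, -250.0] * 3,
        "B": [100.0] * 27 + [-1150.0] * 3,
        "C": [50.0] * 15 + [0.0] * 9 + [-25.0] * 6,
        "D": [50.0] * 27 + [-200.0] * 3,
    }
    orders = {d: list(rng.permutation(v)) for d, v in card_pools.items()}
    schedule = list("ABCD" * 30)
    rng.shuffle(schedule)
    schedule = schedule[:n_trials]
    pos = {d: 0 for d in DECKS}
    trials = []
    for deck in schedule:
        if rng.random() < play_prob and pos[deck] < len(orders[deck]):
            trials.append((deck, 1, float(orders[deck][pos[deck]])))
            pos[deck] += 1
        else:
            trials.append((deck, 0, None))
    return trials
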