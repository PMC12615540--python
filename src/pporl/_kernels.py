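"""Numba kernels for the cohort-level PP-ORL likelihood and simulation.

The likelihood kernel carries forward-mode derivatives of the per-deck
expectations with respect to the two learning rates (the two beta weights
enter the play value linearly, so their derivatives need no state).  The
recursion's branch conditions depend only on the data, never on the
parameters, so the log-likelihood is smooth and the tangent propagation is
exact.  Equality with the naive trial-stepped recursion is enforced by the
test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: fictive-update divisor: number of other decks
_C = 3.0


@njit(cache=True)
def cohort_loglik_grad(deck_idx, choice, outcome, params):
    """Log-likelihood and its gradient for every subject.

    Parameters
    ----------
    deck_idx : (n, T) int64, presented deck 0..3 per trial
    choice : (n, T) int64, 1 play / 0 pass
    outcome : (n, T) float64, scaled outcome (ignored on passes)
    params : (n, 4) float64, columns a_rew, a_pun, beta_f, beta_b

    Returns
    -------
    ll : (n,) float64
    grad : (n, 4) float64, d ll / d (a_rew, a_pun, beta_f, beta_b)
    """
    n, T = deck_idx.shape
    ll = np.zeros(n)
    grad = np.zeros((n, 4))
    for i in range(n):
        a_rew = params[i, 0]
        a_pun = params[i, 1]
        bf = params[i, 2]
        bb = params[i, 3]
        ev = np.zeros(4)
        ef = np.zeros(4)
        # dev[j, k], def_[j, k]: derivative wrt (k=0: a_rew, k=1: a_pun)
        dev = np.zeros((4, 2))
        def_ = np.zeros((4, 2))
        for t in range(T):
            j = deck_idx[i, t]
            y = choice[i, t]
            v = ev[j] + bf * ef[j] + bb
            # log Bernoulli mass: y*v - softplus(v)
            if v > 0.0:
                sp = v + np.log1p(np.exp(-v))
            else:
                sp = np.log1p(np.exp(v))
            ll[i] += y * v - sp
            p = 1.0 / (1.0 + np.exp(-v))
            resid = y - p
            grad[i, 0] += resid * (dev[j, 0] + bf * def_[j, 0])
            grad[i, 1] += resid * (dev[j, 1] + bf * def_[j, 1])
            grad[i, 2] += resid * ef[j]
            grad[i, 3] += resid
            if y == 1:
                x = outcome[i, t]
                sgn = 0.0
                if x > 0.0:
                    sgn = 1.0
                elif x < 0.0:
                    sgn = -1.0
                if x >= 0.0:
                    a_self, k_self = a_rew, 0
                    a_other, k_other = a_pun, 1
                else:
                    a_self, k_self = a_pun, 1
                    a_other, k_other = a_rew, 0
                # tangents first (they use the pre-update state)
                dev[j, 0] *= (1.0 - a_self)
                dev[j, 1] *= (1.0 - a_self)
                def_[j, 0] *= (1.0 - a_self)
                def_[j, 1] *= (1.0 - a_self)
                dev[j, k_self] += x - ev[j]
                def_[j, k_self] += sgn - ef[j]
                ev[j] += a_self * (x - ev[j])
                ef[j] += a_self * (sgn - ef[j])
                ftgt = -sgn / _C
                for d in range(4):
                    if d != j:
                        def_[d, 0] *= (1.0 - a_other)
                        def_[d, 1] *= (1.0 - a_other)
                        def_[d, k_other] += ftgt - ef[d]
                        ef[d] += a_other * (ftgt - ef[d])
    return ll, grad


@njit(cache=True)
def simulate_choices(deck_idx, seq_outcomes, params, u_choice, u_timeout,
                     timeout_prob):
    """Simulate play/pass behaviour for many agents on a shared schedule.

    Parameters
    ----------
    deck_idx : (T,) int64, presented deck per trial (shared schedule)
    seq_outcomes : (4, n_cards) float64, scaled card order per deck
    params : (n, 4) float64
    u_choice, u_timeout : (n, T) float64, pre-drawn uniforms
    timeout_prob : float, per-trial timeout probability (timeout => pass)

    Returns
    -------
    choices : (n, T) int64
    outcomes : (n, T) float64 (scaled; 0 on passes)
    timeouts : (n, T) boolean
    """
    n = params.shape[0]
    T = deck_idx.shape[0]
    choices = np.zeros((n, T), dtype=np.int64)
    outcomes = np.zeros((n, T))
    timeouts = np.zeros((n, T), dtype=np.bool_)
    for i in range(n):
        a_rew = params[i, 0]
        a_pun = params[i, 1]
        bf = params[i, 2]
        bb = params[i, 3]
        ev = np.zeros(4)
        ef = np.zeros(4)
        pos = np.zeros(4, dtype=np.int64)
        for t in range(T):
            j = deck_idx[t]
            if timeout_prob > 0.0 and u_timeout[i, t] < timeout_prob:
                timeouts[i, t] = True
                continue
            v = ev[j] + bf * ef[j] + bb
            p = 1.0 / (1.0 + np.exp(-v))
            if u_choice[i, t] < p:
                x = seq_outcomes[j, pos[j]]
                pos[j] += 1
                choices[i, t] = 1
                outcomes[i, t] = x
                sgn = 0.0
                if x > 0.0:
                    sgn = 1.0
                elif x < 0.0:
                    sgn = -1.0
                if x >= 0.0:
                    a_self, a_other = a_rew, a_pun
                else:
                    a_self, a_other = a_pun, a_rew
                ev[j] += a_self * (x - ev[j])
                ef[j] += a_self * (sgn - ef[j])
                ftgt = -sgn / _C
                for d in range(4):
                    if d != j:
                        ef[d] += a_other * (ftgt - ef[d])
    return choices, outcomes, timeouts
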