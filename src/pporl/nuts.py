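"""No-U-Turn Hamiltonian Monte Carlo over a differentiable log density.

A self-contained multinomial NUTS implementation in the style that modern
probabilistic-programming backends use: leapfrog integration with a
diagonal mass matrix, dynamic trajectory doubling stopped by the
generalized U-turn criterion, multinomial sampling of the proposal within
the trajectory, dual-averaging step-size adaptation toward a target
acceptance statistic, and windowed estimation of the diagonal mass matrix
from warmup draws.  Divergences are flagged when the simulated Hamiltonian
error exceeds 1000.

The sampler is generic: it targets any callable ``logp_grad(x) -> (logp,
grad)`` and is exercised against closed-form Gaussian targets in the test
suite before being trusted on the hierarchical model posterior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["ChainResult", "SamplerError", "sample_chain"]

_DIVERGENCE_THRESHOLD = 1000.0


class SamplerError(RuntimeError):
    """Raised when sampling cannot start (e.g. non-finite initial density)."""


@dataclass
class ChainResult:
    """Post-warmup draws and per-draw sampler statistics for one chain."""

    draws: np.ndarray  #: (n_draws, dim)
    divergent: np.ndarray  #: (n_draws,) bool
    accept_stat: np.ndarray  #: (n_draws,) mean leapfrog acceptance statistic
    tree_depth: np.ndarray  #: (n_draws,) int
    energy: np.ndarray  #: (n_draws,) Hamiltonian at the accepted state
    step_size: float
    inv_mass: np.ndarray


def _kinetic(r: np.ndarray, inv_mass: np.ndarray) -> float:
    return 0.5 * float(np.dot(r, inv_mass * r))


def _find_initial_step(logp_grad, x, lp, grad, inv_mass, rng) -> float:
    """Double/halve until the one-step acceptance probability crosses 1/2."""
    eps = 1.0
    r = rng.normal(size=x.size) / np.sqrt(inv_mass)
    h0 = -lp + _kinetic(r, inv_mass)

    def one_step(eps: float) -> float:
        r1 = r + 0.5 * eps * grad
        x1 = x + eps * inv_mass * r1
        lp1, g1 = logp_grad(x1)
        if not np.all(np.isfinite(g1)) or not np.isfinite(lp1):
            return -np.inf
        r1 = r1 + 0.5 * eps * g1
        return h0 - (-lp1 + _kinetic(r1, inv_mass))

    log_accept = one_step(eps)
    direction = 1 if log_accept > np.log(0.5) else -1
    for _ in range(100):
        eps *= 2.0 ** direction
        log_accept = one_step(eps)
        if direction == 1 and not (log_accept > np.log(0.5)):
            break
        if direction == -1 and not (log_accept < np.log(0.5)):
            break
        if eps > 1e7 or eps < 1e-10:
            break
    return eps


class _Tree:
    """One (sub)trajectory: endpoints, multinomial proposal, stop flags."""

    __slots__ = ("x_minus", "r_minus", "g_minus", "x_plus", "r_plus", "g_plus",
                 "x_prop", "lp_prop", "log_sum_w", "sum_accept", "n_leapfrog",
                 "turning", "diverging")


def _warmup_schedule(n_warmup: int) -> tuple[int, int, list[int]]:
    """(step-size-only init buffer, terminal buffer, mass-window boundaries)."""
    if n_warmup < 20:
        return n_warmup, 0, []
    init = min(75, max(int(0.15 * n_warmup), 10))
    term = min(50, max(int(0.10 * n_warmup), 10))
    middle = n_warmup - init - term
    boundaries: list[int] = []
    if middle >= 20:
        size = min(25, middle)
        pos = init
        while pos + size < n_warmup - term:
            # merge the final window if doubling again would overshoot
            if pos + size + 2 * size >= n_warmup - term:
                size = (n_warmup - term) - pos
            boundaries.append(pos + size)
            pos += size
            size *= 2
        if not boundaries or boundaries[-1] != n_warmup - term:
            boundaries.append(n_warmup - term)
    return init, term, boundaries


def sample_chain(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    n_draws: int,
    n_warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
) -> ChainResult:
    """Run one NUTS chain; returns the ``n_draws`` post-warmup draws."""
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    inv_mass = np.ones(dim)
    lp, grad = logp_grad(x)
    if not np.isfinite(lp) or not np.all(np.isfinite(grad)):
        raise SamplerError("non-finite log density or gradient at the initial point")

    eps = _find_initial_step(logp_grad, x, lp, grad, inv_mass, rng)

    # dual averaging (Hoffman-Gelman defaults)
    da_gamma, da_t0, da_kappa = 0.05, 10.0, 0.75
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar, da_count = 0.0, 0.0, 0

    init_buf, term_buf, boundaries = _warmup_schedule(n_warmup)
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    total = n_warmup + n_draws
    draws = np.empty((n_draws, dim))
    divergent = np.zeros(n_draws, dtype=bool)
    accept_stat = np.zeros(n_draws)
    tree_depth = np.zeros(n_draws, dtype=np.int64)
    energy = np.zeros(n_draws)

    def build_tree(x, r, g, depth, direction, h0) -> _Tree:
        if depth == 0:
            r1 = r + 0.5 * direction * eps * g
            x1 = x + direction * eps * inv_mass * r1
            lp1, g1 = logp_grad(x1)
            tree = _Tree()
            if np.isfinite(lp1) and np.all(np.isfinite(g1)):
                r1 = r1 + 0.5 * direction * eps * g1
                h1 = -lp1 + _kinetic(r1, inv_mass)
            else:
                lp1, h1 = -np.inf, np.inf
            log_w = h0 - h1 if np.isfinite(h1) else -np.inf
            tree.x_minus = tree.x_plus = tree.x_prop = x1
            tree.r_minus = tree.r_plus = r1
            tree.g_minus = tree.g_plus = g1
            tree.lp_prop = lp1
            tree.log_sum_w = log_w
            tree.sum_accept = float(np.exp(min(log_w, 0.0)))
            tree.n_leapfrog = 1
            tree.turning = False
            tree.diverging = bool((h1 - h0) > _DIVERGENCE_THRESHOLD) \
                if np.isfinite(h1) else True
            return tree

        first = build_tree(x, r, g, depth - 1, direction, h0)
        if first.turning or first.diverging:
            return first
        if direction == 1:
            second = build_tree(first.x_plus, first.r_plus, first.g_plus,
                                depth - 1, direction, h0)
        else:
            second = build_tree(first.x_minus, first.r_minus, first.g_minus,
                                depth - 1, direction, h0)

        merged = _Tree()
        merged.sum_accept = first.sum_accept + second.sum_accept
        merged.n_leapfrog = first.n_leapfrog + second.n_leapfrog
        merged.diverging = second.diverging
        merged.turning = second.turning
        if direction == 1:
            merged.x_minus, merged.r_minus, merged.g_minus = \
                first.x_minus, first.r_minus, first.g_minus
            merged.x_plus, merged.r_plus, merged.g_plus = \
                second.x_plus, second.r_plus, second.g_plus
        else:
            merged.x_minus, merged.r_minus, merged.g_minus = \
                second.x_minus, second.r_minus, second.g_minus
            merged.x_plus, merged.r_plus, merged.g_plus = \
                first.x_plus, first.r_plus, first.g_plus
        merged.log_sum_w = np.logaddexp(first.log_sum_w, second.log_sum_w)
        # multinomial (unbiased within-tree) proposal selection
        if (not merged.diverging and not merged.turning
                and np.log(rng.random()) < second.log_sum_w - merged.log_sum_w):
            merged.x_prop, merged.lp_prop = second.x_prop, second.lp_prop
        else:
            merged.x_prop, merged.lp_prop = first.x_prop, first.lp_prop
        if not merged.turning and not merged.diverging:
            dx = merged.x_plus - merged.x_minus
            merged.turning = (
                float(np.dot(dx, inv_mass * merged.r_minus)) < 0
                or float(np.dot(dx, inv_mass * merged.r_plus)) < 0)
        return merged

    for it in range(total):
        r0 = rng.normal(size=dim) / np.sqrt(inv_mass)
        h0 = -lp + _kinetic(r0, inv_mass)

        x_minus = x_plus = x
        r_minus = r_plus = r0
        g_minus = g_plus = grad
        x_prop, lp_prop = x, lp
        log_sum_w = 0.0
        sum_accept, n_leapfrog = 0.0, 0
        depth, diverged = 0, False

        while depth < max_treedepth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == 1:
                subtree = build_tree(x_plus, r_plus, g_plus, depth, 1, h0)
                if not (subtree.turning or subtree.diverging):
                    x_plus, r_plus, g_plus = \
                        subtree.x_plus, subtree.r_plus, subtree.g_plus
            else:
                subtree = build_tree(x_minus, r_minus, g_minus, depth, -1, h0)
                if not (subtree.turning or subtree.diverging):
                    x_minus, r_minus, g_minus = \
                        subtree.x_minus, subtree.r_minus, subtree.g_minus
            sum_accept += subtree.sum_accept
            n_leapfrog += subtree.n_leapfrog
            if subtree.diverging:
                diverged = True
                break
            if subtree.turning:
                break
            # biased progressive sampling of the new half-tree
            if np.log(rng.random()) < subtree.log_sum_w - log_sum_w:
                x_prop, lp_prop = subtree.x_prop, subtree.lp_prop
            log_sum_w = np.logaddexp(log_sum_w, subtree.log_sum_w)
            depth += 1
            dx = x_plus - x_minus
            if (float(np.dot(dx, inv_mass * r_minus)) < 0
                    or float(np.dot(dx, inv_mass * r_plus)) < 0):
                break

        x, lp = x_prop, lp_prop
        _, grad = logp_grad(x)
        alpha = sum_accept / max(n_leapfrog, 1)

        if it < n_warmup:
            da_count += 1
            frac = 1.0 / (da_count + da_t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - alpha)
            log_eps = mu - np.sqrt(da_count) / da_gamma * h_bar
            eta = da_count ** (-da_kappa)
            log_eps_bar = eta * log_eps + (1.0 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))

            in_window = init_buf <= it < n_warmup - term_buf and boundaries
            if in_window:
                welford_n += 1
                delta = x - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (x - welford_mean)
                if it + 1 in boundaries:
                    if welford_n >= 5:
                        var = welford_m2 / max(welford_n - 1, 1)
                        w = welford_n / (welford_n + 5.0)
                        inv_mass = w * var + (1.0 - w) * 1e-3
                        inv_mass = np.maximum(inv_mass, 1e-10)
                    welford_n = 0
                    welford_mean[:] = 0.0
                    welford_m2[:] = 0.0
                    # re-tune the step size for the new metric
                    lp, grad = logp_grad(x)
                    eps = _find_initial_step(logp_grad, x, lp, grad,
                                             inv_mass, rng)
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            k = it - n_warmup
            draws[k] = x
            divergent[k] = diverged
            accept_stat[k] = alpha
            tree_depth[k] = depth
            energy[k] = h0

    return ChainResult(draws, divergent, accept_stat, tree_depth, energy,
                       eps, inv_mass)
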