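"""Posterior sampling, convergence diagnostics, predictive checks, recovery.

:func:`fit` draws from the joint hierarchical posterior with the NUTS
sampler in :mod:`pporl.nuts`; chains run sequentially with independent
seeds spawned from one root seed, so a fit is bit-reproducible for a fixed
seed and package version.  Diagnostics follow current practice:
rank-normalized split R-hat and bulk effective sample size (via ArviZ) for
every stored quantity, with 1.1 as the convergence criterion, plus the
divergence count from the sampler itself.

:func:`posterior_predictive` re-simulates task behaviour from posterior
draws and summarizes play proportions per group x deck x block with 50%
and 95% central credible bands next to the observed curves.
:func:`parameter_recovery` closes the loop: simulate a cohort at known
group coefficients, refit, and score coefficient bias, interval coverage,
and the correlation between true and estimated person-level parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import nuts
from .cohort import CohortData, CohortSpec, generate_cohort
from .decks import DECK_LABELS
from .hierarchy import (COEF_NAMES, PARAM_NAMES, GroupCoefficients,
                        ORLPosterior, SubjectEffects, design_matrix,
                        person_parameters)
from .orl import OUTCOME_SCALE
from ._kernels import simulate_choices


class InferenceError(RuntimeError):
    """Raised for invalid sampler configurations or unusable draws."""


@dataclass(frozen=True)
class SamplerConfig:
    """Sampling plan: total iterations per chain include the warmup."""

    n_chains: int = 4
    n_iterations: int = 1000
    n_warmup: int = 250
    seed: int = 0
    target_accept: float = 0.8
    max_treedepth: int = 10

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise InferenceError("need at least one chain")
        if not 0 < self.n_warmup < self.n_iterations:
            raise InferenceError("require 0 < n_warmup < n_iterations")
        if not 0.0 < self.target_accept < 1.0:
            raise InferenceError("target_accept must lie in (0, 1)")

    @classmethod
    def full_profile(cls, seed: int = 0) -> "SamplerConfig":
        """The study-scale plan: 4 chains x 5000 iterations, 1000 warmup."""
        return cls(n_chains=4, n_iterations=5000, n_warmup=1000, seed=seed)


@dataclass(frozen=True)
class PosteriorDraws:
    """Per-chain posterior draws of every group- and person-level quantity.

    ``beta``: (chain, draw, param, coef) regression coefficients on the
    latent scale; ``sigma``: (chain, draw, param) group SDs; ``z``:
    (chain, draw, subject, param) standardized person effects.  ``X`` is the
    cohort design matrix, so the derived person-level parameters
    gamma = X beta' + z*sigma are recomputable from what is stored.
    """

    beta: np.ndarray
    sigma: np.ndarray
    z: np.ndarray
    X: np.ndarray
    subject_ids: tuple[str, ...]
    divergent: np.ndarray = field(default=None)  # (chain, draw) bool
    accept_stat: np.ndarray = field(default=None)
    tree_depth: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        c, d = self.beta.shape[:2]
        if self.beta.shape != (c, d, 4, 5) or self.sigma.shape != (c, d, 4):
            raise InferenceError("inconsistent draw array shapes")
        if self.z.shape[:2] != (c, d) or self.z.shape[3] != 4:
            raise InferenceError("inconsistent z array shape")
        if self.divergent is None:
            object.__setattr__(self, "divergent",
                               np.zeros((c, d), dtype=bool))

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.z.shape[2]

    def coef_draws(self, param: str, coef: str) -> np.ndarray:
        """(chain, draw) draws of one group-level coefficient."""
        return self.beta[:, :, PARAM_NAMES.index(param),
                         COEF_NAMES.index(coef)]

    def gamma(self) -> np.ndarray:
        """(chain, draw, subject, param) latent person-level parameters."""
        mu = np.einsum("sk,cdpk->cdsp", self.X, self.beta)
        return mu + self.z * self.sigma[:, :, None, :]

    def person_params(self) -> np.ndarray:
        """(chain, draw, subject, param) native-scale parameters."""
        from scipy.special import ndtr
        g = self.gamma()
        g[..., :2] = ndtr(g[..., :2])
        return g

    def to_inference_data(self, include_z: bool = True):
        """ArviZ InferenceData with named dims for diagnostics/summaries."""
        import arviz as az
        posterior = {"beta": self.beta, "sigma": self.sigma}
        dims = {"beta": ["param", "coef"], "sigma": ["param"]}
        coords = {"param": list(PARAM_NAMES), "coef": list(COEF_NAMES),
                  "subject": list(self.subject_ids)}
        if include_z:
            posterior["z"] = self.z
            dims["z"] = ["subject", "param"]
        sample_stats = {"diverging": self.divergent}
        return az.from_dict(posterior=posterior, sample_stats=sample_stats,
                            dims=dims, coords=coords)

    @classmethod
    def from_point(cls, coeffs: GroupCoefficients, effects: SubjectEffects,
                   X: np.ndarray, subject_ids: Sequence[str],
                   n_draws: int = 2, n_chains: int = 1) -> "PosteriorDraws":
        """A point-mass 'posterior' (every draw identical) — used to probe
        predictive calibration at known parameters."""
        c, d = n_chains, n_draws
        beta = np.broadcast_to(coeffs.beta, (c, d, 4, 5)).copy()
        sigma = np.broadcast_to(
            np.maximum(coeffs.sigma, 1e-12), (c, d, 4)).copy()
        z = np.broadcast_to(effects.z, (c, d) + effects.z.shape).copy()
        return cls(beta, sigma, z, np.asarray(X, dtype=float),
                   tuple(subject_ids))


def fit(cohort: CohortData, config: SamplerConfig,
        outcome_scale: float = OUTCOME_SCALE) -> PosteriorDraws:
    """Sample the joint posterior for a cohort.

    Runs ``config.n_chains`` NUTS chains over the unconstrained joint
    density (non-centered person effects, log-scale group SDs), discarding
    the warmup iterations.  Identical seed and inputs give identical draws.
    """
    if cohort.n_subjects == 0:
        raise InferenceError("cannot fit an empty cohort")
    posterior = ORLPosterior(cohort.behavior, cohort.covariates,
                             outcome_scale)
    n_keep = config.n_iterations - config.n_warmup
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)

    chains = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        last_err: Exception | None = None
        for _ in range(10):  # retry fresh initial points if density is -inf
            x0 = posterior.initial_point(rng)
            try:
                res = nuts.sample_chain(
                    posterior.logp_and_grad, x0, n_keep, config.n_warmup,
                    rng, config.target_accept, config.max_treedepth)
                break
            except nuts.SamplerError as err:
                last_err = err
        else:
            raise InferenceError(
                f"chain {c}: no finite initial density after 10 tries"
            ) from last_err
        chains.append(res)

    n = posterior.n_subjects
    beta = np.empty((config.n_chains, n_keep, 4, 5))
    sigma = np.empty((config.n_chains, n_keep, 4))
    z = np.empty((config.n_chains, n_keep, n, 4))
    divergent = np.empty((config.n_chains, n_keep), dtype=bool)
    accept = np.empty((config.n_chains, n_keep))
    depth = np.empty((config.n_chains, n_keep), dtype=np.int64)
    for c, res in enumerate(chains):
        for k in range(n_keep):
            b, s, zz = posterior.unpack(res.draws[k])
            beta[c, k] = b
            sigma[c, k] = np.exp(s)
            z[c, k] = zz
        divergent[c] = res.divergent
        accept[c] = res.accept_stat
        depth[c] = res.tree_depth
    return PosteriorDraws(beta, sigma, z, posterior.X, cohort.subject_ids,
                          divergent, accept, depth)


@dataclass(frozen=True)
class ConvergenceReport:
    """Split R-hat / ESS per stored quantity plus the divergence count."""

    table: pd.DataFrame  #: columns quantity, rhat, ess
    n_divergent: int
    n_total_draws: int

    @property
    def max_rhat(self) -> float:
        return float(self.table["rhat"].max())

    @property
    def flagged(self) -> list[str]:
        """Quantities whose split R-hat reaches the 1.1 criterion."""
        bad = self.table[self.table["rhat"] >= 1.1]
        return list(bad["quantity"])

    @property
    def converged(self) -> bool:
        return not self.flagged


def convergence_report(draws: PosteriorDraws) -> ConvergenceReport:
    """Rank-normalized split R-hat and bulk ESS for every stored quantity."""
    import arviz as az
    if draws.n_chains < 2:
        raise InferenceError("convergence diagnostics need at least 2 chains")
    if draws.n_draws == 0:
        raise InferenceError("no draws to diagnose")
    idata = draws.to_inference_data(include_z=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata, method="rank")
        ess = az.ess(idata, method="bulk")
    rows = []
    for var in ("beta", "sigma", "z"):
        r = np.asarray(rhat[var]).reshape(-1)
        e = np.asarray(ess[var]).reshape(-1)
        labels = _flat_labels(var, rhat[var].shape, draws)
        for lab, rv, ev in zip(labels, r, e):
            rows.append({"quantity": lab, "rhat": float(rv), "ess": float(ev)})
    table = pd.DataFrame(rows)
    return ConvergenceReport(table, int(draws.divergent.sum()),
                             int(draws.divergent.size))


def _flat_labels(var: str, shape: tuple[int, ...],
                 draws: PosteriorDraws) -> list[str]:
    if var == "beta":
        return [f"beta[{p},{c}]" for p in PARAM_NAMES for c in COEF_NAMES]
    if var == "sigma":
        return [f"sigma[{p}]" for p in PARAM_NAMES]
    return [f"z[{s},{p}]" for s in draws.subject_ids for p in PARAM_NAMES]


def _presentation_blocks(schedule, block_size: int) -> np.ndarray:
    """Per-trial block index from per-deck presentation order."""
    counts = {d: 0 for d in DECK_LABELS}
    block = np.empty(schedule.n_trials, dtype=np.int64)
    for t, deck in enumerate(schedule.presented_deck):
        block[t] = counts[deck] // block_size
        counts[deck] += 1
    return block


def _group_masks(cohort: CohortData,
                 group_by: str | None) -> dict[str, np.ndarray]:
    n = cohort.n_subjects
    if group_by is None:
        return {"all": np.ones(n, dtype=bool)}
    vals = np.array([getattr(c, group_by) for c in cohort.covariates])
    return {f"{group_by}=1": vals == 1, f"{group_by}=0": vals == 0}


def posterior_predictive(
    draws: PosteriorDraws,
    cohort: CohortData,
    n_reps: int,
    seed: int,
    block_size: int = 10,
    group_by: str | None = None,
    outcome_scale: float = OUTCOME_SCALE,
) -> pd.DataFrame:
    """Predictive play-proportion bands against the observed curves.

    For each of ``n_reps`` posterior draws the whole cohort's behaviour is
    re-simulated on its task schedule; play proportions are tallied per
    group x deck x block (blocks of ``block_size`` per-deck presentations)
    and summarized as the predictive mean with 50% and 95% central
    intervals.  Returns a tidy frame with the observed proportion per cell.
    """
    if n_reps < 2:
        raise InferenceError("n_reps must be at least 2")
    if draws.n_subjects != cohort.n_subjects:
        raise InferenceError("draws and cohort subject counts differ")
    n_cards = len(next(iter(cohort.sequences.values())).outcomes)
    if n_cards % block_size != 0:
        raise InferenceError(
            f"block_size {block_size} does not divide the {n_cards}-card decks")

    rng = np.random.default_rng(seed)
    deck_idx = np.array([DECK_LABELS.index(d)
                         for d in cohort.schedule.presented_deck],
                        dtype=np.int64)
    seq = np.stack([np.array(cohort.sequences[d].outcomes) / outcome_scale
                    for d in DECK_LABELS])
    block = _presentation_blocks(cohort.schedule, block_size)
    n_blocks = n_cards // block_size
    masks = _group_masks(cohort, group_by)

    # observed play matrix (timeouts are passes, already choice 0)
    n, T = cohort.n_subjects, cohort.schedule.n_trials
    observed = np.zeros((n, T))
    for i, subj in enumerate(cohort.behavior):
        observed[i] = [rec.choice for rec in subj.trials]

    flat = [(c, d) for c in range(draws.n_chains)
            for d in range(draws.n_draws)]
    pick = rng.choice(len(flat), size=n_reps,
                      replace=len(flat) < n_reps)
    native_all = draws.person_params()

    def cell_means(play: np.ndarray) -> np.ndarray:
        out = np.empty((len(masks), 4, n_blocks))
        for gi, mask in enumerate(masks.values()):
            sub = play[mask]
            for j in range(4):
                for b in range(n_blocks):
                    cols = (deck_idx == j) & (block == b)
                    out[gi, j, b] = sub[:, cols].mean() if sub.size else np.nan
        return out

    sim_cells = np.empty((n_reps, len(masks), 4, n_blocks))
    for r, k in enumerate(pick):
        c, d = flat[k]
        params = np.ascontiguousarray(native_all[c, d])
        u_choice = rng.random((n, T))
        u_timeout = rng.random((n, T))
        choices, _, _ = simulate_choices(deck_idx, seq, params,
                                         u_choice, u_timeout, 0.0)
        sim_cells[r] = cell_means(choices.astype(float))

    obs_cells = cell_means(observed)
    rows = []
    for gi, gname in enumerate(masks):
        for j, deck in enumerate(DECK_LABELS):
            for b in range(n_blocks):
                s = sim_cells[:, gi, j, b]
                rows.append({
                    "group": gname, "deck": deck, "block": b + 1,
                    "observed": obs_cells[gi, j, b],
                    "predicted_mean": float(np.mean(s)),
                    "lo50": float(np.quantile(s, 0.25)),
                    "hi50": float(np.quantile(s, 0.75)),
                    "lo95": float(np.quantile(s, 0.025)),
                    "hi95": float(np.quantile(s, 0.975)),
                })
    return pd.DataFrame(rows)


def save_draws(draws: PosteriorDraws, path) -> None:
    """Persist draws to a compressed array container (chain x draw indexed)."""
    np.savez_compressed(
        path, beta=draws.beta, sigma=draws.sigma, z=draws.z, X=draws.X,
        subject_ids=np.array(draws.subject_ids), divergent=draws.divergent,
        accept_stat=draws.accept_stat if draws.accept_stat is not None
        else np.zeros(0),
        tree_depth=draws.tree_depth if draws.tree_depth is not None
        else np.zeros(0, dtype=np.int64))


def load_draws(path) -> PosteriorDraws:
    with np.load(path, allow_pickle=False) as f:
        accept = f["accept_stat"] if f["accept_stat"].size else None
        depth = f["tree_depth"] if f["tree_depth"].size else None
        return PosteriorDraws(
            f["beta"], f["sigma"], f["z"], f["X"],
            tuple(str(s) for s in f["subject_ids"]),
            f["divergent"], accept, depth)


@dataclass(frozen=True)
class RecoveryReport:
    """Coefficient-level and person-level recovery diagnostics."""

    coefficients: pd.DataFrame  #: true, posterior mean, bias, CI, covered
    person_correlation: dict[str, float]  #: true-vs-posterior-mean r by param
    draws: PosteriorDraws


def parameter_recovery(
    true_coeffs: GroupCoefficients,
    cohort_size: int,
    config: SamplerConfig,
    seed: int,
    spec: CohortSpec | None = None,
) -> RecoveryReport:
    """Simulate at known coefficients, refit, and score the recovery."""
    ss = np.random.SeedSequence(seed).generate_state(4)
    base = spec if spec is not None else CohortSpec(n_subjects=cohort_size)
    base = replace(base, n_subjects=cohort_size, true_coeffs=true_coeffs,
                   covariate_seed=int(ss[0] % 2 ** 31),
                   parameter_seed=int(ss[1] % 2 ** 31),
                   behavior_seed=int(ss[2] % 2 ** 31))
    cohort = generate_cohort(base)
    draws = fit(cohort, replace(config, seed=int(ss[3] % 2 ** 31)))

    rows = []
    for pi, p in enumerate(PARAM_NAMES):
        for ci, c in enumerate(COEF_NAMES):
            post = draws.beta[:, :, pi, ci].reshape(-1)
            truth = float(true_coeffs.beta[pi, ci])
            lo, hi = np.quantile(post, [0.025, 0.975])
            rows.append({
                "param": p, "coef": c, "true": truth,
                "posterior_mean": float(post.mean()),
                "bias": float(post.mean() - truth),
                "lo95": float(lo), "hi95": float(hi),
                "covered": bool(lo <= truth <= hi),
            })
    coefficients = pd.DataFrame(rows)

    true_native = np.array([p.as_array() for p in cohort.true_params])
    est_native = draws.person_params().mean(axis=(0, 1))
    person_corr = {}
    for pi, p in enumerate(PARAM_NAMES):
        person_corr[p] = float(np.corrcoef(true_native[:, pi],
                                           est_native[:, pi])[0, 1])
    return RecoveryReport(coefficients, person_corr, draws)
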