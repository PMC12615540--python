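"""Result surfaces: coefficient tables, contrasts, block play proportions.

Summaries mirror how this class of hierarchical Bayesian task analyses is
reported: posterior means with 95% central credible intervals per group
coefficient (latent scale for the probit-parameterized learning rates), a
significance flag when the interval excludes zero, the proportion of
posterior mass above zero, presence-vs-absence contrasts per diagnosis,
block-wise play proportions, and a dyad-sensitivity subsetting utility
that removes one member of each parent pair.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortData
from .decks import DECK_LABELS
from .hierarchy import COEF_NAMES, PARAM_NAMES
from .inference import InferenceError, PosteriorDraws, _presentation_blocks


class ReportingError(ValueError):
    """Raised for malformed report inputs."""


def _summary_row(samples: np.ndarray, interval: str) -> dict:
    samples = np.asarray(samples, dtype=float).reshape(-1)
    if interval == "quantile":
        lo, hi = np.quantile(samples, [0.025, 0.975])
    elif interval == "hdi":
        import arviz as az
        lo, hi = az.hdi(samples, hdi_prob=0.95)
    else:
        raise ReportingError(f"unknown interval type {interval!r}")
    return {
        "mean": float(samples.mean()),
        "lo95": float(lo),
        "hi95": float(hi),
        "significant": bool(lo > 0 or hi < 0),
        "p_gt_0": float(np.mean(samples > 0)),
    }


def summarize_posterior(draws: PosteriorDraws,
                        interval: str = "quantile") -> pd.DataFrame:
    """One row per (model parameter x group coefficient).

    Columns: posterior mean, 95% central interval (or HDI), a flag set when
    the interval excludes 0, and the proportion of mass above 0.  Group-SD
    rows are appended with the flag left unset (an SD is positive by
    construction).
    """
    if draws.n_draws == 0:
        raise InferenceError("empty draws")
    rows = []
    for pi, p in enumerate(PARAM_NAMES):
        for ci, c in enumerate(COEF_NAMES):
            row = {"param": p, "coef": c}
            row.update(_summary_row(draws.beta[:, :, pi, ci], interval))
            rows.append(row)
    for pi, p in enumerate(PARAM_NAMES):
        row = {"param": p, "coef": "sigma"}
        row.update(_summary_row(draws.sigma[:, :, pi], interval))
        row["significant"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def group_contrasts(draws: PosteriorDraws,
                    interval: str = "quantile") -> pd.DataFrame:
    """Posterior of (group with history) - (group without), per indicator.

    With binary indicators entering the group mean linearly, each contrast's
    posterior is computed draw-by-draw as the difference of the two group
    means and therefore coincides with the coefficient's own posterior.
    """
    if draws.n_draws == 0:
        raise InferenceError("empty draws")
    rows = []
    for pi, p in enumerate(PARAM_NAMES):
        for ci, c in enumerate(COEF_NAMES[1:], start=1):
            base = draws.beta[:, :, pi, 0]
            with_flag = base + draws.beta[:, :, pi, ci]
            diff = with_flag - base
            row = {"param": p, "contrast": f"{c}: present - absent"}
            row.update(_summary_row(diff, interval))
            rows.append(row)
    return pd.DataFrame(rows)


def block_play_proportions(
    cohort: CohortData,
    block_size: int = 10,
    group_by: str | None = None,
) -> pd.DataFrame:
    """Mean play proportion per group x deck x block, plus block differences.

    Blocks are counted in per-deck presentations (presentations 1..10 of a
    deck form its block 1, and so on), matching how learning curves on this
    task are read.  Timeouts count as passes.  Returns one row per cell with
    a ``last_minus_first`` column repeated within each (group, deck).
    """
    n_cards = len(next(iter(cohort.sequences.values())).outcomes)
    if block_size <= 0 or n_cards % block_size != 0:
        raise ReportingError(
            f"block_size {block_size} does not divide the {n_cards}-card decks")
    block = _presentation_blocks(cohort.schedule, block_size)
    deck_idx = np.array([DECK_LABELS.index(d)
                         for d in cohort.schedule.presented_deck])
    n_blocks = n_cards // block_size

    if group_by is None:
        groups = {"all": np.ones(cohort.n_subjects, dtype=bool)}
    else:
        vals = np.array([getattr(c, group_by) for c in cohort.covariates])
        groups = {f"{group_by}=1": vals == 1, f"{group_by}=0": vals == 0}

    play = np.array([[rec.choice for rec in s.trials]
                     for s in cohort.behavior], dtype=float)
    rows = []
    for gname, mask in groups.items():
        sub = play[mask]
        for j, deck in enumerate(DECK_LABELS):
            props = []
            for b in range(n_blocks):
                cols = (deck_idx == j) & (block == b)
                props.append(float(sub[:, cols].mean()) if sub.size else np.nan)
            for b in range(n_blocks):
                rows.append({
                    "group": gname, "deck": deck, "block": b + 1,
                    "play_proportion": props[b],
                    "last_minus_first": props[-1] - props[0],
                })
    return pd.DataFrame(rows)


def drop_dyad_members(cohort: CohortData, seed: int) -> CohortData:
    """Remove one uniformly chosen member of each complete dyad.

    Subjects without a dyad partner (no ``dyad_id`` or a partner not in the
    cohort) are kept.  Used for the sensitivity analysis probing
    non-independence of parent pairs.
    """
    rng = np.random.default_rng(seed)
    members: dict[str, list[int]] = {}
    for i, cov in enumerate(cohort.covariates):
        if cov.dyad_id is not None:
            members.setdefault(cov.dyad_id, []).append(i)
    drop: set[int] = set()
    for dyad_id, idx in sorted(members.items()):
        if len(idx) > 2:
            raise ReportingError(f"dyad {dyad_id!r} has {len(idx)} members")
        if len(idx) == 2:
            drop.add(idx[rng.integers(2)])
    keep = [i for i in range(cohort.n_subjects) if i not in drop]
    true_params = (tuple(cohort.true_params[i] for i in keep)
                   if cohort.true_params is not None else None)
    return CohortData(
        tuple(cohort.covariates[i] for i in keep),
        tuple(cohort.behavior[i] for i in keep),
        true_params, cohort.schedule, cohort.sequences)
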