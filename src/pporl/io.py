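"""Plain-table persistence of cohorts (trials, covariates, ground truth).

Trial table (long format, one row per trial):
    subject_id, trial, deck, choice, outcome, timeout
with ``outcome`` blank on pass trials.  Covariate table (one row per
subject): subject_id, anxiety, depression, sud, sex, dyad_id (blank
allowed).  An optional truth table carries each synthetic subject's
generating parameters for recovery scoring.  Schemas are validated with
explicit error messages; a write/read round-trip is lossless.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortData, task_components
from .hierarchy import SubjectCovariates
from .orl import ORLParams, SubjectData, TrialRecord

TRIAL_COLUMNS = ("subject_id", "trial", "deck", "choice", "outcome", "timeout")
COVARIATE_COLUMNS = ("subject_id", "anxiety", "depression", "sud", "sex",
                     "dyad_id")
TRUTH_COLUMNS = ("subject_id", "a_rew", "a_pun", "beta_f", "beta_b")


class CohortIOError(ValueError):
    """Raised for schema violations in cohort tables."""


def cohort_to_frames(cohort: CohortData
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """(trials, covariates, truth-or-None) frames for a cohort."""
    trial_rows = []
    for subj in cohort.behavior:
        for rec in subj.trials:
            trial_rows.append({
                "subject_id": subj.subject_id, "trial": rec.trial,
                "deck": rec.deck, "choice": rec.choice,
                "outcome": rec.outcome if rec.choice == 1 else np.nan,
                "timeout": int(rec.timeout),
            })
    trials = pd.DataFrame(trial_rows, columns=list(TRIAL_COLUMNS))

    cov_rows = []
    for sid, cov in zip(cohort.subject_ids, cohort.covariates):
        cov_rows.append({
            "subject_id": sid, "anxiety": cov.anxiety,
            "depression": cov.depression, "sud": cov.sud, "sex": cov.sex,
            "dyad_id": cov.dyad_id if cov.dyad_id is not None else "",
        })
    covariates = pd.DataFrame(cov_rows, columns=list(COVARIATE_COLUMNS))

    truth = None
    if cohort.true_params is not None:
        truth = pd.DataFrame(
            [{"subject_id": sid, "a_rew": p.a_rew, "a_pun": p.a_pun,
              "beta_f": p.beta_f, "beta_b": p.beta_b}
             for sid, p in zip(cohort.subject_ids, cohort.true_params)],
            columns=list(TRUTH_COLUMNS))
    return trials, covariates, truth


def write_cohort(cohort: CohortData, trials_path: str | Path,
                 covariates_path: str | Path,
                 truth_path: str | Path | None = None) -> None:
    """Write a cohort to CSV tables (truth table only when ground truth exists)."""
    trials, covariates, truth = cohort_to_frames(cohort)
    # %.17g keeps float64 values exactly round-trippable through text
    trials.to_csv(trials_path, index=False, float_format="%.17g")
    covariates.to_csv(covariates_path, index=False)
    if truth_path is not None and truth is not None:
        truth.to_csv(truth_path, index=False, float_format="%.17g")


def _require_columns(df: pd.DataFrame, required: Sequence[str],
                     what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortIOError(
            f"{what} table is missing column(s): {', '.join(missing)}")


def frames_to_cohort(trials: pd.DataFrame, covariates: pd.DataFrame,
                     truth: pd.DataFrame | None = None,
                     schedule_seed: int | None = None) -> CohortData:
    """Validate and assemble tables into a :class:`CohortData`.

    ``schedule_seed`` must match the seed the cohort's task was built with
    (``None`` = the canonical order); the deck-presentation order in the
    trial table is checked against it.
    """
    _require_columns(trials, TRIAL_COLUMNS[:5], "trial")
    _require_columns(covariates, COVARIATE_COLUMNS[:5], "covariate")

    dup = trials.duplicated(subset=["subject_id", "trial"])
    if dup.any():
        keys = trials.loc[dup, ["subject_id", "trial"]].to_records(index=False)
        raise CohortIOError(f"duplicated (subject, trial) keys: {list(keys)[:5]}")

    for col in ("anxiety", "depression", "sud", "sex"):
        bad = ~covariates[col].isin([0, 1])
        if bad.any():
            raise CohortIOError(
                f"non-binary values in covariate column {col!r}: "
                f"rows {list(covariates.index[bad])[:5]}")

    pass_with_outcome = (trials["choice"] == 0) & trials["outcome"].notna()
    if pass_with_outcome.any():
        raise CohortIOError(
            "outcome recorded on pass rows: "
            f"{[(r.subject_id, int(r.trial)) for r in trials[pass_with_outcome].itertuples()][:5]}")
    play_without = (trials["choice"] == 1) & trials["outcome"].isna()
    if play_without.any():
        raise CohortIOError(
            "missing outcome on play rows: "
            f"{[(r.subject_id, int(r.trial)) for r in trials[play_without].itertuples()][:5]}")

    cov_by_id: dict[str, SubjectCovariates] = {}
    for r in covariates.itertuples():
        dyad = getattr(r, "dyad_id", "") if "dyad_id" in covariates else ""
        dyad = None if (pd.isna(dyad) or dyad == "") else str(dyad)
        cov_by_id[str(r.subject_id)] = SubjectCovariates(
            int(r.anxiety), int(r.depression), int(r.sud), int(r.sex), dyad)

    has_timeout = "timeout" in trials.columns
    behavior, cov_list = [], []
    for sid, grp in trials.groupby("subject_id", sort=False):
        sid = str(sid)
        if sid not in cov_by_id:
            raise CohortIOError(f"subject {sid} has trials but no covariate row")
        grp = grp.sort_values("trial")
        recs = tuple(
            TrialRecord(
                int(r.trial), str(r.deck), int(r.choice),
                float(r.outcome) if int(r.choice) == 1 else None,
                bool(int(r.timeout)) if has_timeout and not pd.isna(r.timeout)
                else False)
            for r in grp.itertuples())
        behavior.append(SubjectData(sid, recs))
        cov_list.append(cov_by_id[sid])

    _, schedule, sequences = task_components(schedule_seed)
    for subj in behavior:
        decks = tuple(rec.deck for rec in subj.trials)
        if decks != schedule.presented_deck:
            raise CohortIOError(
                f"subject {subj.subject_id}: deck order does not match the "
                "task schedule (wrong schedule_seed?)")

    true_params = None
    if truth is not None:
        _require_columns(truth, TRUTH_COLUMNS, "truth")
        by_id = {str(r.subject_id):
                 ORLParams(r.a_rew, r.a_pun, r.beta_f, r.beta_b)
                 for r in truth.itertuples()}
        true_params = tuple(by_id[s.subject_id] for s in behavior)

    return CohortData(tuple(cov_list), tuple(behavior), true_params,
                      schedule, sequences)


def read_cohort(trials_path: str | Path, covariates_path: str | Path,
                truth_path: str | Path | None = None,
                schedule_seed: int | None = None) -> CohortData:
    """Read a cohort back from CSV tables written by :func:`write_cohort`."""
    trials = pd.read_csv(trials_path, float_precision="round_trip")
    covariates = pd.read_csv(covariates_path,
                             dtype={"dyad_id": str}, keep_default_na=True)
    truth = (pd.read_csv(truth_path, float_precision="round_trip")
             if truth_path is not None else None)
    return frames_to_cohort(trials, covariates, truth, schedule_seed)
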