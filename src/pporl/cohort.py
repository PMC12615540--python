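"""Synthetic cohorts with study-like covariate structure and PP-ORL behaviour.

The generator emulates the cohort the analysis pipeline expects without any
external data: lifetime anxiety / depression / substance-use-disorder
indicators drawn jointly from an 8-cell comorbidity distribution (the three
diagnoses are strongly dependent, so independent coin flips would
misrepresent the cohort), a ~74% female sample containing opposite-sex
parent dyads, person-level model parameters drawn from the group-level
hierarchy, and full play-or-pass behaviour simulated on the four-deck task.

Ground-truth group coefficients default to :data:`STUDY_COEFFS`, a
study-like effect pattern (e.g. anxiety raising the punishment learning
rate on the probit scale, women showing lower punishment learning and
response bias), so generated cohorts behave like the population of interest
out of the box.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .decks import (DeckSpec, OutcomeSequence, TaskSchedule, build_deck_specs,
                    build_trial_schedule, generate_payout_sequence)
from .hierarchy import (GroupCoefficients, SubjectCovariates, design_matrix,
                        person_parameters, HierarchyError)
from .orl import ORLParams, SubjectData, simulate_agent

#: (anxiety, depression, sud) -> cohort count, the observed 8-cell
#: comorbidity table of the 293-parent study population.
DIAGNOSIS_COMBO_COUNTS: dict[tuple[int, int, int], int] = {
    (1, 0, 0): 33,
    (1, 1, 0): 28,
    (0, 1, 0): 23,
    (1, 0, 1): 6,
    (0, 1, 1): 15,
    (0, 0, 1): 38,
    (1, 1, 1): 26,
    (0, 0, 0): 124,
}

_N_STUDY = sum(DIAGNOSIS_COMBO_COUNTS.values())  # 293

#: study-like group-level coefficients (latent scale) and group SDs.
#: The SDs are field-typical hierarchical spreads; see docs/methods.md.
STUDY_COEFFS = GroupCoefficients(
    beta=np.array([
        # b0,   anx,   dep,   sud,   sex
        [-1.20, 0.10, -0.04, -0.07, -0.03],   # a_rew (probit scale)
        [-1.32, 0.15, -0.05, -0.07, -0.17],   # a_pun (probit scale)
        [3.11, 0.00, 0.94, 0.09, -0.06],      # beta_f
        [1.22, 0.20, 0.01, -0.08, -0.30],     # beta_b
    ]),
    sigma=np.array([0.45, 0.45, 1.20, 0.65]),
)


class CohortError(ValueError):
    """Raised for inconsistent cohort specifications."""


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one cohort reproducibly."""

    n_subjects: int
    combo_probs: Mapping[tuple[int, int, int], float] = field(
        default_factory=lambda: {k: v / _N_STUDY
                                 for k, v in DIAGNOSIS_COMBO_COUNTS.items()})
    female_fraction: float = 216 / _N_STUDY
    dyad_fraction: float = 134 / _N_STUDY  #: fraction of subjects in a dyad
    true_coeffs: GroupCoefficients = STUDY_COEFFS
    dyad_param_corr: float = 0.0  #: within-dyad correlation of person effects
    covariate_seed: int = 11
    parameter_seed: int = 12
    behavior_seed: int = 13
    schedule_seed: int | None = None  #: None = canonical card/deck order
    timeout_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise CohortError("n_subjects must be non-negative")
        probs = np.array(list(self.combo_probs.values()), dtype=float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise CohortError(
                "comorbidity combination probabilities must be non-negative "
                f"and sum to 1 (sum = {probs.sum():.6f})")
        for name in ("female_fraction", "dyad_fraction", "timeout_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CohortError(f"{name} must lie in [0, 1], got {v}")
        if not -1.0 < self.dyad_param_corr < 1.0:
            raise CohortError("dyad_param_corr must lie in (-1, 1)")

    @property
    def prevalence(self) -> dict[str, float]:
        """Marginal lifetime prevalences implied by the combination table."""
        out = {"anxiety": 0.0, "depression": 0.0, "sud": 0.0}
        for (a, d, s), p in self.combo_probs.items():
            out["anxiety"] += a * p
            out["depression"] += d * p
            out["sud"] += s * p
        return out


@dataclass(frozen=True)
class CohortData:
    """Covariates, behaviour, and (for synthetic cohorts) ground truth."""

    covariates: tuple[SubjectCovariates, ...]
    behavior: tuple[SubjectData, ...]
    true_params: tuple[ORLParams, ...] | None
    schedule: TaskSchedule
    sequences: Mapping[str, OutcomeSequence]

    def __post_init__(self) -> None:
        if len(self.covariates) != len(self.behavior):
            raise CohortError("covariates and behavior lengths differ")
        if self.true_params is not None and \
                len(self.true_params) != len(self.behavior):
            raise CohortError("true_params length differs from behavior")

    @property
    def n_subjects(self) -> int:
        return len(self.behavior)

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(s.subject_id for s in self.behavior)


def generate_covariates(spec: CohortSpec,
                        seed: int | None = None) -> list[SubjectCovariates]:
    """Draw diagnosis/sex indicators and dyad structure for a cohort.

    Diagnoses come i.i.d. from the joint 8-cell comorbidity distribution.
    Dyads are opposite-sex pairs sharing a ``dyad_id``; the sex of the
    remaining singleton subjects is drawn so the cohort-wide female
    fraction matches the spec in expectation.
    """
    rng = np.random.default_rng(spec.covariate_seed if seed is None else seed)
    n = spec.n_subjects
    if n == 0:
        return []

    combos = list(spec.combo_probs.keys())
    probs = np.array([spec.combo_probs[c] for c in combos], dtype=float)
    probs = probs / probs.sum()
    combo_idx = rng.choice(len(combos), size=n, p=probs)

    n_dyads = int(round(spec.dyad_fraction * n)) // 2
    order = rng.permutation(n)
    dyad_of = {}
    sex = np.zeros(n, dtype=int)
    for d in range(n_dyads):
        i, j = order[2 * d], order[2 * d + 1]
        dyad_of[i] = dyad_of[j] = f"dyad{d + 1:04d}"
        # each dyad contributes exactly one female; which member is random
        if rng.random() < 0.5:
            sex[i], sex[j] = 1, 0
        else:
            sex[i], sex[j] = 0, 1
    singles = order[2 * n_dyads:]
    if len(singles) > 0:
        p_female = (spec.female_fraction * n - n_dyads) / len(singles)
        p_female = float(np.clip(p_female, 0.0, 1.0))
        sex[singles] = rng.random(len(singles)) < p_female

    out = []
    for i in range(n):
        a, d, s = combos[combo_idx[i]]
        out.append(SubjectCovariates(anxiety=a, depression=d, sud=s,
                                     sex=int(sex[i]),
                                     dyad_id=dyad_of.get(i)))
    return out


def generate_true_parameters(
    coeffs: GroupCoefficients,
    covariates: Sequence[SubjectCovariates],
    seed: int,
    dyad_param_corr: float = 0.0,
) -> tuple[list[ORLParams], np.ndarray]:
    """Draw each subject's ground-truth parameters from the hierarchy.

    Person effects are standard normal (correlated within dyads when
    ``dyad_param_corr`` is nonzero); gamma = mu + z*sigma with the probit
    transform on the learning rates.  ``sigma = 0`` collapses every subject
    onto its group mean.  Returns the native-scale parameters and the z
    draws used.
    """
    if np.any(coeffs.sigma < 0):
        raise HierarchyError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    n = len(covariates)
    z = rng.normal(size=(n, 4))
    if dyad_param_corr != 0.0:
        rho = dyad_param_corr
        seen: dict[str, int] = {}
        for i, cov in enumerate(covariates):
            if cov.dyad_id is None:
                continue
            if cov.dyad_id in seen:
                j = seen[cov.dyad_id]
                z[i] = rho * z[j] + np.sqrt(1 - rho ** 2) * z[i]
            else:
                seen[cov.dyad_id] = i
    X = design_matrix(covariates)
    native = person_parameters(coeffs, X, z)
    # clip pathological tail draws away from the open-interval bounds
    native[:, :2] = np.clip(native[:, :2], 1e-12, 1 - 1e-12)
    params = [ORLParams(*row) for row in native]
    return params, z


def task_components(schedule_seed: int | None = None
                    ) -> tuple[list[DeckSpec], TaskSchedule,
                               dict[str, OutcomeSequence]]:
    """Deck specs, trial schedule and card orders shared by a cohort."""
    specs = build_deck_specs()
    schedule = build_trial_schedule(specs, schedule_seed)
    sequences = {s.label: generate_payout_sequence(s, schedule_seed)
                 for s in specs}
    return specs, schedule, sequences


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Covariates + ground-truth parameters + simulated task behaviour."""
    _, schedule, sequences = task_components(spec.schedule_seed)
    covariates = generate_covariates(spec)
    params, _ = generate_true_parameters(
        spec.true_coeffs, covariates, spec.parameter_seed,
        spec.dyad_param_corr)
    child_seeds = np.random.SeedSequence(spec.behavior_seed).generate_state(
        max(spec.n_subjects, 1))
    behavior = []
    for i, p in enumerate(params):
        behavior.append(simulate_agent(
            p, schedule, sequences, seed=int(child_seeds[i] % (2 ** 31)),
            subject_id=f"S{i + 1:04d}", timeout_prob=spec.timeout_prob))
    return CohortData(tuple(covariates), tuple(behavior), tuple(params),
                      schedule, sequences)
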