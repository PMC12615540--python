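"""Group-level regression and priors over person-level PP-ORL parameters.

Each of the four model parameters gamma in {a_rew, a_pun, beta_f, beta_b}
is given, per participant i, a linear predictor on a latent scale

    mu_i = b0 + b_anx*X_anx + b_dep*X_dep + b_sud*X_sud + b_sex*X_sex
    gamma_i = mu_i + z_i * sigma          (non-centered: z_i ~ Normal(0,1))

so b0 is the male no-diagnosis reference and each coefficient is the unique
effect of that indicator holding the others fixed.  The learning rates are
mapped through the standard normal CDF into (0, 1); the two beta weights
stay on the identity scale.  Priors: Normal(0,1) on every coefficient,
Half-Normal(0,2) on the learning-rate group SDs, Half-Cauchy(0,1) on the
beta-weight group SDs.

:class:`ORLPosterior` packs everything into one unconstrained vector
(group SDs on the log scale, with the Jacobian term) and returns the joint
log density with its analytic gradient, which is what the NUTS sampler
consumes.  The forward-mode likelihood gradient comes from
:mod:`pporl._kernels`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import ndtr

from ._kernels import cohort_loglik_grad
from .orl import OUTCOME_SCALE, SubjectData, subject_arrays

PARAM_NAMES = ("a_rew", "a_pun", "beta_f", "beta_b")
COEF_NAMES = ("b0", "anx", "dep", "sud", "sex")
#: which parameters live on the probit (pre-CDF) latent scale
LEARNING_RATE_PARAMS = (0, 1)

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_HALF_NORMAL_SCALE = 2.0  # group-SD prior scale for the learning rates
_HALF_CAUCHY_SCALE = 1.0  # group-SD prior scale for beta_f / beta_b


class HierarchyError(ValueError):
    """Raised for invalid covariates, coefficients or latent states."""


@dataclass(frozen=True)
class SubjectCovariates:
    """Binary lifetime-diagnosis and sex indicators for one participant."""

    anxiety: int
    depression: int
    sud: int
    sex: int  #: 0 male (reference), 1 female
    dyad_id: str | None = None

    def __post_init__(self) -> None:
        for name in ("anxiety", "depression", "sud", "sex"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise HierarchyError(f"{name} indicator must be 0 or 1, got {v!r}")

    def design_row(self) -> np.ndarray:
        """[1, X_anx, X_dep, X_sud, X_sex] — the regression design row."""
        return np.array([1.0, self.anxiety, self.depression, self.sud, self.sex])


@dataclass(frozen=True)
class GroupCoefficients:
    """Regression coefficients and group SD for each of the four parameters.

    ``beta`` has shape (4 parameters, 5 coefficients) ordered as
    :data:`PARAM_NAMES` x :data:`COEF_NAMES`; ``sigma`` has shape (4,).
    """

    beta: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if beta.shape != (4, 5):
            raise HierarchyError(f"beta must be (4, 5), got {beta.shape}")
        if sigma.shape != (4,):
            raise HierarchyError(f"sigma must be (4,), got {sigma.shape}")
        # sigma = 0 is admitted as the degenerate (no-pooling-spread) hierarchy
        # used by simulators; densities and transforms that require sigma > 0
        # enforce it themselves.
        if not np.all(sigma >= 0) or not np.all(np.isfinite(sigma)):
            raise HierarchyError("group standard deviations must be finite and >= 0")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "sigma", sigma)

    def coef(self, param: str, name: str) -> float:
        return float(self.beta[PARAM_NAMES.index(param), COEF_NAMES.index(name)])

    @classmethod
    def from_dicts(cls, beta: dict[str, dict[str, float]],
                   sigma: dict[str, float]) -> "GroupCoefficients":
        b = np.array([[beta[p][c] for c in COEF_NAMES] for p in PARAM_NAMES])
        s = np.array([sigma[p] for p in PARAM_NAMES])
        return cls(b, s)


@dataclass(frozen=True)
class SubjectEffects:
    """Standardized person effects z, shape (n_subjects, 4)."""

    z: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[1] != 4:
            raise HierarchyError(f"z must be (n, 4), got {z.shape}")
        if not np.all(np.isfinite(z)):
            raise HierarchyError("person effects must be finite")
        object.__setattr__(self, "z", z)

    @property
    def n_subjects(self) -> int:
        return self.z.shape[0]


def design_matrix(covariates: Sequence[SubjectCovariates]) -> np.ndarray:
    """(n, 5) stacked design rows."""
    if len(covariates) == 0:
        return np.zeros((0, 5))
    return np.stack([c.design_row() for c in covariates])


def group_mean(coeffs: GroupCoefficients, cov: SubjectCovariates) -> np.ndarray:
    """Latent group mean mu for one subject, one entry per model parameter."""
    return coeffs.beta @ cov.design_row()


def person_parameter(mu: float, z: float, sigma: float, kind: str) -> float:
    """gamma = mu + z*sigma, probit-transformed for learning-rate kinds.

    ``kind`` is ``"learning_rate"`` (result in (0,1) via the standard normal
    CDF) or ``"unbounded"`` (identity).
    """
    if sigma <= 0:
        raise HierarchyError("sigma must be positive")
    gamma = mu + z * sigma
    if kind == "learning_rate":
        return float(ndtr(gamma))
    if kind == "unbounded":
        return float(gamma)
    raise HierarchyError(f"unknown parameter kind {kind!r}")


def person_parameters(coeffs: GroupCoefficients, X: np.ndarray,
                      z: np.ndarray) -> np.ndarray:
    """Native-scale (n, 4) parameter matrix for a whole cohort.

    Columns follow :data:`PARAM_NAMES`; the two learning rates pass through
    the normal CDF, beta_f and beta_b stay latent-scale.
    """
    gamma = X @ coeffs.beta.T + z * coeffs.sigma
    out = gamma.copy()
    out[:, LEARNING_RATE_PARAMS] = ndtr(gamma[:, LEARNING_RATE_PARAMS])
    return out


def _half_normal_logpdf(x: np.ndarray, scale: float) -> np.ndarray:
    return (math.log(2.0) - math.log(scale) - _LOG_SQRT_2PI
            - 0.5 * (x / scale) ** 2)

def _half_cauchy_logpdf(x: np.ndarray, scale: float) -> np.ndarray:
    return (math.log(2.0 / (math.pi * scale)) - np.log1p((x / scale) ** 2))


def log_prior(coeffs: GroupCoefficients, effects: SubjectEffects) -> float:
    """Joint log prior density on the constrained scale.

    Normal(0,1) on every regression coefficient and every z; Half-Normal(0,2)
    on the learning-rate group SDs; Half-Cauchy(0,1) on the beta-weight group
    SDs.  States with any sigma <= 0 are rejected with -inf.
    """
    if np.any(coeffs.sigma <= 0):
        return -math.inf
    lp = float(np.sum(-0.5 * coeffs.beta ** 2 - _LOG_SQRT_2PI))
    lp += float(np.sum(_half_normal_logpdf(coeffs.sigma[:2], _HALF_NORMAL_SCALE)))
    lp += float(np.sum(_half_cauchy_logpdf(coeffs.sigma[2:], _HALF_CAUCHY_SCALE)))
    lp += float(np.sum(-0.5 * effects.z ** 2 - _LOG_SQRT_2PI))
    return lp


def joint_log_posterior(
    behavior: Sequence[SubjectData],
    covariates: Sequence[SubjectCovariates],
    coeffs: GroupCoefficients,
    effects: SubjectEffects,
    outcome_scale: float = OUTCOME_SCALE,
) -> float:
    """log prior + summed subject log-likelihoods at the implied parameters."""
    if len(behavior) != len(covariates) or len(behavior) != effects.n_subjects:
        raise HierarchyError(
            f"dimension mismatch: {len(behavior)} subjects, "
            f"{len(covariates)} covariate rows, {effects.n_subjects} effect rows")
    lp = log_prior(coeffs, effects)
    if len(behavior) == 0:
        return lp
    deck, choice, outcome = stack_behavior(behavior, outcome_scale)
    X = design_matrix(covariates)
    params = person_parameters(coeffs, X, effects.z)
    ll, _ = cohort_loglik_grad(deck, choice, outcome, params)
    return lp + float(ll.sum())


def stack_behavior(behavior: Sequence[SubjectData],
                   outcome_scale: float = OUTCOME_SCALE
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack per-subject trial arrays; all subjects must share a trial count."""
    if len(behavior) == 0:
        return (np.zeros((0, 0), dtype=np.int64),
                np.zeros((0, 0), dtype=np.int64), np.zeros((0, 0)))
    arrays = [subject_arrays(s, outcome_scale) for s in behavior]
    lengths = {a[0].shape[0] for a in arrays}
    if len(lengths) > 1:
        raise HierarchyError(f"subjects have unequal trial counts: {sorted(lengths)}")
    deck = np.stack([a[0] for a in arrays])
    choice = np.stack([a[1] for a in arrays])
    outcome = np.stack([a[2] for a in arrays])
    return deck, choice, outcome


class ORLPosterior:
    """The joint posterior density on one unconstrained vector.

    Layout: 20 regression coefficients (4 params x 5, row-major), 4 log
    group SDs, then the (n, 4) person effects flattened row-major.  The log
    density includes the log-SD change-of-variables Jacobian, so the sampler
    works on an unconstrained space.
    """

    def __init__(self, behavior: Sequence[SubjectData],
                 covariates: Sequence[SubjectCovariates],
                 outcome_scale: float = OUTCOME_SCALE) -> None:
        if len(behavior) != len(covariates):
            raise HierarchyError("behavior and covariates lengths differ")
        self.n_subjects = len(behavior)
        self.X = design_matrix(covariates)
        self.deck, self.choice, self.outcome = stack_behavior(
            behavior, outcome_scale)

    @property
    def dim(self) -> int:
        return 24 + 4 * self.n_subjects

    def pack(self, beta: np.ndarray, log_sigma: np.ndarray,
             z: np.ndarray) -> np.ndarray:
        return np.concatenate([np.ravel(beta), np.ravel(log_sigma), np.ravel(z)])

    def unpack(self, x: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        beta = x[:20].reshape(4, 5)
        log_sigma = x[20:24]
        z = x[24:].reshape(self.n_subjects, 4)
        return beta, log_sigma, z

    def to_constrained(self, x: np.ndarray
                       ) -> tuple[GroupCoefficients, SubjectEffects]:
        beta, log_sigma, z = self.unpack(x)
        return GroupCoefficients(beta, np.exp(log_sigma)), SubjectEffects(z)

    def logp_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        beta, log_sigma, z = self.unpack(x)
        sigma = np.exp(log_sigma)

        # --- priors (+ Jacobian of sigma = exp(log_sigma)) ---
        lp = float(np.sum(-0.5 * beta ** 2 - _LOG_SQRT_2PI))
        lp += float(np.sum(_half_normal_logpdf(sigma[:2], _HALF_NORMAL_SCALE)))
        lp += float(np.sum(_half_cauchy_logpdf(sigma[2:], _HALF_CAUCHY_SCALE)))
        lp += float(np.sum(log_sigma))
        lp += float(np.sum(-0.5 * z ** 2 - _LOG_SQRT_2PI))

        g_beta = -beta.copy()
        g_log_sigma = np.ones(4)
        g_log_sigma[:2] += -(sigma[:2] / _HALF_NORMAL_SCALE) ** 2
        s2 = (sigma[2:] / _HALF_CAUCHY_SCALE) ** 2
        g_log_sigma[2:] += -2.0 * s2 / (1.0 + s2)
        g_z = -z.copy()

        # --- likelihood ---
        if self.n_subjects > 0:
            gamma = self.X @ beta.T + z * sigma
            native = gamma.copy()
            native[:, :2] = ndtr(gamma[:, :2])
            ll, g_native = cohort_loglik_grad(
                self.deck, self.choice, self.outcome, native)
            lp += float(ll.sum())
            d_gamma = g_native.copy()
            phi = np.exp(-0.5 * gamma[:, :2] ** 2) / math.sqrt(2.0 * math.pi)
            d_gamma[:, :2] *= phi
            g_beta += d_gamma.T @ self.X
            g_z += d_gamma * sigma
            g_log_sigma += np.sum(d_gamma * z, axis=0) * sigma

        grad = self.pack(g_beta, g_log_sigma, g_z)
        return lp, grad

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        """A dispersed but tame start: coefficients and z near 0, SDs near 0.4."""
        beta = rng.normal(0.0, 0.3, size=(4, 5))
        log_sigma = rng.normal(-1.0, 0.3, size=4)
        z = rng.normal(0.0, 0.3, size=(self.n_subjects, 4))
        return self.pack(beta, log_sigma, z)
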