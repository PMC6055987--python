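"""Comparator allocation procedures.

Alongside the Gittins-index rules the package implements the standard
covariate-adjusted response-adaptive (CARA) comparators for a binary
outcome under the per-arm logistic model  logit p_t(z) = alpha_t + beta_t z:

* equal randomization (ER);
* stratified permuted block design (SPBD);
* the estimate-driven CARA targets 1-4 (two-arm) and the heuristic
  multi-arm extensions of targets 1-2, all preceded by an ER burn-in and
  refreshed from maximum-likelihood estimates at block boundaries;
* Thompson sampling within covariate group, with the allocation
  probability raised to a stabilizing exponent c (default J / (2T)).

Targets 3 and 4 are written exactly as the simulation study uses them: the
control arm is weighted by the experimental arm's dispersion term (the
crossed orientation), which is what reproduces the study's allocation
proportions.  They are defined for two arms only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .bandit import JointState

__all__ = [
    "LogisticOutcomeModel",
    "TargetAllocation",
    "er_probabilities",
    "spbd_assign",
    "cara_target",
    "thompson_probabilities",
    "fit_outcome_model",
    "burn_in_schedule",
]


@dataclass
class LogisticOutcomeModel:
    """Per-arm logistic outcome model: logit p_t(z) = alpha_t + beta_t * z."""

    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.alpha.shape != self.beta.shape:
            raise ValueError("alpha and beta must have one entry per treatment")

    def success_probs(self, n_levels: int = 2) -> np.ndarray:
        """Success probability matrix p[z, t] for z = 0..n_levels-1."""
        z = np.arange(n_levels)[:, None]
        return expit(self.alpha[None, :] + self.beta[None, :] * z)


@dataclass
class TargetAllocation:
    """Per-covariate-level treatment allocation probabilities rho[z, t]."""

    rho: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.atleast_2d(np.asarray(self.rho, dtype=float))
        if np.any(self.rho < -1e-12):
            raise ValueError("allocation probabilities must be nonnegative")
        if np.any(np.abs(self.rho.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("allocation probabilities must sum to 1 per level")


def er_probabilities(n_treatments: int, n_levels: int = 1) -> TargetAllocation:
    """Equal randomization: probability 1/(T+1) per arm at every level."""
    if n_treatments < 1:
        raise ValueError("need at least one experimental treatment")
    rho = np.full((n_levels, n_treatments + 1), 1.0 / (n_treatments + 1))
    return TargetAllocation(rho)


def spbd_assign(
    block_counts: np.ndarray, m: int, rng: np.random.Generator
) -> int:
    """Next assignment of a stratified permuted block, given the within-block counts.

    ``block_counts[t]`` is the number of patients already assigned to
    treatment ``t`` inside the stratum's current permuted block of length
    ``m``.  Drawing a treatment with probability proportional to its
    remaining slots is distributionally identical to fixing a uniformly
    random permutation of the block up front.  A full block (all slots
    used) starts a new one.
    """
    block_counts = np.asarray(block_counts, dtype=int)
    n_arms = block_counts.size
    if m % n_arms != 0:
        raise ValueError(f"block length {m} not divisible by {n_arms} treatments")
    per_arm = m // n_arms
    if np.any(block_counts < 0) or np.any(block_counts > per_arm):
        raise ValueError("block_counts inconsistent with block length")
    remaining = per_arm - block_counts
    if remaining.sum() == 0:  # block complete: start a fresh one
        remaining = np.full(n_arms, per_arm)
    return int(rng.choice(n_arms, p=remaining / remaining.sum()))


def cara_target(variant: int, estimates: np.ndarray) -> TargetAllocation:
    """Estimate-driven CARA allocation targets.

    ``estimates[z, t]`` are success-probability estimates per covariate
    level and treatment (values in (0, 1)).  Writing q = 1 - p:

    * variant 1: rho_t ∝ p_t / q_t (odds-proportional, any number of arms);
    * variant 2: rho_t ∝ p_t (success-proportional, any number of arms);
    * variant 3: two arms, rho_0 = sqrt(p1 q1) / (sqrt(p0 q0) + sqrt(p1 q1))
      (control weighted by the experimental arm's standard deviation);
    * variant 4: two arms, rho_0 = sqrt(p1) q1 / (sqrt(p0) q0 + sqrt(p1) q1).

    Probabilities are normalized within each covariate level.
    """
    p = np.atleast_2d(np.asarray(estimates, dtype=float))
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("estimates must lie strictly in (0, 1)")
    q = 1.0 - p
    n_arms = p.shape[1]
    if variant == 1:
        w = p / q
    elif variant == 2:
        w = p
    elif variant in (3, 4):
        if n_arms != 2:
            raise ValueError(f"CARA target {variant} is defined for two arms only")
        if variant == 3:
            w_arm = np.sqrt(p * q)  # per-arm standard deviation
        else:
            w_arm = np.sqrt(p) * q
        w = w_arm[:, ::-1]  # crossed: each arm weighted by the other's term
    else:
        raise ValueError(f"unknown CARA target variant {variant}")
    return TargetAllocation(w / w.sum(axis=1, keepdims=True))


def thompson_probabilities(
    state: JointState,
    covariate_level: int,
    exponent_c: float,
    posterior_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Thompson-sampling allocation probabilities within one covariate group.

    Estimates, by Monte-Carlo draws from the Beta posteriors, the
    probability that each arm available at the covariate level has the
    largest response rate, raises it to the power ``c`` and renormalizes.
    ``c`` below 1 flattens the allocation (the block procedures use
    c = J / (2T)); ``c`` growing large concentrates it on the posterior
    modal arm.
    """
    if posterior_draws < 1:
        raise ValueError("posterior_draws must be >= 1")
    if exponent_c <= 0:
        raise ValueError("exponent must be positive")
    sl = state.arm_slice(covariate_level)
    draws = rng.beta(state.s[sl], state.f[sl], size=(posterior_draws, state.n_treatments + 1))
    wins = np.bincount(np.argmax(draws, axis=1), minlength=state.n_treatments + 1)
    pr_best = wins / posterior_draws
    if np.all(pr_best == 0):  # unreachable; argmax always selects one
        return np.full(state.n_treatments + 1, 1.0 / (state.n_treatments + 1))
    w = pr_best**exponent_c
    tot = w.sum()
    if tot == 0:  # all win probabilities zero after powering (extreme c)
        w = (pr_best == pr_best.max()).astype(float)
        tot = w.sum()
    return w / tot


def cell_counts(
    covariates: np.ndarray,
    treatments: np.ndarray,
    outcomes: np.ndarray,
    n_levels: int,
    n_treatments: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed (successes, totals) per (covariate level, treatment) cell."""
    idx = covariates * (n_treatments + 1) + treatments
    n_arms = n_levels * (n_treatments + 1)
    n = np.bincount(idx, minlength=n_arms).reshape(n_levels, n_treatments + 1)
    succ = np.bincount(idx, weights=outcomes, minlength=n_arms).reshape(
        n_levels, n_treatments + 1
    )
    return succ, n


def fit_outcome_model(
    covariates: np.ndarray,
    treatments: np.ndarray,
    outcomes: np.ndarray,
    n_levels: int = 2,
    n_treatments: int = 1,
):
    """Maximum-likelihood fit of the saturated per-arm logistic model.

    With a separate (alpha_t, beta_t) per arm the MLE of p_t(z) is the raw
    success proportion of cell (z, t).  Degenerate cells are flagged and
    regularized: empty cells fall back to 0.5, separated cells (all
    successes or all failures) get a +1/2 continuity correction so the
    estimates stay inside (0, 1).

    Returns ``(model, p_hat, estimable)`` where ``model`` is the
    ``LogisticOutcomeModel`` implied by the two covariate levels (binary
    covariate only, else None), ``p_hat[z, t]`` the regularized estimates
    and ``estimable[z, t]`` flags cells with data.
    """
    covariates = np.asarray(covariates, dtype=int)
    treatments = np.asarray(treatments, dtype=int)
    outcomes = np.asarray(outcomes, dtype=float)
    if covariates.size == 0:
        raise ValueError("history must be non-empty")
    succ, n = cell_counts(covariates, treatments, outcomes, n_levels, n_treatments)
    estimable = n > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hat = np.where(estimable, succ / np.where(n > 0, n, 1), 0.5)
    separated = estimable & ((p_hat <= 0.0) | (p_hat >= 1.0))
    p_hat = np.where(separated, (succ + 0.5) / (n + 1.0), p_hat)
    model = None
    if n_levels == 2:
        alpha = logit(p_hat[0])
        beta = logit(p_hat[1]) - alpha
        model = LogisticOutcomeModel(alpha, beta)
    return model, p_hat, estimable


def burn_in_schedule(n_patients: int, burn_in: int) -> np.ndarray:
    """Boolean mask: True where the patient is randomized by ER (burn-in).

    The first ``burn_in`` patients use equal randomization; afterwards the
    estimate-driven target applies, refreshed at block boundaries.
    """
    if not 0 <= burn_in <= n_patients:
        raise ValueError(f"burn-in {burn_in} must lie in [0, {n_patients}]")
    mask = np.zeros(n_patients, dtype=bool)
    mask[:burn_in] = True
    return mask
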