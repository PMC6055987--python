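"""Combination-arm bandit state and the deterministic CARA Gittins rule.

A trial with ``T`` experimental treatments, one control and a covariate
taking ``S`` values is reformulated as a classic bandit with ``S * (T + 1)``
independent "combination arms", one per (covariate level, treatment) pair.
A patient with covariate level ``z`` may only receive the ``T + 1`` arms at
that level; the deterministic CARA Gittins-index rule assigns the available
arm with the largest index.  Each arm keeps a conjugate Beta posterior that
only that arm's outcomes update, so covariates can be folded away and the
classic index machinery applies unchanged.

Multiple and polychotomous covariates are handled by flattening the
covariate vector into a single stratum label with ``S`` = product of the
per-covariate level counts (mixed-radix encoding).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .gittins import GittinsTable

__all__ = [
    "CombinationArm",
    "JointState",
    "CovariateLaw",
    "update_posterior",
    "available_arms",
    "cara_gi_select",
    "flatten_covariates",
]


@dataclass(frozen=True)
class CombinationArm:
    """One (covariate level, treatment) pseudo-arm; treatment 0 is control."""

    covariate_level: int
    treatment: int

    def flat_index(self, n_treatments: int) -> int:
        """Bijective flat index  z * (T + 1) + t."""
        return self.covariate_level * (n_treatments + 1) + self.treatment

    @classmethod
    def from_flat(cls, index: int, n_treatments: int) -> "CombinationArm":
        z, t = divmod(index, n_treatments + 1)
        return cls(z, t)


@dataclass
class CovariateLaw:
    """Known distribution of the (flattened) covariate.

    ``probabilities[z]`` is Pr(Z = z); they must sum to 1.  For a binary
    covariate with success probability q use ``CovariateLaw.bernoulli(q)``.
    """

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 1 or self.probabilities.size < 1:
            raise ValueError("covariate law needs a 1-D probability vector")
        if np.any(self.probabilities < 0):
            raise ValueError("covariate probabilities must be nonnegative")
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ValueError("covariate probabilities must sum to 1")

    @classmethod
    def bernoulli(cls, q: float) -> "CovariateLaw":
        return cls(np.array([1.0 - q, q]))

    @property
    def n_levels(self) -> int:
        return self.probabilities.size

    def sample(self, rng: np.random.Generator, size=None):
        return rng.choice(self.n_levels, size=size, p=self.probabilities)


@dataclass
class JointState:
    """Beta posterior counts for all combination arms.

    ``s[k]`` / ``f[k]`` are the effective success / failure counts of the
    arm with flat index ``k = z * (T + 1) + t`` (prior mass plus observed
    outcomes).  This is the ``S(T+1) x 2`` matrix of the block procedures.
    """

    n_levels: int
    n_treatments: int
    s: np.ndarray
    f: np.ndarray
    prior_s: np.ndarray = field(default=None)
    prior_f: np.ndarray = field(default=None)
    patients_treated: int = 0

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float).copy()
        self.f = np.asarray(self.f, dtype=float).copy()
        n_arms = self.n_levels * (self.n_treatments + 1)
        if self.s.shape != (n_arms,) or self.f.shape != (n_arms,):
            raise ValueError(f"counts must have shape ({n_arms},)")
        if np.any(self.s <= 0) or np.any(self.f <= 0):
            raise ValueError("Beta counts must be positive")
        if self.prior_s is None:
            self.prior_s = self.s.copy()
        if self.prior_f is None:
            self.prior_f = self.f.copy()

    @classmethod
    def uniform_prior(cls, n_levels: int, n_treatments: int) -> "JointState":
        """Beta(1, 1) prior on every combination arm."""
        n_arms = n_levels * (n_treatments + 1)
        return cls(n_levels, n_treatments, np.ones(n_arms), np.ones(n_arms))

    @property
    def n_arms(self) -> int:
        return self.n_levels * (self.n_treatments + 1)

    def arm_slice(self, covariate_level: int) -> slice:
        k0 = covariate_level * (self.n_treatments + 1)
        return slice(k0, k0 + self.n_treatments + 1)

    def posterior_mean(self) -> np.ndarray:
        return self.s / (self.s + self.f)

    def observed_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Observed (successes, failures) per arm, prior mass removed."""
        return self.s - self.prior_s, self.f - self.prior_f

    def copy(self) -> "JointState":
        return JointState(
            self.n_levels,
            self.n_treatments,
            self.s,
            self.f,
            prior_s=self.prior_s.copy(),
            prior_f=self.prior_f.copy(),
            patients_treated=self.patients_treated,
        )

    # checkpointing
    def to_json(self) -> str:
        return json.dumps(
            {
                "n_levels": self.n_levels,
                "n_treatments": self.n_treatments,
                "s": self.s.tolist(),
                "f": self.f.tolist(),
                "prior_s": self.prior_s.tolist(),
                "prior_f": self.prior_f.tolist(),
                "patients_treated": self.patients_treated,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "JointState":
        obj = json.loads(text)
        return cls(
            obj["n_levels"],
            obj["n_treatments"],
            np.array(obj["s"]),
            np.array(obj["f"]),
            prior_s=np.array(obj["prior_s"]),
            prior_f=np.array(obj["prior_f"]),
            patients_treated=obj["patients_treated"],
        )


def update_posterior(state: JointState, arm: CombinationArm, outcome: int) -> JointState:
    """Conjugate update: increment the selected arm's success or failure count.

    Returns a new state; the input is not mutated.  Updates on distinct
    arms commute.
    """
    if outcome not in (0, 1):
        raise ValueError(f"outcome must be 0 or 1, got {outcome}")
    k = arm.flat_index(state.n_treatments)
    if not 0 <= k < state.n_arms:
        raise ValueError(f"invalid arm {arm}")
    new = state.copy()
    if outcome == 1:
        new.s[k] += 1.0
    else:
        new.f[k] += 1.0
    new.patients_treated += 1
    return new


def available_arms(covariate_level: int, n_treatments: int) -> list[CombinationArm]:
    """The T + 1 arms a patient at this covariate level can receive, control first."""
    return [CombinationArm(covariate_level, t) for t in range(n_treatments + 1)]


def cara_gi_select(
    state: JointState,
    covariate_level: int,
    table: GittinsTable,
    rng: np.random.Generator | None = None,
    tie_break: str = "control_first",
) -> CombinationArm:
    """Deterministic CARA Gittins-index selection.

    Among the arms available for the patient's covariate level, returns the
    one with the largest Gittins index.  Exact ties go to the lowest
    treatment index (control preferred) by default, or to a seeded uniform
    draw with ``tie_break="random"``.
    """
    if not 0 <= covariate_level < state.n_levels:
        raise ValueError(f"covariate level {covariate_level} out of range")
    sl = state.arm_slice(covariate_level)
    indices = np.array(
        [table.value(s_, f_) for s_, f_ in zip(state.s[sl], state.f[sl])]
    )
    if tie_break == "random":
        if rng is None:
            raise ValueError("random tie-break needs an rng")
        best = np.flatnonzero(indices == indices.max())
        t = int(rng.choice(best))
    else:
        t = int(np.argmax(indices))  # first max: lowest treatment index
    return CombinationArm(covariate_level, t)


def flatten_covariates(levels_per_covariate: list[int]):
    """Fold a covariate vector into a single stratum label.

    Returns ``(S, encode, decode)`` where ``S`` is the product of the
    per-covariate level counts and ``encode`` / ``decode`` form a bijection
    between covariate vectors and ``{0, ..., S-1}`` (mixed-radix, first
    covariate most significant).
    """
    if not levels_per_covariate:
        raise ValueError("need at least one covariate")
    if any(m < 1 for m in levels_per_covariate):
        raise ValueError("each covariate needs at least one level")
    radices = list(levels_per_covariate)
    total = 1
    for m in radices:
        total *= m

    def encode(vector) -> int:
        if len(vector) != len(radices):
            raise ValueError("covariate vector length mismatch")
        code = 0
        for v, m in zip(vector, radices):
            if not 0 <= v < m:
                raise ValueError(f"covariate value {v} out of range for {m} levels")
            code = code * m + v
        return code

    def decode(code: int) -> tuple[int, ...]:
        if not 0 <= code < total:
            raise ValueError(f"stratum code {code} out of range")
        out = []
        for m in reversed(radices):
            code, r = divmod(code, m)
            out.append(r)
        return tuple(reversed(out))

    return total, encode, decode
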