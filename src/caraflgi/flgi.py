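"""Forward-looking Gittins index (FLGI) block randomization with covariates.

The deterministic CARA Gittins rule is turned into a randomized block
procedure: before each block of ``b`` patients, the probability that each
combination arm would be selected by the Gittins rule at some position of
the block is computed by rolling the rule forward over every possible
future (covariate draws from the known law, outcomes from each arm's
posterior-predictive mean, posteriors updated inside the lookahead).
Patients in the block are then randomized with those probabilities, which
stay frozen until the block completes.

Two evaluation routes are provided: exact tree enumeration (feasible for
small blocks; the test oracle) and Monte-Carlo forward simulation of the
block (the production path).  The controlled variant (CFLGI) pins the
control arm's probability at 1/(K+1) within every covariate group and
renormalizes the experimental arms on the remaining mass.

Probabilities are stored per covariate group: ``pi[z, t]`` is the
probability that a patient with covariate level ``z`` receives treatment
``t``, so every row sums to 1.  The raw block-average quantities, which are
normalized by the expected covariate-group size ``b * q_z`` and are only
guaranteed to normalize after averaging over the first patient's covariate,
are exposed as the ``conditional`` field of the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bandit import CovariateLaw, JointState
from .gittins import GittinsTable

logger = logging.getLogger(__name__)

__all__ = [
    "BlockProbabilities",
    "flgi_probabilities_exact",
    "flgi_probabilities_mc",
    "cflgi_probabilities",
    "assign_block",
]


@dataclass
class BlockProbabilities:
    """Per-covariate-group allocation probabilities for one block.

    ``pi[z, t]``: probability that a patient with covariate level ``z`` in
    this block receives treatment ``t``; rows sum to 1.  ``conditional``
    (exact route only) maps the first patient's covariate level to the raw
    expected-group-size-normalized block averages; ``per_position`` (exact
    route only) holds the per-position allocation probabilities
    ``Pr(arm zt at position i | first covariate)``.
    """

    pi: np.ndarray
    block_index: int
    method: str
    replications: int | None = None
    conditional: dict[int, np.ndarray] | None = None
    per_position: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if np.any(self.pi < -1e-12):
            raise ValueError("allocation probabilities must be nonnegative")
        row_sums = self.pi.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > 1e-9):
            raise ValueError("per-covariate-group probabilities must sum to 1")

    @property
    def n_levels(self) -> int:
        return self.pi.shape[0]

    @property
    def n_treatments(self) -> int:
        return self.pi.shape[1] - 1


def _group_indices(state: JointState, table: GittinsTable, s, f, level: int) -> np.ndarray:
    sl = state.arm_slice(level)
    return np.array([table.value(si, fi) for si, fi in zip(s[sl], f[sl])])


# --------------------------------------------------------------------------
# exact tree enumeration
# --------------------------------------------------------------------------


def flgi_probabilities_exact(
    state: JointState,
    block_size: int,
    law: CovariateLaw,
    table: GittinsTable,
    block_index: int = 1,
    max_paths: int = 1 << 21,
) -> BlockProbabilities:
    """Exact CARA FLGI probabilities by full enumeration of the block tree.

    Branches over every future covariate draw and every Bernoulli outcome,
    with outcome probabilities equal to the selected arm's current
    posterior mean and the Gittins selection applied at each node.  The
    cost grows as ``(2 S)**b``; blocks beyond ``max_paths`` leaves raise
    and should use the Monte-Carlo route instead.
    """
    n_lv, n_tr = state.n_levels, state.n_treatments
    n_arms = n_lv * (n_tr + 1)
    if (2 * n_lv) ** block_size > max_paths:
        raise ValueError(
            f"exact enumeration would visit ~{(2 * n_lv) ** block_size} paths "
            f"(cap {max_paths}); use flgi_probabilities_mc"
        )
    q = law.probabilities
    # alloc[z_first, position, arm]: allocation probability given the first
    # patient's covariate level
    alloc = np.zeros((n_lv, block_size, n_arms))

    def recurse(z_first: int, pos: int, s: np.ndarray, f: np.ndarray, prob: float):
        if pos == block_size:
            return
        levels = [(z_first, 1.0)] if pos == 0 else [
            (z, q[z]) for z in range(n_lv) if q[z] > 0.0
        ]
        for z, pz in levels:
            idx = _group_indices(state, table, s, f, z)
            t = int(np.argmax(idx))  # ties: control first
            arm = z * (n_tr + 1) + t
            p_here = prob * pz
            alloc[z_first, pos, arm] += p_here
            mu = s[arm] / (s[arm] + f[arm])
            if mu > 0.0:
                s[arm] += 1.0
                recurse(z_first, pos + 1, s, f, p_here * mu)
                s[arm] -= 1.0
            if mu < 1.0:
                f[arm] += 1.0
                recurse(z_first, pos + 1, s, f, p_here * (1.0 - mu))
                f[arm] -= 1.0

    for z_first in range(n_lv):
        if q[z_first] > 0.0:
            recurse(z_first, 0, state.s.copy(), state.f.copy(), 1.0)

    # raw block averages normalized by expected group size b * q_z (arm's z)
    arm_level = np.repeat(np.arange(n_lv), n_tr + 1)
    group_size = block_size * q[arm_level]  # per arm
    conditional: dict[int, np.ndarray] = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for z_first in range(n_lv):
            if q[z_first] > 0.0:
                raw = alloc[z_first].sum(axis=0) / group_size
                conditional[z_first] = raw.reshape(n_lv, n_tr + 1)
        marginal = (alloc.sum(axis=1) * q[:, None]).sum(axis=0) / group_size

    pi = marginal.reshape(n_lv, n_tr + 1)
    for z in range(n_lv):
        if q[z] > 0.0:
            pi[z] /= pi[z].sum()  # analytic row sum is 1; remove float drift
        else:
            pi[z] = 1.0 / (n_tr + 1)  # level never occurs; uniform placeholder
    logger.debug("exact FLGI block %d probabilities: %s", block_index, pi.tolist())
    return BlockProbabilities(
        pi=pi,
        block_index=block_index,
        method="exact",
        conditional=conditional,
        per_position=alloc,
    )


# --------------------------------------------------------------------------
# Monte-Carlo forward simulation
# --------------------------------------------------------------------------


def flgi_probabilities_mc(
    state: JointState,
    block_size: int,
    law: CovariateLaw,
    table: GittinsTable,
    replications: int,
    rng: np.random.Generator,
    block_index: int = 1,
) -> BlockProbabilities:
    """Monte-Carlo CARA FLGI probabilities.

    Simulates the block forward ``replications`` times - covariates from
    the known law, outcomes from the selected arm's posterior-predictive
    mean, arms by the Gittins rule - and estimates each group's allocation
    probabilities as the pooled within-group allocation frequencies.
    Reproducible given the generator state.
    """
    if replications < 1:
        raise ValueError("replications must be >= 1")
    n_lv, n_tr = state.n_levels, state.n_treatments
    n_arms = n_lv * (n_tr + 1)
    integer_counts = np.allclose(state.s, np.round(state.s)) and np.allclose(
        state.f, np.round(state.f)
    )
    if not integer_counts:
        raise ValueError(
            "Monte-Carlo lookahead requires integer posterior counts "
            "(table-indexed fast path); use the exact route otherwise"
        )
    R = replications
    S_cnt = np.tile(np.round(state.s).astype(np.int64), (R, 1))
    F_cnt = np.tile(np.round(state.f).astype(np.int64), (R, 1))
    counts = np.zeros((R, n_arms), dtype=np.int64)
    Z = law.sample(rng, size=(R, block_size))
    U = rng.random((R, block_size))
    rows = np.arange(R)
    t_range = np.arange(n_tr + 1)
    G = table.values
    for i in range(block_size):
        base = Z[:, i] * (n_tr + 1)  # (R,)
        cols = base[:, None] + t_range[None, :]  # (R, T+1)
        g = G[S_cnt[rows[:, None], cols], F_cnt[rows[:, None], cols]]
        t_sel = np.argmax(g, axis=1)  # ties: control first
        arm = base + t_sel
        s_sel = S_cnt[rows, arm]
        mu = s_sel / (s_sel + F_cnt[rows, arm])
        success = U[:, i] < mu
        S_cnt[rows, arm] += success
        F_cnt[rows, arm] += ~success
        counts[rows, arm] += 1

    pooled = counts.sum(axis=0).astype(float).reshape(n_lv, n_tr + 1)
    pi = np.empty_like(pooled)
    for z in range(n_lv):
        tot = pooled[z].sum()
        pi[z] = pooled[z] / tot if tot > 0 else 1.0 / (n_tr + 1)
    logger.debug(
        "MC FLGI block %d probabilities (%d reps): %s", block_index, R, pi.tolist()
    )
    return BlockProbabilities(
        pi=pi, block_index=block_index, method="monte_carlo", replications=R
    )


# --------------------------------------------------------------------------
# controlled variant
# --------------------------------------------------------------------------


def cflgi_probabilities(
    state: JointState,
    block_size: int,
    law: CovariateLaw,
    table: GittinsTable,
    replications: int,
    rng: np.random.Generator,
    block_index: int = 1,
    method: str = "monte_carlo",
) -> BlockProbabilities:
    """Controlled CARA FLGI: control pinned at 1/(K+1) per covariate group.

    ``K`` is the number of experimental arms; their FLGI probabilities are
    renormalized onto the remaining mass ``K/(K+1)``.  If the FLGI puts no
    mass on any experimental arm of a group, the experimental mass is
    spread uniformly (logged).
    """
    if method == "exact":
        base = flgi_probabilities_exact(state, block_size, law, table, block_index)
    else:
        base = flgi_probabilities_mc(
            state, block_size, law, table, replications, rng, block_index
        )
    K = state.n_treatments
    if K < 1:
        raise ValueError("CFLGI needs at least one experimental arm")
    pi = base.pi.copy()
    pi[:, 0] = 1.0 / (K + 1)
    for z in range(state.n_levels):
        mass = base.pi[z, 1:].sum()
        if mass > 0:
            pi[z, 1:] = base.pi[z, 1:] / mass * (K / (K + 1))
        else:
            logger.info(
                "CFLGI block %d: no experimental mass for covariate level %d; "
                "spreading uniformly",
                block_index,
                z,
            )
            pi[z, 1:] = 1.0 / (K + 1)
    return BlockProbabilities(
        pi=pi,
        block_index=block_index,
        method=f"cflgi_{base.method}",
        replications=base.replications,
    )


# --------------------------------------------------------------------------
# within-block assignment
# --------------------------------------------------------------------------


def assign_block(
    prob: BlockProbabilities, covariates_of_block, rng: np.random.Generator
):
    """Randomize each patient of a block among the arms of their covariate level.

    Patients are independent draws from the block's per-group
    probabilities.  Returns the assigned treatments as a list of
    ``(covariate_level, treatment)`` flat treatment indices.
    """
    from .bandit import CombinationArm

    out = []
    for z in covariates_of_block:
        row = prob.pi[int(z)]
        tot = row.sum()
        if not tot > 0:
            raise ValueError(f"no allocation mass for covariate level {z}")
        t = int(rng.choice(row.size, p=row / tot))
        out.append(CombinationArm(int(z), t))
    return out
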