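"""Trial simulation, hypothesis tests and operating characteristics.

Patients arrive sequentially with a covariate drawn from a known law and a
binary outcome drawn from the per-arm logistic model
``logit p_t(z) = alpha_t + beta_t z``.  An allocation rule assigns each
patient a treatment; block rules freeze the data at block boundaries while
the fully sequential Gittins rule observes each outcome before the next
patient.  Over replications the simulator aggregates the usual operating
characteristics of response-adaptive designs: power / type-I error,
allocation proportions and their variability, expected numbers of failures
(ENF) and successes (ENS), the proportion of patients on their
covariate-specific best arm (p*), and a combined power-ethics measure (CM).

Supported rules: ``er``, ``spbd``, ``cara1``-``cara4``, ``thompson``,
``gi`` (deterministic, block size 1), ``flgi`` and ``cflgi``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit
from scipy.stats import fisher_exact, norm

from .bandit import CovariateLaw, JointState
from .flgi import (
    BlockProbabilities,
    cflgi_probabilities,
    flgi_probabilities_exact,
    flgi_probabilities_mc,
)
from .gittins import GittinsTable
from .rules import (
    burn_in_schedule,
    cara_target,
    cell_counts,
    fit_outcome_model,
    thompson_probabilities,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrialConfig",
    "TrialResult",
    "OperatingCharacteristics",
    "simulate_trial",
    "wald_test_adjusted_difference",
    "fisher_exact_pvalue",
    "comparison_pvalue",
    "calibrate_test_cutoff",
    "bonferroni_decisions",
    "operating_characteristics",
    "SCENARIO_TWO_ARM_NULL",
    "SCENARIO_TWO_ARM_EFFECT",
    "SCENARIO_THREE_ARM",
]

# Study scenarios used throughout the examples and tests: a two-arm
# redesign of a 450-patient trial with a prognostic binary covariate
# (q = 0.5), and a three-arm, 300-patient setting with a qualitative
# treatment-covariate interaction (a different best arm per covariate
# group).
SCENARIO_TWO_ARM_NULL = {"alpha": [0.6482, 0.6482], "beta": [0.0, 0.0]}
SCENARIO_TWO_ARM_EFFECT = {"alpha": [0.6482, 1.6702], "beta": [0.0, -0.3793]}
SCENARIO_THREE_ARM = {
    "alpha": [-1.252, -0.652, -0.052],
    "beta": [1.152, 1.552, -0.473],
}
SCENARIO_THREE_ARM_NULL = {
    "alpha": [-1.252, -1.252, -1.252],
    "beta": [1.152, 1.152, 1.152],
}

_RULES = ("er", "spbd", "cara1", "cara2", "cara3", "cara4", "thompson", "gi", "flgi", "cflgi")


@dataclass
class TrialConfig:
    """Complete specification of one simulated trial design."""

    n_patients: int
    n_treatments: int
    rule: dict
    covariate_q: list | float = 0.5
    alpha: list | None = None
    beta: list | None = None
    success_probs: list | None = None  # (S, T+1) overrides alpha/beta
    prior_s: float = 1.0
    prior_f: float = 1.0
    discount: float = 0.99
    mc_replications: int = 100
    burn_in: int = 50
    thompson_c: float | None = None  # default J / (2 T)
    thompson_draws: int = 10_000
    test: dict = field(default_factory=lambda: {"name": "wald"})
    alpha_nominal: float = 0.05
    cm_threshold: float | None = None  # default 0.85 two-arm, 0.75 otherwise
    best_arms: list | None = None  # per covariate level; default argmax p_t(z)
    seed: int | None = None

    def __post_init__(self) -> None:
        if isinstance(self.covariate_q, (int, float)):
            self.covariate_q = [1.0 - float(self.covariate_q), float(self.covariate_q)]
        self.law = CovariateLaw(np.asarray(self.covariate_q, dtype=float))
        if self.n_patients < 1 or self.n_treatments < 1:
            raise ValueError("need n_patients >= 1 and n_treatments >= 1")
        if not 0.0 < self.alpha_nominal < 1.0:
            raise ValueError("nominal alpha must lie in (0, 1)")
        name = self.rule.get("name")
        if name not in _RULES:
            raise ValueError(f"unknown rule {name!r}; choose one of {_RULES}")
        b = self.block_size
        if self.n_patients % b != 0:
            raise ValueError(
                f"block size {b} must divide the trial size {self.n_patients}"
            )
        if name.startswith("cara") and not 0 <= self.burn_in <= self.n_patients:
            raise ValueError("burn-in must lie in [0, n_patients]")
        if name == "spbd":
            m = self.rule.get("m", 10)
            if m % (self.n_treatments + 1) != 0:
                raise ValueError("permuted block length must be divisible by T+1")
        p = self.p_matrix()
        if p.shape != (self.law.n_levels, self.n_treatments + 1):
            raise ValueError("success probabilities must have shape (S, T+1)")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("success probabilities must lie in [0, 1]")
        if self.cm_threshold is None:
            self.cm_threshold = 0.85 if self.n_treatments == 1 else 0.75
        if self.best_arms is not None and len(self.best_arms) != self.law.n_levels:
            raise ValueError("best_arms needs one entry per covariate level")

    @property
    def block_size(self) -> int:
        name = self.rule.get("name")
        if name in ("er", "gi", "spbd"):
            return self.rule.get("block_size", 1)
        return self.rule.get("block_size", 10)

    @property
    def n_stages(self) -> int:
        return self.n_patients // self.block_size

    def p_matrix(self) -> np.ndarray:
        """Success probabilities p[z, t] implied by the outcome model."""
        if self.success_probs is not None:
            return np.asarray(self.success_probs, dtype=float)
        if self.alpha is None or self.beta is None:
            raise ValueError("provide either success_probs or alpha and beta")
        a = np.asarray(self.alpha, dtype=float)
        b = np.asarray(self.beta, dtype=float)
        if a.shape != (self.n_treatments + 1,) or b.shape != (self.n_treatments + 1,):
            raise ValueError("alpha and beta need one entry per treatment incl. control")
        z = np.arange(self.law.n_levels)[:, None].astype(float)
        return expit(a[None, :] + b[None, :] * z)

    def resolved_best_arms(self) -> np.ndarray:
        """Best treatment per covariate level (ties resolve to control)."""
        if self.best_arms is not None:
            return np.asarray(self.best_arms, dtype=int)
        return np.argmax(self.p_matrix(), axis=1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("law", None)
        return d


@dataclass
class TrialResult:
    """Per-patient record of one simulated trial."""

    covariates: np.ndarray
    treatments: np.ndarray
    outcomes: np.ndarray
    n_levels: int
    n_treatments: int
    block_probs: list | None = None

    def __post_init__(self) -> None:
        n = self.covariates.size
        if not (self.treatments.size == n and self.outcomes.size == n):
            raise ValueError("per-patient arrays must share one length")

    @property
    def n_patients(self) -> int:
        return self.covariates.size

    def cells(self) -> tuple[np.ndarray, np.ndarray]:
        """(successes, totals) per (covariate level, treatment) cell."""
        return cell_counts(
            self.covariates, self.treatments, self.outcomes, self.n_levels, self.n_treatments
        )


# --------------------------------------------------------------------------
# trial engines
# --------------------------------------------------------------------------


def _draw_outcomes(p: np.ndarray, z, t, rng: np.random.Generator) -> np.ndarray:
    return (rng.random(np.size(t)) < p[z, t]).astype(np.int8)


def _sample_from_rows(pi: np.ndarray, z_block: np.ndarray, rng) -> np.ndarray:
    """One treatment per patient, drawn from the patient's covariate row of pi."""
    cum = np.cumsum(pi, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(z_block.size)
    return (u[:, None] > cum[z_block]).sum(axis=1)


def _simulate_spbd(config: TrialConfig, covs, p, rng) -> np.ndarray:
    m = config.rule.get("m", 10)
    n_arms = config.n_treatments + 1
    base = np.repeat(np.arange(n_arms), m // n_arms)
    treatments = np.empty(config.n_patients, dtype=int)
    for z in range(config.law.n_levels):
        idx = np.flatnonzero(covs == z)
        if idx.size == 0:
            continue
        n_blocks = -(-idx.size // m)
        seq = np.concatenate([rng.permutation(base) for _ in range(n_blocks)])
        treatments[idx] = seq[: idx.size]
    return treatments


def _gi_fast_loop(config, covs, p, table, rng):
    """Fully sequential deterministic Gittins rule (block size 1)."""
    n_arms_g = config.n_treatments + 1
    S, T1 = config.law.n_levels, n_arms_g
    s = np.full(S * T1, int(config.prior_s), dtype=np.int64)
    f = np.full(S * T1, int(config.prior_f), dtype=np.int64)
    if config.prior_s != int(config.prior_s) or config.prior_f != int(config.prior_f):
        raise ValueError("fast Gittins path needs integer prior counts")
    G = table.values
    treatments = np.empty(config.n_patients, dtype=int)
    u = rng.random(config.n_patients)
    outcomes = np.empty(config.n_patients, dtype=np.int8)
    for n in range(config.n_patients):
        z = covs[n]
        b0 = z * T1
        g = G[s[b0 : b0 + T1], f[b0 : b0 + T1]]
        t = int(np.argmax(g))  # ties: control first
        y = 1 if u[n] < p[z, t] else 0
        if y:
            s[b0 + t] += 1
        else:
            f[b0 + t] += 1
        treatments[n] = t
        outcomes[n] = y
    return treatments, outcomes


def simulate_trial(
    config: TrialConfig,
    rng: np.random.Generator,
    table: GittinsTable | None = None,
) -> TrialResult:
    """Simulate one complete trial under the configured allocation rule.

    Gittins-based rules require a ``GittinsTable`` deep enough for all
    reachable states (prior mass + N + lookahead).  Fully reproducible
    given the generator state.
    """
    name = config.rule["name"]
    S = config.law.n_levels
    T = config.n_treatments
    p = config.p_matrix()
    N = config.n_patients
    covs = config.law.sample(rng, size=N)

    if name in ("gi", "flgi", "cflgi") and table is None:
        raise ValueError(f"rule {name!r} requires a Gittins table")

    if name == "er":
        treatments = rng.integers(0, T + 1, size=N)
        outcomes = _draw_outcomes(p, covs, treatments, rng)
        return TrialResult(covs, treatments, outcomes, S, T)

    if name == "spbd":
        treatments = _simulate_spbd(config, covs, p, rng)
        outcomes = _draw_outcomes(p, covs, treatments, rng)
        return TrialResult(covs, treatments, outcomes, S, T)

    if name == "gi":
        treatments, outcomes = _gi_fast_loop(config, covs, p, table, rng)
        return TrialResult(covs, treatments, outcomes, S, T)

    # block procedures: probabilities frozen at each block boundary
    b = config.block_size
    J = config.n_stages
    treatments = np.empty(N, dtype=int)
    outcomes = np.empty(N, dtype=np.int8)
    state = JointState(
        S, T, np.full(S * (T + 1), config.prior_s), np.full(S * (T + 1), config.prior_f)
    )
    er_mask = (
        burn_in_schedule(N, config.burn_in) if name.startswith("cara") else np.zeros(N, bool)
    )
    block_probs: list[BlockProbabilities] = []
    c_exponent = (
        config.thompson_c if config.thompson_c is not None else J / (2.0 * T)
    )
    uniform = np.full((S, T + 1), 1.0 / (T + 1))

    for j in range(J):
        lo, hi = j * b, (j + 1) * b
        z_block = covs[lo:hi]
        if name.startswith("cara"):
            variant = int(name[-1])
            if lo >= config.burn_in:
                _, p_hat, _ = fit_outcome_model(
                    covs[:lo], treatments[:lo], outcomes[:lo], S, T
                ) if lo > 0 else (None, np.full((S, T + 1), 0.5), None)
                p_hat = np.clip(p_hat, 1e-6, 1 - 1e-6)
                pi = cara_target(variant, p_hat).rho
            else:
                pi = uniform
            bp = BlockProbabilities(pi=pi, block_index=j + 1, method=f"cara{variant}")
        elif name == "thompson":
            pi = np.stack(
                [
                    thompson_probabilities(state, z, c_exponent, config.thompson_draws, rng)
                    for z in range(S)
                ]
            )
            bp = BlockProbabilities(pi=pi, block_index=j + 1, method="thompson")
        elif name == "flgi":
            if config.rule.get("method") == "exact":
                bp = flgi_probabilities_exact(state, b, config.law, table, j + 1)
            else:
                bp = flgi_probabilities_mc(
                    state, b, config.law, table, config.mc_replications, rng, j + 1
                )
        elif name == "cflgi":
            bp = cflgi_probabilities(
                state,
                b,
                config.law,
                table,
                config.mc_replications,
                rng,
                j + 1,
                method=config.rule.get("method", "monte_carlo"),
            )
        else:  # pragma: no cover
            raise ValueError(f"unhandled rule {name!r}")

        t_block = _sample_from_rows(bp.pi, z_block, rng)
        if name.startswith("cara") and er_mask[lo:hi].any():
            mask = er_mask[lo:hi]
            t_block[mask] = rng.integers(0, T + 1, size=int(mask.sum()))
        y_block = _draw_outcomes(p, z_block, t_block, rng)
        treatments[lo:hi] = t_block
        outcomes[lo:hi] = y_block
        # posteriors advance only once the block completes
        arm = z_block * (T + 1) + t_block
        np.add.at(state.s, arm[y_block == 1], 1.0)
        np.add.at(state.f, arm[y_block == 0], 1.0)
        state.patients_treated += b
        block_probs.append(bp)

    return TrialResult(covs, treatments, outcomes, S, T, block_probs=block_probs)


# --------------------------------------------------------------------------
# hypothesis tests
# --------------------------------------------------------------------------


def _ztest_from_cells(s0, n0, s1, n1) -> float:
    """Score-type two-proportion z-test; two-sided normal p-value."""
    if n0 == 0 or n1 == 0:
        return 1.0
    p0, p1 = s0 / n0, s1 / n1
    pbar = (s0 + s1) / (n0 + n1)
    var = pbar * (1.0 - pbar) * (1.0 / n0 + 1.0 / n1)
    if var <= 0:
        return 1.0
    z = (p1 - p0) / np.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


def wald_test_adjusted_difference(
    result: TrialResult, arm: int = 1, stratum: int = 0
) -> float:
    """Normal-cutoff test of the covariate-adjusted difference alpha_t - alpha_0.

    Under the saturated per-arm logistic model the intercept contrast is
    identified by the covariate-level-``stratum`` cells alone, so the test
    reduces to a two-proportion z-test (pooled variance under the null)
    between the arm and control within that stratum.  Non-estimable cells
    give p = 1.
    """
    succ, n = result.cells()
    return _ztest_from_cells(
        succ[stratum, 0], n[stratum, 0], succ[stratum, arm], n[stratum, arm]
    )


def fisher_exact_pvalue(table: np.ndarray) -> float:
    """Two-sided Fisher exact p-value on a 2x2 success/failure table."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a 2x2 table of nonnegative counts")
    if table.sum(axis=1).min() == 0 or table.sum() == 0:
        return 1.0
    return float(fisher_exact(table, alternative="two-sided")[1])


def comparison_pvalue(
    result: TrialResult, arm: int, config: TrialConfig, stratum: int | None = None
) -> float:
    """p-value for experimental ``arm`` vs control under the configured test.

    ``stratum=None`` gives the trial-level comparison (normal-cutoff test
    of the adjusted difference, or Fisher on the margins pooled over
    covariate levels); an explicit ``stratum`` restricts both tests to
    that covariate subgroup (used for the multi-arm marginal powers).
    """
    test = config.test.get("name", "wald")
    succ, n = result.cells()
    if test == "wald":
        return wald_test_adjusted_difference(result, arm, stratum=stratum or 0)
    if test == "fisher":
        if stratum is None:
            s0, n0 = succ[:, 0].sum(), n[:, 0].sum()
            s1, n1 = succ[:, arm].sum(), n[:, arm].sum()
        else:
            s0, n0 = succ[stratum, 0], n[stratum, 0]
            s1, n1 = succ[stratum, arm], n[stratum, arm]
        return fisher_exact_pvalue([[s1, n1 - s1], [s0, n0 - s0]])
    raise ValueError(f"unknown test {test!r}")


def bonferroni_decisions(p_values, nominal_alpha: float, n_comparisons: int):
    """Reject each hypothesis whose p-value is below alpha / K."""
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    return np.asarray(p_values, dtype=float) < nominal_alpha / n_comparisons


def calibrate_test_cutoff(
    config_under_null: TrialConfig,
    replications: int,
    nominal_alpha: float,
    rng: np.random.Generator,
    table: GittinsTable | None = None,
    arm: int = 1,
    stratum: int | None = None,
) -> float:
    """Simulation-calibrated rejection threshold for a given design.

    Simulates the design under its (null) outcome model, collects the
    comparison p-values and returns the largest threshold whose empirical
    rejection rate (``p <= cutoff``) does not exceed ``nominal_alpha`` on
    the calibration sample.  Discrete tests (Fisher) are conservative at
    fixed nominal levels; rejecting at the calibrated cutoff restores the
    nominal type-I error rate.
    """
    if replications < 1:
        raise ValueError("replications must be >= 1")
    streams = rng.spawn(replications)
    ps = np.array(
        [
            comparison_pvalue(
                simulate_trial(config_under_null, streams[i], table), arm,
                config_under_null, stratum,
            )
            for i in range(replications)
        ]
    )
    if nominal_alpha >= 1.0:
        return float(ps.max())
    k = int(np.floor(nominal_alpha * replications))
    uniq = np.unique(ps)
    counts = np.searchsorted(np.sort(ps), uniq, side="right")
    ok = uniq[counts <= k]
    return float(ok.max()) if ok.size else 0.0


# --------------------------------------------------------------------------
# operating characteristics
# --------------------------------------------------------------------------


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    mean = float(np.nanmean(x))
    sd = float(np.nanstd(x, ddof=1)) if x.size > 1 else float("nan")
    return mean, sd


@dataclass
class OperatingCharacteristics:
    """Aggregated trial metrics over replications."""

    replications: int
    power: float  # trial-level rejection rate (type-I error under the null)
    family_wise_rate: float
    power_by_level: np.ndarray  # subgroup-best-arm rejection rate per level
    alloc_prop_mean: np.ndarray
    alloc_prop_sd: np.ndarray
    best_prop_mean: np.ndarray  # within-level proportion on the level's best arm
    best_prop_sd: np.ndarray
    enf_mean: float
    enf_sd: float
    ens_mean: float
    ens_sd: float
    pstar_mean: float
    pstar_sd: float
    cm_pct: float


def operating_characteristics(
    config: TrialConfig,
    replications: int,
    rng: np.random.Generator,
    table: GittinsTable | None = None,
) -> OperatingCharacteristics:
    """Simulate independent replications of a design and aggregate its metrics.

    Each replication runs on its own spawned substream, so results are
    bit-reproducible from the master generator and independent across
    replications.  ``p*`` weights the within-level best-arm allocation
    proportions by the known covariate law; CM counts replications that
    both allocate at least ``cm_threshold`` of covariate-level-0 patients
    to that level's best arm and reject at the trial level.
    """
    if replications < 1:
        raise ValueError("replications must be >= 1")
    S, T, N = config.law.n_levels, config.n_treatments, config.n_patients
    best = config.resolved_best_arms()
    q = config.law.probabilities
    is_null = bool(np.all(best == 0))
    cutoff = config.test.get("cutoff")

    streams = rng.spawn(replications)
    failures = np.empty(replications)
    alloc = np.empty((replications, T + 1))
    best_prop = np.full((replications, S), np.nan)
    pstar = np.empty(replications)
    reject_any = np.zeros(replications, bool)
    reject_trial = np.zeros(replications, bool)
    reject_level = np.zeros((replications, S), bool)

    for i in range(replications):
        res = simulate_trial(config, streams[i], table)
        failures[i] = N - res.outcomes.sum()
        alloc[i] = np.bincount(res.treatments, minlength=T + 1) / N
        for z in range(S):
            nz = int((res.covariates == z).sum())
            if nz:
                # under the global null the "best" arm is control, matching
                # the convention that p* is the control proportion there
                best_prop[i, z] = (
                    ((res.covariates == z) & (res.treatments == best[z])).sum() / nz
                )
        bp = np.where(np.isnan(best_prop[i]), 0.0, best_prop[i])
        pstar[i] = float((q * bp).sum())

        p_arms = np.array(
            [comparison_pvalue(res, t, config) for t in range(1, T + 1)]
        )
        if cutoff is not None:
            dec = p_arms <= cutoff / T if T > 1 else p_arms <= cutoff
        else:
            dec = bonferroni_decisions(p_arms, config.alpha_nominal, T)
        reject_any[i] = bool(dec.any())
        reject_trial[i] = bool(dec[0]) if T == 1 else bool(dec.any())
        if not is_null:
            for z in range(S):
                if best[z] != 0:
                    pz = comparison_pvalue(res, int(best[z]), config, stratum=z)
                    if cutoff is not None:
                        reject_level[i, z] = pz <= (cutoff / T if T > 1 else cutoff)
                    else:
                        reject_level[i, z] = pz < config.alpha_nominal / T

    enf_mean, enf_sd = _mean_sd(failures)
    ens_mean, ens_sd = _mean_sd(N - failures)
    pstar_mean, pstar_sd = _mean_sd(pstar)
    cm = float(
        np.mean((np.nan_to_num(best_prop[:, 0]) >= config.cm_threshold) & reject_any) * 100.0
    )
    alloc_sd = alloc.std(axis=0, ddof=1) if replications > 1 else np.full(T + 1, np.nan)
    bp_sd = (
        np.nanstd(best_prop, axis=0, ddof=1) if replications > 1 else np.full(S, np.nan)
    )
    power_by_level = np.where(best != 0, reject_level.mean(axis=0), np.nan)
    return OperatingCharacteristics(
        replications=replications,
        power=float(reject_trial.mean()),
        family_wise_rate=float(reject_any.mean()),
        power_by_level=power_by_level,
        alloc_prop_mean=alloc.mean(axis=0),
        alloc_prop_sd=alloc_sd,
        best_prop_mean=np.nanmean(best_prop, axis=0),
        best_prop_sd=bp_sd,
        enf_mean=enf_mean,
        enf_sd=enf_sd,
        ens_mean=ens_mean,
        ens_sd=ens_sd,
        pstar_mean=pstar_mean,
        pstar_sd=pstar_sd,
        cm_pct=cm,
    )
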