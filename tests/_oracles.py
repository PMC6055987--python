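"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by a route deliberately different from
the package implementation: plain-tail value iteration with uniform
bisection for the Gittins index, direct tree recursion over a covariate-free
block for FLGI probabilities, numerical integration for Beta comparison
probabilities, and exhaustive hypergeometric enumeration for the Fisher
exact test.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate
from scipy.special import betaln
from scipy.stats import beta as beta_dist


def oracle_gittins(s: float, f: float, discount: float, tol: float = 1e-6,
                   horizon: int = 1800) -> float:
    """Calibration oracle: value iteration with a flat retirement tail.

    Bisects the retirement reward; each evaluation prices the boundary at
    the retirement value itself (no posterior-mean refinement), so the
    code path is independent of the package's implementation.
    """
    one = 1.0 / (1.0 - discount)
    lo, hi = s / (s + f), 1.0
    while hi - lo > tol:
        lam = 0.5 * (lo + hi)
        v = np.full(horizon + 1, lam * one)
        root_play = None
        for j in range(horizon - 1, -1, -1):
            i = np.arange(j + 1)
            mu = (s + i) / (s + f + j)
            play = mu + discount * (mu * v[1 : j + 2] + (1.0 - mu) * v[: j + 1])
            if j == 0:
                root_play = play[0]
            v = np.maximum(lam * one, play)
        if root_play > lam * one:
            lo = lam
        else:
            hi = lam
    return 0.5 * (lo + hi)


def flgi_tree_oracle(s: np.ndarray, f: np.ndarray, block_size: int,
                     index_fn) -> np.ndarray:
    """Expected allocation counts of a covariate-free Gittins block.

    Plain recursion over a single group of arms: at each of the
    ``block_size`` positions the arm with the largest index is chosen
    (first max on ties), the outcome branches with probability equal to the
    arm's posterior mean.  Returns expected allocations per arm divided by
    the block size.
    """
    n_arms = s.size
    counts = np.zeros(n_arms)

    def rec(s_, f_, pos, prob):
        if pos == block_size:
            return
        g = [index_fn(s_[a], f_[a]) for a in range(n_arms)]
        a = int(np.argmax(g))
        counts[a] += prob
        mu = s_[a] / (s_[a] + f_[a])
        s_[a] += 1
        rec(s_, f_, pos + 1, prob * mu)
        s_[a] -= 1
        f_[a] += 1
        rec(s_, f_, pos + 1, prob * (1 - mu))
        f_[a] -= 1

    rec(s.astype(float).copy(), f.astype(float).copy(), 0, 1.0)
    return counts / block_size


def pr_beta_greater(a1: float, b1: float, a2: float, b2: float) -> float:
    """Pr(X > Y) for independent X~Beta(a1,b1), Y~Beta(a2,b2), by quadrature."""
    val, _ = integrate.quad(
        lambda x: beta_dist.pdf(x, a1, b1) * beta_dist.cdf(x, a2, b2), 0, 1
    )
    return val


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher exact p-value by exhaustive enumeration.

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's.
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def log_p(x):
        return (
            -betaln(x + 1, r1 - x + 1) - math.log(r1 + 1)
            - betaln(c1 - x + 1, r2 - (c1 - x) + 1) - math.log(r2 + 1)
        ) - (-betaln(c1 + 1, n - c1 + 1) - math.log(n + 1))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = log_p(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_p(x)
        if lp <= obs + 1e-9:
            total += math.exp(lp)
    return min(total, 1.0)
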