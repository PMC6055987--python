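"""Gittins indices for Beta-Bernoulli arms.

The Gittins index of an arm whose success probability carries a Beta(s, f)
posterior is the supremum, over stopping times, of the ratio between the
expected discounted number of successes collected while the arm is played
and the expected discounted number of plays.  It is the quantity that makes
the index rule optimal for the discounted infinite-horizon bandit, and here
it drives every covariate-adjusted allocation rule in the package.

Indices are computed through the classic calibration problem: play the arm
against a retirement option paying a constant reward ``lam`` per period.
The value of retiring is ``lam / (1 - d)``; the index is the ``lam`` at
which playing and retiring are equally attractive at the root state.  The
calibration problem is solved by finite-horizon backward induction on the
triangular lattice of posterior counts, truncated at a depth where the
discounted tail is negligible; the retirement reward is then located either
by bisection (single state) or by a sweep over a uniform grid of ``lam``
values, which prices every state of a whole table from one dynamic program
per grid point.
"""

from __future__ import annotations

import hashlib
import io
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BetaCounts",
    "GittinsTable",
    "compute_gittins_index",
    "build_gittins_table",
]


# --------------------------------------------------------------------------
# states
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BetaCounts:
    """Effective success/failure counts of a Beta posterior (prior + data)."""

    s: float
    f: float

    def __post_init__(self) -> None:
        if not (self.s > 0 and self.f > 0):
            raise ValueError(f"Beta counts must be positive, got (s={self.s}, f={self.f})")

    @property
    def mean(self) -> float:
        return self.s / (self.s + self.f)


def _check_discount(discount: float) -> None:
    if not 0.0 <= discount < 1.0:
        raise ValueError(f"discount must lie in [0, 1), got {discount}")


def _default_horizon(discount: float, tolerance: float) -> int:
    """Truncation depth for the backward induction.

    Chosen so that d**H is small relative to the requested tolerance.  The
    boundary states are priced at ``max(lam, posterior mean) / (1 - d)``,
    which is itself within the index's exploration bonus of the true value,
    so the effective truncation error is far below ``d**H / (1 - d)``.
    """
    if discount == 0.0:
        return 1
    target = max(tolerance, 1e-12)
    h = int(math.ceil(math.log(target) / math.log(discount)))
    return int(min(max(h, 50), 4000))


# --------------------------------------------------------------------------
# single-state computation (calibration + bisection)
# --------------------------------------------------------------------------


def _calibration_play_value(
    s: float, f: float, lam: float, discount: float, horizon: int
) -> float:
    """Value of the 'play' action at the root of the calibration problem.

    Backward induction over the relative lattice of (extra successes,
    extra failures) up to ``horizon`` plays, with boundary states priced at
    ``max(lam, mean) / (1 - d)``.
    """
    d = discount
    one = 1.0 / (1.0 - d)
    retire = lam * one
    # diagonal j: states (s + i, f + j - i), i = 0..j
    i = np.arange(horizon + 1)
    mu = (s + i) / (s + f + horizon)
    v = np.maximum(lam, mu) * one
    for j in range(horizon - 1, -1, -1):
        i = np.arange(j + 1)
        mu = (s + i) / (s + f + j)
        play = mu + d * (mu * v[1 : j + 2] + (1.0 - mu) * v[: j + 1])
        v = np.maximum(retire, play)
        if j == 0:
            return float(play[0])
    return float(v[0])  # horizon == 0 edge


def compute_gittins_index(
    counts: BetaCounts | tuple[float, float],
    discount: float,
    tolerance: float = 1e-6,
    horizon: int | None = None,
) -> float:
    """Gittins index of a Beta(s, f) Bernoulli arm at the given discount.

    The index depends only on the posterior counts and the discount, never
    on any trial context.  Zero discount collapses to the posterior mean
    (the supremum is attained by stopping after one play).  Counts may be
    non-integer.

    Parameters
    ----------
    counts
        Posterior counts, ``BetaCounts`` or a ``(s, f)`` pair.
    discount
        Discount factor ``d`` in [0, 1).
    tolerance
        Half-width of the final bisection bracket on the index.
    horizon
        Truncation depth of the backward induction; defaults to a depth at
        which the discounted tail is negligible for ``tolerance``.
    """
    if not isinstance(counts, BetaCounts):
        counts = BetaCounts(*counts)
    _check_discount(discount)
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    mu = counts.mean
    if discount == 0.0:
        return mu
    h = _default_horizon(discount, tolerance) if horizon is None else int(horizon)
    one = 1.0 / (1.0 - discount)
    lo, hi = mu, 1.0  # index dominates the mean; rewards are bounded by 1
    while hi - lo > tolerance:
        lam = 0.5 * (lo + hi)
        play = _calibration_play_value(counts.s, counts.f, lam, discount, h)
        if play > lam * one:
            lo = lam
        else:
            hi = lam
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# whole-table computation (shared-lambda sweep)
# --------------------------------------------------------------------------


@dataclass
class GittinsTable:
    """Lookup table of Gittins indices over integer-count states.

    Covers every state with integer counts ``s, f >= 1`` and ``s + f <=
    max_depth``.  ``values[s, f]`` is the index (NaN outside the covered
    triangle).  Non-integer lookups fall back to direct computation and are
    memoised.
    """

    discount: float
    max_depth: int
    tolerance: float
    values: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def value(self, s: float, f: float) -> float:
        """Index for counts (s, f); table lookup or direct fallback."""
        if s <= 0 or f <= 0:
            raise ValueError(f"Beta counts must be positive, got (s={s}, f={f})")
        si, fi = int(s), int(f)
        if si == s and fi == f:
            if si + fi > self.max_depth:
                raise KeyError(
                    f"state (s={si}, f={fi}) exceeds table max_depth={self.max_depth}"
                )
            return float(self.values[si, fi])
        key = (float(s), float(f))
        if key not in self._cache:
            self._cache[key] = compute_gittins_index(
                BetaCounts(s, f), self.discount, min(self.tolerance, 1e-6)
            )
        return self._cache[key]

    # ---- plain-text serialization ----

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_csv_string())

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        buf.write(f"# discount={self.discount!r}\n")
        buf.write(f"# max_depth={self.max_depth}\n")
        buf.write(f"# tolerance={self.tolerance!r}\n")
        buf.write("s,f,index\n")
        for depth in range(2, self.max_depth + 1):
            for s in range(1, depth):
                buf.write(f"{s},{depth - s},{float(self.values[s, depth - s])!r}\n")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, path) -> "GittinsTable":
        meta: dict[str, str] = {}
        rows: list[tuple[int, int, float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line.lstrip("# ").partition("=")
                    meta[key.strip()] = val.strip()
                elif line[0].isdigit():
                    s_, f_, g_ = line.split(",")
                    rows.append((int(s_), int(f_), float(g_)))
        max_depth = int(meta["max_depth"])
        values = np.full((max_depth + 1, max_depth + 1), np.nan)
        for s_, f_, g_ in rows:
            values[s_, f_] = g_
        return cls(
            discount=float(meta["discount"]),
            max_depth=max_depth,
            tolerance=float(meta["tolerance"]),
            values=values,
        )

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_csv_string().encode()).hexdigest()


def build_gittins_table(
    max_depth: int,
    discount: float,
    tolerance: float = 1e-4,
    horizon: int | None = None,
    lam_chunk: int = 256,
) -> GittinsTable:
    """Build a Gittins index table for all integer states with s + f <= max_depth.

    A single backward induction at retirement reward ``lam`` decides, for
    every state simultaneously, whether playing beats retiring - i.e.
    whether the state's index exceeds ``lam``.  Sweeping ``lam`` over a
    uniform grid of step ``tolerance`` and counting, per state, the grid
    points at which playing wins brackets every index to within half a grid
    step.  Construction is deterministic given the arguments.

    Estimates are clamped from below at the posterior mean (the index
    dominates the mean exactly).
    """
    if max_depth < 2:
        raise ValueError("max_depth must be at least 2")
    _check_discount(discount)
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")

    values = np.full((max_depth + 1, max_depth + 1), np.nan)
    if discount == 0.0:
        # zero-discount collapse: index equals the posterior mean exactly
        for depth in range(2, max_depth + 1):
            s = np.arange(1, depth)
            values[s, depth - s] = s / depth
        return GittinsTable(discount, max_depth, tolerance, values)

    h = _default_horizon(discount, tolerance) if horizon is None else int(horizon)
    t_max = max_depth + h
    one = 1.0 / (1.0 - discount)
    d = discount

    # posterior means per diagonal, cached across lambda chunks
    mu_by_diag = [np.arange(1, m) / m for m in range(t_max + 1)]

    n_grid = int(math.ceil(1.0 / tolerance))
    grid = np.arange(n_grid) * tolerance  # lam_0 = 0: playing always wins there
    play_counts = [np.zeros(max(m - 1, 0), dtype=np.int64) for m in range(max_depth + 1)]

    for c0 in range(0, n_grid, lam_chunk):
        lam = grid[c0 : c0 + lam_chunk][:, None]  # (L, 1)
        retire = lam * one
        mu = mu_by_diag[t_max]
        v = np.maximum(lam, mu[None, :]) * one  # boundary diagonal
        for m in range(t_max - 1, 1, -1):
            mu = mu_by_diag[m]
            play = mu + d * (mu * v[:, 1:m] + (1.0 - mu) * v[:, : m - 1])
            if m <= max_depth:
                play_counts[m] += (play > retire).sum(axis=0)
            v = np.maximum(retire, play)

    for m in range(2, max_depth + 1):
        s = np.arange(1, m)
        est = (play_counts[m] - 0.5) * tolerance
        values[s, m - s] = np.maximum(est, s / m)

    return GittinsTable(discount, max_depth, tolerance, values)
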