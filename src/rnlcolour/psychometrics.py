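"""Psychometric function fitting for two-alternative choice data.

The correct-choice probability at stimulus level x is modelled as a logistic
with a fixed guess rate and a bounded lapse rate,

    ψ(x) = γ + (1 - γ - λ) / (1 + exp((a - x)/b)),

where γ is the chance level of the task (0.5 for two alternatives), λ the
lapse rate (upper asymptote 1 - λ, bounded to [0, 0.25]), a the position of
the curve and b > 0 its steepness scale.  Parameters (a, b, λ) are estimated
by maximising the binomial log-likelihood over aggregated per-level counts,
with a multi-start grid guarding against the flat-likelihood plateaus that
near-chance data produce.

The threshold is read off the fitted curve at a criterion proportion; for a
session of n trials per level the criterion is the smallest correct-choice
proportion that is significantly above chance by a one-tailed binomial test
(66.7% for n = 30 at α = 0.05).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "LevelData",
    "PsychometricFit",
    "psi",
    "fit_psychometric",
    "threshold_from_fit",
    "binomial_criterion",
    "compare_conditions",
    "read_trial_table",
]


class UnattainableCriterionError(ValueError):
    """The requested criterion lies outside the fitted curve's range."""


@dataclass(frozen=True)
class LevelData:
    """Aggregated choices at one stimulus level."""
    level: float
    n_trials: int
    n_correct: int

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not 0 <= self.n_correct <= self.n_trials:
            raise ValueError("n_correct must lie in [0, n_trials]")


@dataclass(frozen=True)
class PsychometricFit:
    """Maximum-likelihood logistic fit to binomial choice data."""
    guess_rate: float
    lapse_rate: float
    position: float        # a
    steepness: float       # b > 0
    log_likelihood: float
    converged: bool
    n_levels: int
    ceiling: bool = False  # performance above chance only at the top level

    def __post_init__(self) -> None:
        if self.converged and self.steepness <= 0:
            raise ValueError("steepness must be positive")


def psi(x, guess_rate: float, lapse_rate: float,
        position: float, steepness: float):
    """Evaluate the logistic psychometric function ψ(x)."""
    if steepness <= 0:
        raise ValueError("steepness b must be positive")
    x = np.asarray(x, dtype=float)
    # expit((x-a)/b) == 1/(1+exp((a-x)/b)), overflow-safe
    core = special.expit((x - position) / steepness)
    out = guess_rate + (1.0 - guess_rate - lapse_rate) * core
    return float(out) if out.ndim == 0 else out


def psi_from_fit(x, fit: PsychometricFit):
    return psi(x, fit.guess_rate, fit.lapse_rate, fit.position, fit.steepness)


def _neg_log_likelihood(params: np.ndarray, levels: np.ndarray,
                        n: np.ndarray, k: np.ndarray,
                        guess_rate: float) -> float:
    a, b, lapse = params
    if b <= 0:
        return np.inf
    p = psi(levels, guess_rate, lapse, a, b)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def fit_psychometric(data: Sequence[LevelData], guess_rate: float = 0.5,
                     lapse_bounds: tuple[float, float] = (0.0, 0.25),
                     n_starts: int = 5) -> PsychometricFit:
    """Fit (a, b, λ) by maximum likelihood with a multi-start grid.

    Starting points span the level range for the position and a decade
    around the level spacing for the steepness; the lapse rate starts at
    0.02 and is box-bounded.  Chance-level data (no information about the
    curve's position) yield ``converged=False`` rather than an arbitrary
    threshold.  Data above chance only at the single highest level are
    flagged ``ceiling=True`` with the position pinned near that level.
    """
    data = sorted(data, key=lambda d: d.level)
    if len({d.level for d in data}) < 3:
        raise ValueError("need at least three distinct stimulus levels")
    levels = np.array([d.level for d in data])
    n = np.array([d.n_trials for d in data])
    k = np.array([d.n_correct for d in data])

    span = levels[-1] - levels[0]
    spacing = span / max(len(levels) - 1, 1)
    a_grid = np.linspace(levels[0], levels[-1], n_starts)
    b_grid = np.geomspace(spacing / 3.0, spacing * 3.0, n_starts)
    bounds = [(levels[0] - 2 * span, levels[-1] + 2 * span),
              (spacing * 1e-3, span * 10.0), lapse_bounds]

    best = None
    for a0, b0 in itertools.product(a_grid, b_grid):
        res = optimize.minimize(
            _neg_log_likelihood, x0=np.array([a0, b0, 0.02]),
            args=(levels, n, k, guess_rate), method="L-BFGS-B",
            bounds=bounds)
        if best is None or res.fun < best.fun - 1e-12:
            best = res

    a, b, lapse = best.x
    ll = -best.fun

    # informativeness check: fit must beat a flat chance+lapse model
    def flat_nll(p_flat: float) -> float:
        p_flat = np.clip(p_flat, 1e-12, 1 - 1e-12)
        return -float(np.sum(k * np.log(p_flat) + (n - k) * np.log1p(-p_flat)))

    p_hat = np.clip(k.sum() / n.sum(), guess_rate, 1.0)
    flat_ll = -flat_nll(p_hat)
    informative = ll > flat_ll + 1e-6
    converged = bool(best.success) and informative

    # ceiling: only the top level is individually above chance
    above = np.array([stats.binomtest(int(ki), int(ni), guess_rate,
                                      alternative="greater").pvalue < 0.05
                      for ki, ni in zip(k, n)])
    ceiling = bool(above[-1] and not above[:-1].any())

    return PsychometricFit(guess_rate=guess_rate, lapse_rate=float(lapse),
                           position=float(a), steepness=float(b),
                           log_likelihood=float(ll), converged=converged,
                           n_levels=len(levels), ceiling=ceiling)


def threshold_from_fit(fit: PsychometricFit, criterion: float) -> float:
    """Invert the fitted curve at a criterion proportion.

        x* = a - b·ln((1 - γ - λ)/(c - γ) - 1)

    Raises :class:`UnattainableCriterionError` when the criterion lies
    outside (γ, 1 - λ) or the fit carries no information.
    """
    g, lam = fit.guess_rate, fit.lapse_rate
    if not fit.converged:
        raise UnattainableCriterionError(
            "fit did not converge; threshold undefined")
    if not g < criterion < 1.0 - lam:
        raise UnattainableCriterionError(
            f"criterion {criterion} outside attainable range "
            f"({g}, {1 - lam})")
    ratio = (1.0 - g - lam) / (criterion - g) - 1.0
    return float(fit.position - fit.steepness * np.log(ratio))


def binomial_criterion(n: int, p0: float = 0.5,
                       alpha: float = 0.05) -> tuple[int, float]:
    """Smallest correct count significantly above chance, one-tailed.

    Returns (k_min, k_min/n) where k_min is the smallest k with
    P(X ≥ k | n, p0) < alpha under the binomial null.
    """
    if not 0 < p0 < 1 or not 0 < alpha < 1:
        raise ValueError("p0 and alpha must lie in (0, 1)")
    ks = np.arange(n + 1)
    tail = stats.binom.sf(ks - 1, n, p0)  # P(X >= k)
    ok = np.nonzero(tail < alpha)[0]
    if ok.size == 0:
        raise UnattainableCriterionError(
            f"no criterion attainable with n={n} at alpha={alpha}")
    k_min = int(ks[ok[0]])
    return k_min, k_min / n


def _exact_ranksum_pvalue(x: np.ndarray, y: np.ndarray, w_obs: float) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments.

    Uses midranks, so ties (including identical groups) are handled; the
    p-value is P(|W - E[W]| >= |w_obs - E[W]|) over all C(n, n1) splits.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    mu = ranks.mean() * n1
    d_obs = abs(w_obs - mu)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= d_obs - 1e-12:
            count += 1
    return count / total


def compare_conditions(thresholds_a: Sequence[float],
                       thresholds_b: Sequence[float]
                       ) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two threshold groups.

    Returns (rank sum of the first group, p-value).  Exact enumeration with
    midrank tie handling for combined n ≤ 12, scipy's normal approximation
    with tie correction above.
    """
    x = np.asarray(thresholds_a, dtype=float)
    y = np.asarray(thresholds_b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two thresholds per group")
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = float(ranks[: x.size].sum())
    if x.size + y.size <= 12:
        p = _exact_ranksum_pvalue(x, y, w)
    else:
        p = float(stats.ranksums(x, y).pvalue)
    return w, p


def read_trial_table(path) -> list[LevelData]:
    """Load a trial CSV in aggregated or per-trial layout.

    Aggregated: columns ``level, n_trials, n_correct``.
    Per-trial: columns ``level, choice_correct`` (0/1), aggregated here.
    """
    df = pd.read_csv(path, comment="#")
    cols = set(df.columns)
    if {"level", "n_trials", "n_correct"} <= cols:
        rows = df
    elif {"level", "choice_correct"} <= cols:
        rows = (df.groupby("level")["choice_correct"]
                .agg(n_trials="count", n_correct="sum").reset_index())
    else:
        raise ValueError(
            f"unrecognised trial table columns {sorted(cols)}; expected "
            "(level, n_trials, n_correct) or (level, choice_correct)")
    return [LevelData(float(r.level), int(r.n_trials), int(r.n_correct))
            for r in rows.itertuples()]
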