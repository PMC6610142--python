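"""Simulation-based post-hoc power analysis.

Estimates the power of Fisher exact (binary traits such as race
elimination) and Mann-Whitney (continuous traits such as age) tests to
detect a between-community difference, as a function of total cohort
size — always preserving the observed community split — or of effect
size at the observed n. The Mann-Whitney simulation draws from uniform
distributions matched to each community's mean and SD (support
mean ± sqrt(3)·SD). Required sample sizes are found by a grid pass
refined by bisection; common random numbers (one seed per evaluation)
keep estimated curves monotone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class PowerEstimate:
    power: float
    se: float           # Monte-Carlo standard error
    n_total: int
    reps: int
    alpha: float


@dataclass
class PowerCurve:
    test: str
    grid: list[float]
    power: list[float]
    se: list[float]
    alpha: float
    reps: int
    split: float
    seed: int
    params: dict = field(default_factory=dict)


@dataclass
class RequiredN:
    """Smallest n reaching the target power; ``reached`` is False when the
    target is unattainable on the grid (n is then > max(grid))."""
    n: int | None
    bracket: tuple[int, int]
    target_power: float
    reached: bool


def _split_sizes(n_total: int, split: float) -> tuple[int, int]:
    if not 0 < split < 1:
        raise ValueError("split must lie in (0, 1)")
    n1 = int(round(n_total * split))
    n2 = n_total - n1
    if n1 == 0 or n2 == 0:
        raise ValueError(f"degenerate allocation at n_total={n_total}")
    return n1, n2


def power_fisher(n_total: int, split: float, p1: float, p2: float,
                 alpha: float = 0.05, reps: int = 10_000,
                 seed: int = 0) -> PowerEstimate:
    """Monte-Carlo power of the two-sided Fisher exact test for a
    difference in success proportions between the two communities."""
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("proportions must lie in [0, 1]")
    n1, n2 = _split_sizes(n_total, split)
    rng = np.random.default_rng(seed)
    k1 = rng.binomial(n1, p1, size=reps)
    k2 = rng.binomial(n2, p2, size=reps)
    cache: dict[tuple[int, int], bool] = {}
    hits = 0
    for a, b in zip(k1, k2):
        key = (int(a), int(b))
        if key not in cache:
            p = stats.fisher_exact([[a, n1 - a], [b, n2 - b]])[1]
            cache[key] = p < alpha
        hits += cache[key]
    power = hits / reps
    return PowerEstimate(power=power, se=float(np.sqrt(power * (1 - power) / reps)),
                         n_total=n_total, reps=reps, alpha=alpha)


def power_mannwhitney(n_total: int, split: float, mean1: float, sd1: float,
                      mean2: float, sd2: float, alpha: float = 0.05,
                      reps: int = 10_000, seed: int = 0,
                      floor: float | None = None) -> PowerEstimate:
    """Monte-Carlo power of the two-sided Mann-Whitney U test for a shift
    between uniform distributions matched to each community's mean/SD.

    Uses the tie-free normal approximation with continuity correction,
    vectorized across replicates.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    n1, n2 = _split_sizes(n_total, split)
    half1, half2 = np.sqrt(3) * sd1, np.sqrt(3) * sd2
    lows = (mean1 - half1, mean2 - half2)
    if floor is not None and min(lows) < floor:
        warnings.warn(f"uniform support truncated at floor {floor}")
    rng = np.random.default_rng(seed)
    n = n1 + n2
    mu_u = n1 * n2 / 2.0
    sd_u = np.sqrt(n1 * n2 * (n + 1) / 12.0)
    hits = 0
    chunk = max(1, int(5e6 // n))
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        x = rng.uniform(mean1 - half1, mean1 + half1, size=(m, n1))
        y = rng.uniform(mean2 - half2, mean2 + half2, size=(m, n2))
        if floor is not None:
            x = np.maximum(x, floor)
            y = np.maximum(y, floor)
        data = np.concatenate([x, y], axis=1)
        # continuous draws are tie-free, so ranks = double argsort
        order = np.argsort(data, axis=1, kind="stable")
        ranks = np.empty_like(order)
        np.put_along_axis(ranks, order, np.arange(1, n + 1)[None, :], axis=1)
        u1 = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
        z = (np.abs(u1 - mu_u) - 0.5) / sd_u
        pvals = 2 * stats.norm.sf(z)
        hits += int((pvals < alpha).sum())
        done += m
    power = hits / reps
    return PowerEstimate(power=power, se=float(np.sqrt(power * (1 - power) / reps)),
                         n_total=n_total, reps=reps, alpha=alpha)


def required_n(power_fn, target_power: float = 0.9,
               n_grid=(50, 100, 200, 400, 800), reps: int = 10_000,
               seed: int = 0, resolution: int = 1) -> RequiredN:
    """Smallest total n achieving the target power.

    ``power_fn(n, reps, seed)`` must return a PowerEstimate; the same seed
    is passed at every n (common random numbers). A grid pass brackets the
    answer and integer bisection refines it down to ``resolution``
    individuals; the returned bracket is the final (below-target,
    at-target) pair.
    """
    grid = list(n_grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("n_grid must be strictly increasing")
    lo = None
    hi = None
    for ncur in grid:
        est = power_fn(ncur, reps=reps, seed=seed)
        if est.power >= target_power:
            hi = ncur
            break
        lo = ncur
    if hi is None:
        return RequiredN(n=None, bracket=(grid[-1], grid[-1]),
                         target_power=target_power, reached=False)
    if lo is None:
        return RequiredN(n=hi, bracket=(hi, hi), target_power=target_power,
                         reached=True)
    while hi - lo > max(resolution, 1):
        mid = (lo + hi) // 2
        if power_fn(mid, reps=reps, seed=seed).power >= target_power:
            hi = mid
        else:
            lo = mid
    return RequiredN(n=hi, bracket=(lo, hi), target_power=target_power,
                     reached=True)


def power_by_effect(test: str, n_total: int, split: float, params: dict,
                    effect_multipliers=(1.0, 1.5, 2.0, 3.0),
                    alpha: float = 0.05, reps: int = 10_000,
                    seed: int = 0) -> PowerCurve:
    """Power at the observed n for scaled effect sizes.

    Fisher: proportions move away from the pooled proportion,
    p_i' = pbar + m (p_i - pbar), clipped to [0, 1] with a warning.
    Mann-Whitney: the mean ratio is scaled around 1,
    mean1' = mean2 (1 + m (mean1/mean2 - 1)); SDs are kept.
    """
    powers, ses = [], []
    for m in effect_multipliers:
        if m < 0:
            raise ValueError("effect multipliers must be >= 0")
        if test == "fisher":
            p1, p2 = params["p1"], params["p2"]
            pbar = split * p1 + (1 - split) * p2
            p1m, p2m = pbar + m * (p1 - pbar), pbar + m * (p2 - pbar)
            if not (0 <= p1m <= 1 and 0 <= p2m <= 1):
                warnings.warn(f"multiplier {m}: proportions clipped to [0, 1]")
                p1m, p2m = np.clip(p1m, 0, 1), np.clip(p2m, 0, 1)
            est = power_fisher(n_total, split, p1m, p2m, alpha=alpha,
                               reps=reps, seed=seed)
        elif test == "mannwhitney":
            mean2 = params["mean2"]
            ratio = params["mean1"] / mean2
            mean1m = mean2 * (1 + m * (ratio - 1))
            est = power_mannwhitney(n_total, split, mean1m, params["sd1"],
                                    mean2, params["sd2"], alpha=alpha,
                                    reps=reps, seed=seed)
        else:
            raise ValueError(f"unknown test {test!r}")
        powers.append(est.power)
        ses.append(est.se)
    return PowerCurve(test=test, grid=list(effect_multipliers), power=powers,
                      se=ses, alpha=alpha, reps=reps, split=split, seed=seed,
                      params=dict(params))
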