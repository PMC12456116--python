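"""Permutation-based group inference and rank correlation.

Group differences in colour and pigment metrics are tested with Fisher-Pitman
permutation tests: the observed between-group statistic is compared with its
distribution under random relabelling of samples, so no distributional
assumption beyond exchangeability is needed. For k >= 3 groups the statistic
is the between-group sum of squares sum_j n_j (xbar_j - xbar)^2; for two
groups it is the absolute difference of group means (two-sided). When the
number of distinct relabellings is small the null distribution is enumerated
exactly; otherwise Monte-Carlo resampling is used with the add-one p-value
estimator p = (1 + #{perm >= obs}) / (1 + R), which cannot return zero.

Pairwise post hoc tests are Benjamini-Hochberg adjusted across the pairs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_RESAMPLES = 100_000
ENUMERATION_CAP = 200_000
_STAT_ATOL = 1e-12


@dataclass(frozen=True)
class GroupedValues:
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        l = np.asarray(self.labels)
        if v.ndim != 1 or v.shape != l.shape:
            raise ValueError("values and labels must be 1-D and equal length")
        groups, counts = np.unique(l, return_counts=True)
        if groups.size < 2:
            raise ValueError("need at least 2 groups")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", l)

    @property
    def group_sizes(self) -> dict:
        groups, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(groups.tolist(), counts.tolist()))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_resamples: int
    method: str               # "exact_enumeration" | "monte_carlo"
    seed: int | None = None


def _statistic(values: np.ndarray, sizes: np.ndarray) -> float:
    """Observed statistic for contiguous group blocks of the given sizes."""
    bounds = np.cumsum(sizes)[:-1]
    parts = np.split(values, bounds)
    if sizes.size == 2:
        return abs(parts[0].mean() - parts[1].mean())
    grand = values.mean()
    return float(sum(s * (p.mean() - grand) ** 2 for s, p in zip(sizes, parts)))


def _batch_statistic(mat: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Statistic for each row of a (R, n) matrix of permuted values."""
    bounds = np.cumsum(sizes)[:-1]
    parts = np.split(mat, bounds, axis=1)
    means = np.stack([p.mean(axis=1) for p in parts], axis=1)
    if sizes.size == 2:
        return np.abs(means[:, 0] - means[:, 1])
    grand = mat.mean(axis=1)
    return np.einsum("j,rj->r", sizes.astype(float), (means - grand[:, None]) ** 2)


def _n_relabellings(sizes: np.ndarray) -> int:
    total = math.factorial(int(sizes.sum()))
    for s in sizes:
        total //= math.factorial(int(s))
    return total


def _enumerate_stats(values: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Statistic over every distinct assignment of items to group slots."""
    n = values.size
    stats_out = []

    def recurse(remaining: tuple, assigned: list, depth: int) -> None:
        if depth == sizes.size - 1:
            perm = np.concatenate([values[list(g)] for g in assigned + [remaining]])
            stats_out.append(_statistic(perm, sizes))
            return
        for combo in itertools.combinations(remaining, int(sizes[depth])):
            rest = tuple(i for i in remaining if i not in combo)
            recurse(rest, assigned + [list(combo)], depth + 1)

    recurse(tuple(range(n)), [], 0)
    return np.asarray(stats_out)


def fisher_pitman_test(data: GroupedValues, n_resamples: int = DEFAULT_RESAMPLES,
                       seed: int | None = None,
                       enumeration_cap: int = ENUMERATION_CAP) -> TestResult:
    """Fisher-Pitman permutation test for equality of group locations."""
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    order = np.argsort(data.labels, kind="stable")
    values = data.values[order]
    _, counts = np.unique(data.labels, return_counts=True)
    sizes = counts
    observed = _statistic(values, sizes)

    if _n_relabellings(sizes) <= enumeration_cap:
        null = _enumerate_stats(values, sizes)
        p = float(np.mean(null >= observed - _STAT_ATOL))
        return TestResult(observed, p, null.size, "exact_enumeration", None)

    rng = np.random.default_rng(seed)
    n = values.size
    # permuting values and reading off contiguous blocks == relabelling
    batch = min(n_resamples, max(1, 50_000_000 // max(n, 1)))
    exceed = 0
    done = 0
    while done < n_resamples:
        b = min(batch, n_resamples - done)
        perms = rng.permuted(np.tile(values, (b, 1)), axis=1)
        null = _batch_statistic(perms, sizes)
        exceed += int(np.sum(null >= observed - _STAT_ATOL))
        done += b
    p = (1 + exceed) / (1 + n_resamples)
    return TestResult(observed, float(p), n_resamples, "monte_carlo", seed)


def pairwise_posthoc(data: GroupedValues, n_resamples: int = DEFAULT_RESAMPLES,
                     seed: int | None = None) -> pd.DataFrame:
    """All pairwise two-group permutation tests, BH-FDR adjusted over pairs."""
    groups = np.unique(data.labels)
    if groups.size < 3:
        raise ValueError("post hoc tests need >= 3 groups; use the main test")
    rows = []
    raw = []
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(
        groups.size * (groups.size - 1) // 2)]
    for (g1, g2), sub_seed in zip(itertools.combinations(groups.tolist(), 2), child_seeds):
        mask = np.isin(data.labels, [g1, g2])
        sub = GroupedValues(data.values[mask], data.labels[mask])
        res = fisher_pitman_test(sub, n_resamples=n_resamples, seed=sub_seed)
        rows.append({"group1": g1, "group2": g2, "statistic": res.statistic,
                     "p_raw": res.p_value, "method": res.method})
        raw.append(res.p_value)
    adj = bh_fdr(np.asarray(raw))
    out = pd.DataFrame(rows)
    out["p_adjusted"] = adj
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-matched to input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def spearman_corr(x, y, n_resamples: int = 0, seed: int | None = None) -> TestResult:
    """Spearman rank correlation with mid-ranks for ties.

    ``n_resamples`` > 0 gives a two-sided permutation p (one vector permuted);
    otherwise the large-sample t approximation is used and flagged in
    ``method``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D vectors with n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero variance in ranked data")
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n_resamples > 0:
        rng = np.random.default_rng(seed)
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = np.sqrt(np.sum(rxc**2) * np.sum(ryc**2))
        perms = rng.permuted(np.tile(ryc, (n_resamples, 1)), axis=1)
        null_rho = perms @ rxc / denom
        exceed = int(np.sum(np.abs(null_rho) >= abs(rho) - _STAT_ATOL))
        p = (1 + exceed) / (1 + n_resamples)
        return TestResult(rho, float(p), n_resamples, "monte_carlo", seed)

    n = x.size
    if abs(rho) >= 1.0:
        p = 0.0 if n > 2 else 1.0
        p = max(p, np.finfo(float).tiny)
    else:
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return TestResult(rho, min(p, 1.0), 0, "t_approximation", None)
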