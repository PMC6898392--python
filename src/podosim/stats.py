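"""Nonparametric statistics and fits for group comparisons.

Two-group comparisons use the Mann-Whitney U test (exact for small samples,
normal approximation with tie correction otherwise); three or more groups
use Kruskal-Wallis with Dunn's post-hoc z tests (Holm-adjusted by default);
monotone association uses Spearman's rank correlation; trajectories and the
density-albuminuria relationship use ordinary least squares.  All tests are
two-sided.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "FitResult",
    "mann_whitney_u",
    "kruskal_wallis_dunn",
    "spearman_rho",
    "linear_fit",
    "fold_change",
]

EXACT_MAX_N = 16  # largest combined sample for exact Mann-Whitney enumeration


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    method: str
    pairwise: dict | None = field(default=None)

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class FitResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def _exact_mw_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of group labelings.

    Handles ties correctly by enumerating all C(n, n1) assignments of the
    pooled sample and counting labelings at least as extreme (in |U - mean|)
    as the observed one.
    """
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    mu = n1 * len(y) / 2.0
    r1_obs = ranks[:n1].sum()
    u_obs = r1_obs - n1 * (n1 + 1) / 2.0
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        r1 = ranks[list(comb)].sum()
        u = r1 - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


def mann_whitney_u(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode`` is 'exact' (combined n <= 16), 'asymptotic' (normal
    approximation with tie correction and continuity correction), or 'auto'
    (exact when the combined sample is small enough, else asymptotic).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n = x.size + y.size
    if mode not in {"auto", "exact", "asymptotic"}:
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and n <= EXACT_MAX_N)
    if use_exact and n > EXACT_MAX_N:
        raise ValueError(f"exact mode limited to combined n <= {EXACT_MAX_N}")
    ties = np.unique(np.concatenate([x, y])).size < n
    if use_exact:
        if ties:
            u = float(sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic)
            p = _exact_mw_pvalue(x, y)
            method = "exact enumeration (ties)"
        else:
            res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            u, p = float(res.statistic), float(res.pvalue)
            method = "exact"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        method = "normal approximation, tie-corrected"
    return TestResult(
        name="Mann-Whitney U",
        statistic=u,
        p_value=p,
        n_per_group=(x.size, y.size),
        method=method,
    )


def kruskal_wallis_dunn(groups, adjust: str = "holm") -> TestResult:
    """Kruskal-Wallis H (tie-corrected) with Dunn's pairwise post-hoc tests.

    Dunn z statistics use the pooled-rank variance with tie correction;
    pairwise p-values are adjusted for multiplicity (Holm by default, or any
    method statsmodels' multipletests accepts, or 'none').
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need >= 3 groups; use mann_whitney_u for two")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        h, p_kw = 0.0, 1.0
    else:
        h, p_kw = (float(v) for v in sps.kruskal(*groups))

    n_tot = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in groups]
    mean_ranks = []
    start = 0
    for s in sizes:
        mean_ranks.append(ranks[start : start + s].mean())
        start += s
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term

    pairs, zs, ps = [], [], []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        pairs.append((i, j))
        zs.append(z)
        ps.append(2.0 * sps.norm.sf(abs(z)))
    if adjust and adjust != "none":
        ps_adj = list(multipletests(ps, method=adjust)[1])
    else:
        ps_adj = list(ps)
    pairwise = {
        pair: {"z": z, "p_unadjusted": p, "p_adjusted": pa}
        for pair, z, p, pa in zip(pairs, zs, ps, ps_adj)
    }
    return TestResult(
        name="Kruskal-Wallis + Dunn",
        statistic=h,
        p_value=p_kw,
        n_per_group=tuple(sizes),
        method=f"tie-corrected H; Dunn z, {adjust} adjustment",
        pairwise=pairwise,
    )


def _exact_spearman_pvalue(rho_obs: float, rx: np.ndarray, ry: np.ndarray) -> float:
    """Exact two-sided permutation p for Spearman rho (tie-free, n <= 9)."""
    n = rx.size
    denom = n * (n**2 - 1)
    count = total = 0
    for perm in itertools.permutations(ry):
        d2 = float(np.sum((rx - np.array(perm)) ** 2))
        rho = 1.0 - 6.0 * d2 / denom
        total += 1
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def spearman_rho(x, y, exact_max_n: int = 9) -> TestResult:
    """Spearman rank correlation with two-sided p.

    Exact permutation p for tie-free samples with n <= ``exact_max_n``,
    otherwise the t approximation.  Constant input yields an undefined rho
    (NaN) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input; Spearman rho undefined")
        return TestResult(
            name="Spearman rho",
            statistic=float("nan"),
            p_value=float("nan"),
            n_per_group=(x.size,),
            method="undefined (constant input)",
        )
    rho, p = sps.spearmanr(x, y)
    rho, p = float(rho), float(p)
    ties = np.unique(x).size < x.size or np.unique(y).size < y.size
    method = "t approximation"
    if x.size <= exact_max_n and not ties:
        p = _exact_spearman_pvalue(rho, sps.rankdata(x), sps.rankdata(y))
        method = "exact permutation"
    return TestResult(
        name="Spearman rho",
        statistic=rho,
        p_value=p,
        n_per_group=(x.size,),
        method=method,
    )


def linear_fit(x, y) -> FitResult:
    """Ordinary least-squares line with R^2.

    Constant y is a well-defined degenerate case (slope 0, R^2 = 0);
    constant x is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    if np.ptp(y) == 0:
        return FitResult(slope=0.0, intercept=float(y[0]), r_squared=0.0, p_value=1.0, n=x.size)
    fit = sps.linregress(x, y)
    return FitResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=x.size,
    )


def fold_change(group: np.ndarray, reference: np.ndarray) -> float:
    """Ratio of group means: mean(group) / mean(reference)."""
    group = np.asarray(group, dtype=float)
    reference = np.asarray(reference, dtype=float)
    ref_mean = reference.mean()
    if ref_mean <= 0:
        raise ValueError("reference group mean must be positive")
    return float(group.mean() / ref_mean)
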