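"""Community-level statistics for OPU tables.

Implements the ordination/testing layer of the pipeline: Wisconsin double
standardization, Bray-Curtis dissimilarity, nonmetric multidimensional
scaling (Kruskal stress-1 with pool-adjacent-violators monotone regression),
ANOSIM, exact Mann-Whitney and Spearman tests with enumeration-backed small-
sample null distributions, the Wilcoxon signed-rank normal approximation,
and an ANCOM-style W statistic for differentially abundant OPUs.

Orientation convention: abundance tables are samples x OPUs (sites as rows),
matching the usual community-ecology layout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm, rankdata, t as t_dist
from statsmodels.stats.multitest import multipletests

_TINY_P = 1e-300


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    alternative: str = "two-sided"
    n_permutations: int | None = None
    exact: bool = False
    z: float | None = None

    def __post_init__(self):
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x k, centered at the origin
    stress: float
    n_starts: int
    best_start: int
    converged: bool
    seed: int | None
    stress_history: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Standardization and dissimilarity
# ---------------------------------------------------------------------------

def wisconsin(table: pd.DataFrame) -> pd.DataFrame:
    """Wisconsin double standardization: divide each entry by its column
    (OPU) maximum, then by its row (sample) total. Output rows sum to 1."""
    values = table.to_numpy(dtype=float)
    if (values < 0).any():
        raise StatsError("negative abundances")
    col_max = values.max(axis=0)
    zero_cols = np.flatnonzero(col_max == 0)
    if zero_cols.size:
        raise StatsError(
            f"all-zero column(s): {list(table.columns[zero_cols[:3]])}"
        )
    values = values / col_max
    row_tot = values.sum(axis=1, keepdims=True)
    if (row_tot == 0).any():
        raise StatsError("sample with zero total after column standardization")
    return pd.DataFrame(values / row_tot, index=table.index, columns=table.columns)


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples (rows):
    d(i,j) = sum|x_ik - x_jk| / sum(x_ik + x_jk)."""
    values = table.to_numpy(dtype=float)
    if (values < 0).any():
        raise StatsError("negative abundances")
    condensed = pdist(values, metric="braycurtis")
    if np.isnan(condensed).any():
        raise StatsError("Bray-Curtis undefined for a pair of all-zero samples")
    return pd.DataFrame(squareform(condensed), index=table.index,
                        columns=table.index)


# ---------------------------------------------------------------------------
# Nonmetric multidimensional scaling
# ---------------------------------------------------------------------------

def _monotone_fit(dist: np.ndarray, order_codes: np.ndarray,
                  block_sizes: np.ndarray) -> np.ndarray:
    """Isotonic (PAVA) fit of embedded distances against the dissimilarity
    order. Tied dissimilarities are pooled into one block whose fitted value
    is shared (ties averaged)."""
    nblocks = len(block_sizes)
    sums = np.bincount(order_codes, weights=dist, minlength=nblocks)
    block_means = sums / block_sizes
    fit = isotonic_regression(block_means, weights=block_sizes, increasing=True)
    return fit.x[order_codes]


def _stress(dist: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((dist**2).sum())
    if denom == 0:
        return 0.0
    return math.sqrt(float(((dist - dhat) ** 2).sum()) / denom)


def nmds(
    dissim: pd.DataFrame | np.ndarray,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
) -> OrdinationResult:
    """NMDS minimizing Kruskal stress-1.

    Alternates pool-adjacent-violators monotone regression of the embedded
    distances on the dissimilarity ranks with backtracking gradient steps on
    the configuration, so stress is non-increasing within a start; the best
    of ``n_starts`` random initializations is reported, centered at the
    origin.
    """
    D = np.asarray(dissim, dtype=float) if not isinstance(dissim, pd.DataFrame) else dissim.to_numpy(dtype=float)
    index = dissim.index if isinstance(dissim, pd.DataFrame) else pd.RangeIndex(D.shape[0])
    n = D.shape[0]
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise StatsError("dissimilarity matrix must be square and symmetric")
    if n < k + 1:
        raise StatsError(f"need at least k+1={k + 1} samples")
    iu = np.triu_indices(n, 1)
    d_obs = D[iu]
    # tie blocks in the observed dissimilarities, in ascending order
    uniq, order_codes = np.unique(d_obs, return_inverse=True)
    block_sizes = np.bincount(order_codes).astype(float)

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, int, bool, list[float]] | None = None
    for start in range(n_starts):
        y = rng.normal(size=(n, k))
        converged = False
        history: list[float] = []
        dist = np.maximum(pdist(y), 1e-12)
        dhat = _monotone_fit(dist, order_codes, block_sizes)
        stress = _stress(dist, dhat)
        history.append(stress)
        for _ in range(max_iter):
            # gradient of stress^2 w.r.t. the configuration, dhat held fixed
            T = float((dist**2).sum())
            resid = (dist - dhat) - stress**2 * dist
            R = squareform(resid / dist)
            diff = y[:, None, :] - y[None, :, :]
            grad = (2.0 / T) * (R[:, :, None] * diff).sum(axis=1)
            gnorm = float(np.sqrt((grad**2).sum()))
            if gnorm == 0:
                converged = True
                break
            alpha = 0.2 * float(np.sqrt((y**2).sum())) / gnorm
            improved = False
            for _half in range(40):
                y_try = y - alpha * grad
                dist_try = np.maximum(pdist(y_try), 1e-12)
                dhat_try = _monotone_fit(dist_try, order_codes, block_sizes)
                stress_try = _stress(dist_try, dhat_try)
                if stress_try <= stress:
                    improved = True
                    break
                alpha /= 2.0
            if not improved:
                converged = True
                break
            y, dist, dhat = y_try, dist_try, dhat_try
            delta = stress - stress_try
            stress = stress_try
            history.append(stress)
            if delta < tol * max(stress, 1e-12):
                converged = True
                break
        y = y - y.mean(axis=0)
        if best is None or stress < best[0]:
            best = (stress, y, start, converged, history)

    stress, y, start, converged, history = best
    coords = pd.DataFrame(
        y, index=index, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(coords, stress, n_starts, start, converged, seed, history)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def _anosim_r(rank_condensed: np.ndarray, within: np.ndarray) -> float:
    n_pairs = len(rank_condensed)
    r_within = rank_condensed[within].mean()
    r_between = rank_condensed[~within].mean()
    return float((r_between - r_within) / (n_pairs / 2.0))


def _distinct_label_permutations(labels: Sequence) -> list[np.ndarray]:
    """All distinct assignments of the multiset of labels to positions."""
    labels = list(labels)
    n = len(labels)
    values = sorted(set(labels), key=str)
    counts = {v: labels.count(v) for v in values}
    out: list[np.ndarray] = []
    assign = np.empty(n, dtype=object)

    def rec(positions: list[int], vi: int) -> None:
        if vi == len(values) - 1:
            for p in positions:
                assign[p] = values[vi]
            out.append(assign.copy())
            return
        v = values[vi]
        for chosen in itertools.combinations(positions, counts[v]):
            rest = [p for p in positions if p not in set(chosen)]
            for p in chosen:
                assign[p] = v
            rec(rest, vi + 1)

    rec(list(range(n)), 0)
    return out


def anosim(
    dissim: pd.DataFrame | np.ndarray,
    groups: Mapping[str, str] | Sequence,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "auto",
) -> TestResult:
    """ANOSIM: R = (mean between-group rank - mean within-group rank)
    scaled by M/2 with M = n(n-1)/2 pairs, so R = 1 under complete
    separation.

    ``method='exact'`` enumerates every distinct label assignment (used
    automatically when there are at most 1000); otherwise the p-value is the
    permutation estimate (1 + #{R_perm >= R_obs}) / (1 + n_perm).
    """
    D = dissim.to_numpy(dtype=float) if isinstance(dissim, pd.DataFrame) else np.asarray(dissim, float)
    n = D.shape[0]
    if isinstance(groups, Mapping):
        if not isinstance(dissim, pd.DataFrame):
            raise StatsError("mapping groups require a labeled DataFrame")
        labels = [groups[s] for s in dissim.index]
    else:
        labels = list(groups)
    if len(labels) != n:
        raise StatsError("group labels do not match the matrix size")
    sizes = pd.Series(labels).value_counts()
    if len(sizes) < 2:
        raise StatsError("ANOSIM needs at least two groups")
    if (sizes < 2).any():
        raise StatsError("every group needs at least two members")

    iu = np.triu_indices(n, 1)
    ranks = rankdata(D[iu])  # mid-ranks for ties
    lab = np.asarray(labels, dtype=object)

    def r_for(assign: np.ndarray) -> float:
        within = assign[iu[0]] == assign[iu[1]]
        return _anosim_r(ranks, within)

    r_obs = r_for(lab)

    if method == "auto":
        n_exact = math.factorial(n)
        for c in sizes:
            n_exact //= math.factorial(c)
        method = "exact" if n_exact <= 1000 else "permutation"

    if method == "exact":
        perms = _distinct_label_permutations(labels)
        count = sum(1 for a in perms if r_for(a) >= r_obs - 1e-12)
        return TestResult("anosim", r_obs, count / len(perms),
                          alternative="greater", n_permutations=len(perms),
                          exact=True)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if r_for(rng.permutation(lab)) >= r_obs - 1e-12:
            hits += 1
    return TestResult("anosim", r_obs, (1 + hits) / (1 + n_perm),
                      alternative="greater", n_permutations=n_perm)


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

@lru_cache(maxsize=128)
def _u_null_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Counts of arrangements by U statistic under the tie-free null
    (recursion N(a,b,u) = N(a-1,b,u-b) + N(a,b-1,u))."""
    table: dict[tuple[int, int], np.ndarray] = {}
    for a in range(n1 + 1):
        for b in range(n2 + 1):
            if a == 0 or b == 0:
                table[(a, b)] = np.ones(1, dtype=object)
                continue
            size = a * b + 1
            arr = np.zeros(size, dtype=object)
            prev_a = table[(a - 1, b)]
            arr[b:b + len(prev_a)] += prev_a
            prev_b = table[(a, b - 1)]
            arr[:len(prev_b)] += prev_b
            table[(a, b)] = arr
    return tuple(int(v) for v in table[(n1, n2)])


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_max_n: int = 25,
) -> TestResult:
    """Mann-Whitney U test. The statistic is U for ``x`` (number of (x, y)
    pairs with x > y, ties counting one half).

    The p-value is exact (dynamic-programming null distribution) for
    tie-free data with n1+n2 <= ``exact_max_n``, otherwise a tie-corrected
    normal approximation with continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise StatsError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise StatsError(f"unknown alternative {alternative!r}")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    has_ties = len(np.unique(pooled)) < len(pooled)

    if not has_ties and n1 + n2 <= exact_max_n:
        counts = np.array(_u_null_counts(n1, n2), dtype=float)
        total = counts.sum()
        ui = int(round(u))
        p_ge = counts[ui:].sum() / total
        p_le = counts[: ui + 1].sum() / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return TestResult("mann-whitney", u, max(p, _TINY_P), alternative,
                          exact=True)

    # tie-corrected normal approximation with continuity correction
    nt = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (nt * (nt - 1))
    sigma2 = n1 * n2 / 12.0 * ((nt + 1) - tie_term)
    if sigma2 <= 0:
        raise StatsError("degenerate data: all values tied")
    mu = n1 * n2 / 2.0
    sigma = math.sqrt(sigma2)
    if alternative == "greater":
        z = (u - mu - 0.5) / sigma
        p = norm.sf(z)
    elif alternative == "less":
        z = (u - mu + 0.5) / sigma
        p = norm.cdf(z)
    else:
        z = (u - mu - math.copysign(0.5, u - mu)) / sigma if u != mu else 0.0
        p = 2.0 * norm.sf(abs(z))
    return TestResult("mann-whitney", u, min(max(p, _TINY_P), 1.0),
                      alternative, z=float(z))


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Paired Wilcoxon signed-rank test (two-sided), normal approximation
    with tie-corrected variance and no continuity correction. Zero
    differences are dropped; all-zero differences are an error."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise StatsError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise StatsError("all paired differences are zero")
    r = rankdata(np.abs(d))
    w_plus = float(r[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if sigma2 <= 0:
        raise StatsError("degenerate variance in signed-rank test")
    z = (w_plus - mu) / math.sqrt(sigma2)
    p = 2.0 * norm.sf(abs(z))
    return TestResult("wilcoxon-signed-rank", w_plus,
                      min(max(p, _TINY_P), 1.0), z=float(z))


def spearman(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 9
) -> TestResult:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    For tie-free samples with n <= ``exact_max_n`` the two-sided p-value is
    exact by enumeration over all rank permutations; otherwise the
    t approximation with n-2 degrees of freedom is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise StatsError("need equal-length samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise StatsError("constant input vector")
    n = len(x)
    rx, ry = rankdata(x), rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    has_ties = len(np.unique(x)) < n or len(np.unique(y)) < n

    if not has_ties and n <= exact_max_n:
        perms = np.array(list(itertools.permutations(range(n))), dtype=float)
        d2 = ((perms - np.arange(n)) ** 2).sum(axis=1)
        rho_perm = 1.0 - 6.0 * d2 / (n * (n**2 - 1))
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
        return TestResult("spearman", rho, max(p, _TINY_P), exact=True)

    if abs(rho) >= 1.0:
        return TestResult("spearman", rho, _TINY_P)
    tstat = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * t_dist.sf(abs(tstat), df=n - 2)
    return TestResult("spearman", rho, min(max(p, _TINY_P), 1.0))


# ---------------------------------------------------------------------------
# ANCOM-style differential abundance
# ---------------------------------------------------------------------------

def ancom_w(
    table: pd.DataFrame,
    groups: Mapping[str, str] | Sequence,
    alpha: float = 0.05,
    detect_frac: float = 0.7,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """ANCOM-style W statistic for two-group differential OPU abundance.

    For each OPU i, every additive log-ratio log((x_i + c)/(x_j + c)) with
    j != i is compared across the two groups by a rank-sum test;
    Benjamini-Hochberg correction is applied within OPU i across its m-1
    ratios, and W_i counts the rejections at ``alpha``. OPU i is flagged as
    detected when W_i >= ``detect_frac`` * (m - 1).

    ``table`` is samples x OPUs. Returns a DataFrame indexed by OPU with
    columns ``W`` and ``detected``.
    """
    if table.shape[1] < 2:
        raise StatsError("ANCOM needs at least two OPUs")
    if isinstance(groups, Mapping):
        labels = pd.Series([groups[s] for s in table.index], index=table.index)
    else:
        labels = pd.Series(list(groups), index=table.index)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise StatsError("ANCOM here compares exactly two groups")
    mask_a = (labels == uniq[0]).to_numpy()
    mask_b = (labels == uniq[1]).to_numpy()
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise StatsError("each group needs at least 3 samples")

    logx = np.log(table.to_numpy(dtype=float) + pseudocount)
    m = logx.shape[1]
    pmat = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            lr = logx[:, i] - logx[:, j]
            res = mann_whitney(lr[mask_a], lr[mask_b], alternative="two-sided")
            pmat[i, j] = pmat[j, i] = res.p_value
    w = np.zeros(m, dtype=int)
    for i in range(m):
        pvals = np.delete(pmat[i], i)
        reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        w[i] = int(reject.sum())
    detected = w >= detect_frac * (m - 1)
    return pd.DataFrame({"W": w, "detected": detected}, index=table.columns)
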