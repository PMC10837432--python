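"""Permutational and classical statistics used by the pipeline.

Implements, from first principles, the tests applied to the tracer
responses: one-factor PERMANOVA on a distance matrix (with sequential
multi-factor partitioning), pairwise PERMANOVA with Bonferroni correction,
the tie-corrected Kruskal-Wallis test (with an exact enumeration p for
small samples), and Welch's unequal-variance t-test.

PERMANOVA partitions the sums of squares of a distance matrix.  For a
one-way design with a groups and n observations,

    SS_total  = (1/n)  sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2
    pseudo-F  = (SS_between/(a-1)) / (SS_within/(n-a))

which for Euclidean distances on univariate data is algebraically the
classical one-way ANOVA F.  The permutation p-value uses the convention of
counting the observed statistic into its own null set:
p = (#{F_perm >= F_obs} + 1) / (B + 1), so p is confined to
[1/(B+1), 1].  When the space of distinct label arrangements is small the
null is enumerated exhaustively (and p is then exact, count/m); otherwise
B distinct arrangements are rejection-sampled without replacement
("unique permutations").

scipy supplies only reference distributions (chi2, t) and rank utilities;
every test statistic here is computed in this module.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "euclidean_dist",
    "check_distance_matrix",
    "PermanovaResult",
    "permanova",
    "permanova_terms",
    "pairwise_permanova",
    "KWResult",
    "kruskal_wallis",
    "TTestResult",
    "welch_t",
]

# Exhaustive enumeration is used when the arrangement space is below both
# this hard cap and 10x the requested permutation count.
_ENUMERATION_CAP = 100_000


# ---------------------------------------------------------------------------
# distances


def euclidean_dist(values) -> np.ndarray:
    """Pairwise Euclidean distance matrix for n observations.

    ``values`` may be 1-D (univariate responses) or 2-D (n x p).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 1-D or 2-D array with >= 2 observations")
    if np.any(~np.isfinite(x)):
        raise ValueError("non-finite values in input")
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def check_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(~np.isfinite(d)) or np.any(d < 0):
        raise ValueError("distances must be finite and non-negative")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass(frozen=True)
class PermanovaResult:
    factor: str
    pseudo_f: float
    r2: float
    p_perm: float
    permutations: int          # null-set size actually used (B, or m if exact)
    ss_total: float
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    method: str                # "exact" | "sampled-unique" | "sampled"
    degenerate: bool = False
    groups: tuple = field(default_factory=tuple)
    p_adjusted: Optional[float] = None


def _encode_labels(labels):
    labels = np.asarray(labels)
    uniq, codes = np.unique(labels, return_inverse=True)
    return uniq, codes.astype(np.intp)


def _ss_partition(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    return ss_total, ss_within


def _pseudo_f(ss_total, ss_within, a, n):
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return math.inf if ss_between > 0 else 0.0
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def _arrangement_count(counts: Sequence[int]) -> int:
    total = sum(counts)
    m = math.factorial(total)
    for c in counts:
        m //= math.factorial(c)
    return m


def _multiset_permutations(codes):
    """Yield every distinct arrangement of a multiset exactly once
    (lexicographic next-permutation walk)."""
    arr = sorted(codes)
    n = len(arr)
    while True:
        yield tuple(arr)
        i = n - 2
        while i >= 0 and arr[i] >= arr[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while arr[j] <= arr[i]:
            j -= 1
        arr[i], arr[j] = arr[j], arr[i]
        arr[i + 1:] = reversed(arr[i + 1:])


def _distinct_arrangements(codes: np.ndarray):
    """All distinct arrangements of the label multiset, as an array."""
    return np.asarray(list(_multiset_permutations(codes.tolist())), dtype=np.intp)


def _sample_unique_permutations(codes: np.ndarray, b: int, rng: np.random.Generator):
    """b distinct label arrangements drawn by rejection sampling."""
    n = codes.size
    out = np.empty((b, n), dtype=np.intp)
    seen = set()
    filled = 0
    while filled < b:
        batch = rng.permuted(np.tile(codes, (b, 1)), axis=1)
        for row in batch:
            key = row.tobytes()
            if key in seen:
                continue
            seen.add(key)
            out[filled] = row
            filled += 1
            if filled == b:
                break
    return out


def _perm_f_values(d2: np.ndarray, label_rows: np.ndarray, counts: np.ndarray,
                   ss_total: float):
    """Vectorised pseudo-F for many label arrangements on one matrix."""
    n = d2.shape[0]
    a = counts.size
    ssw = np.zeros(label_rows.shape[0])
    for g in range(a):
        m = (label_rows == g).astype(float)
        ssw += np.einsum("bi,ij,bj->b", m, d2, m) / (2.0 * counts[g])
    ssb = ss_total - ssw
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (a - 1)) / (ssw / (n - a))
    f[ssw <= 0] = np.inf
    f[(ssw <= 0) & (ssb <= 0)] = 0.0
    return f


def permanova(dist, labels, permutations: int = 999, seed=None,
              factor: str = "factor") -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    ``dist`` is an n x n distance matrix; ``labels`` assigns each of the n
    observations to a group.  The permutation null freely shuffles labels;
    arrangements are unique (drawn without replacement) whenever the
    arrangement space allows, and the null is enumerated exhaustively when
    it is small.
    """
    d = check_distance_matrix(dist)
    uniq, codes = _encode_labels(labels)
    n = d.shape[0]
    if codes.size != n:
        raise ValueError("labels length must match distance matrix size")
    a = uniq.size
    if a < 2:
        raise ValueError("need at least 2 groups")
    if permutations < 1:
        raise ValueError("need at least 1 permutation")
    counts = np.bincount(codes, minlength=a)

    d2 = d ** 2
    ss_total, ss_within = _ss_partition(d2, codes, a)
    ss_between = ss_total - ss_within

    if ss_total <= 1e-12 * max(1.0, float(np.max(d2))) or ss_total == 0.0:
        # every observation identical: no variation to partition
        return PermanovaResult(
            factor=factor, pseudo_f=0.0, r2=0.0, p_perm=1.0,
            permutations=permutations, ss_total=ss_total,
            ss_between=0.0, ss_within=ss_within,
            df_between=a - 1, df_within=n - a, method="degenerate",
            degenerate=True, groups=tuple(uniq.tolist()))

    f_obs = _pseudo_f(ss_total, ss_within, a, n)
    r2 = ss_between / ss_total

    m = _arrangement_count(counts.tolist())
    rng = np.random.default_rng(seed)
    if m <= min(10 * permutations, _ENUMERATION_CAP):
        rows = _distinct_arrangements(codes)
        f_null = _perm_f_values(d2, rows, counts, ss_total)
        # the observed arrangement is one of the enumerated ones
        p = float(np.count_nonzero(f_null >= f_obs - 1e-12)) / m
        used, method = m, "exact"
    else:
        rows = _sample_unique_permutations(codes, permutations, rng)
        f_null = _perm_f_values(d2, rows, counts, ss_total)
        p = (float(np.count_nonzero(f_null >= f_obs - 1e-12)) + 1.0) / (permutations + 1.0)
        used, method = permutations, "sampled-unique"

    return PermanovaResult(
        factor=factor, pseudo_f=float(f_obs), r2=float(r2), p_perm=float(p),
        permutations=used, ss_total=float(ss_total),
        ss_between=float(ss_between), ss_within=float(ss_within),
        df_between=a - 1, df_within=n - a, method=method,
        groups=tuple(uniq.tolist()))


def _hat_matrix(x: np.ndarray) -> np.ndarray:
    # projection onto the column space of x (pseudo-inverse handles rank
    # deficiency from dummy coding)
    return x @ np.linalg.pinv(x)


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    c = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * c @ d2 @ c


def permanova_terms(dist, factors, permutations: int = 999, seed=None):
    """Sequential (Type-I) multi-factor PERMANOVA.

    ``factors`` is a mapping or DataFrame of factor name -> labels.  Terms
    are added in the given order; each term's SS is the increment in
    explained SS (trace of the hat-projected Gower-centred matrix), tested
    against the residual of the full model.  The permutation null is free
    row permutation — an approximation to residual permutation under the
    reduced model, acceptable for the balanced designs used here.
    Returns one :class:`PermanovaResult` per factor.
    """
    import pandas as pd

    if isinstance(factors, pd.DataFrame):
        items = [(str(c), factors[c].to_numpy()) for c in factors.columns]
    else:
        items = [(str(k), np.asarray(v)) for k, v in dict(factors).items()]
    if not items:
        raise ValueError("need at least one factor")

    d = check_distance_matrix(dist)
    n = d.shape[0]
    g = _gower_center(d ** 2)
    ss_total = float(np.trace(g))

    def dummies(labels):
        _, codes = _encode_labels(labels)
        k = codes.max() + 1
        return np.eye(k)[codes]

    # design matrices: intercept, then cumulative factor blocks
    blocks = [np.ones((n, 1))]
    dfs = []
    for _, lab in items:
        x = dummies(lab)
        blocks.append(x)
        dfs.append(len(np.unique(lab)) - 1)

    def term_ss(gmat):
        out = []
        prev = _hat_matrix(blocks[0])
        prev_tr = float(np.trace(prev @ gmat))
        for i in range(1, len(blocks)):
            h = _hat_matrix(np.hstack(blocks[: i + 1]))
            tr = float(np.trace(h @ gmat))
            out.append(tr - prev_tr)
            prev_tr = tr
        return out, float(np.trace(gmat)) - prev_tr

    ss_terms, ss_resid = term_ss(g)
    df_resid = n - 1 - sum(dfs)
    if df_resid <= 0:
        raise ValueError("model saturates the design: no residual df")

    f_obs = [
        (ss / df) / (ss_resid / df_resid) if ss_resid > 0 else math.inf
        for ss, df in zip(ss_terms, dfs)
    ]

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(items))
    for _ in range(permutations):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ssp, ssr = term_ss(gp)
        for i, (ss, df) in enumerate(zip(ssp, dfs)):
            fp = (ss / df) / (ssr / df_resid) if ssr > 0 else math.inf
            if fp >= f_obs[i] - 1e-12:
                exceed[i] += 1

    results = []
    for i, (name, _) in enumerate(items):
        results.append(PermanovaResult(
            factor=name, pseudo_f=float(f_obs[i]),
            r2=float(ss_terms[i] / ss_total) if ss_total > 0 else 0.0,
            p_perm=float((exceed[i] + 1) / (permutations + 1)),
            permutations=permutations, ss_total=ss_total,
            ss_between=float(ss_terms[i]), ss_within=float(ss_resid),
            df_between=dfs[i], df_within=df_resid, method="sampled",
        ))
    return results


def pairwise_permanova(dist, labels, permutations: int = 999, seed=None,
                       correction: str = "bonferroni"):
    """PERMANOVA on every unordered pair of groups, Bonferroni-adjusted.

    p_adj = min(1, p * m) with m the number of pairs tested.
    """
    if correction != "bonferroni":
        raise ValueError("only Bonferroni correction is supported")
    d = check_distance_matrix(dist)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    pairs = list(itertools.combinations(uniq.tolist(), 2))
    m = len(pairs)
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    child_seeds = ss.spawn(m)
    results = []
    for (ga, gb), cs in zip(pairs, child_seeds):
        idx = np.flatnonzero((labels == ga) | (labels == gb))
        sub = d[np.ix_(idx, idx)]
        res = permanova(sub, labels[idx], permutations=permutations,
                        seed=cs, factor=f"{ga} vs {gb}")
        results.append(PermanovaResult(
            **{**res.__dict__, "p_adjusted": min(1.0, res.p_perm * m)}))
    return results


# ---------------------------------------------------------------------------
# Kruskal-Wallis


@dataclass(frozen=True)
class KWResult:
    h: float
    df: int
    p_chi2: float
    p_exact: Optional[float]      # exhaustive permutation p (small n only)
    n: int
    tie_correction: float
    degenerate: bool = False


def _kw_h(values: np.ndarray, codes: np.ndarray, a: int) -> float:
    n = values.size
    ranks = sps.rankdata(values)
    h = 0.0
    for g in range(a):
        rg = ranks[codes == g]
        h += rg.size * (rg.mean() - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    _, tie_counts = np.unique(values, return_counts=True)
    t = float(np.sum(tie_counts ** 3 - tie_counts))
    corr = 1.0 - t / (n ** 3 - n)
    if corr <= 0:
        return 0.0  # all values tied
    return h / corr


def kruskal_wallis(groups, exact_max_n: int = 10) -> KWResult:
    """Tie-corrected Kruskal-Wallis rank test across >= 2 groups.

    H = [12/(N(N+1))] * sum n_i (Rbar_i - (N+1)/2)^2, divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N).  p is from the chi-squared
    approximation with df = a-1; for N <= ``exact_max_n`` an exact p from
    exhaustive enumeration of group assignments is also reported.
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    values = np.concatenate(arrays)
    n = values.size
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    codes = np.concatenate([np.full(a.size, i, dtype=np.intp)
                            for i, a in enumerate(arrays)])
    a = len(arrays)

    _, tie_counts = np.unique(values, return_counts=True)
    all_tied = tie_counts.size == 1
    h = 0.0 if all_tied else _kw_h(values, codes, a)
    corr = 1.0 - float(np.sum(tie_counts ** 3 - tie_counts)) / (n ** 3 - n)
    p_chi2 = float(sps.chi2.sf(h, a - 1))

    p_exact = None
    if n <= exact_max_n and not all_tied:
        count = 0
        total = 0
        for arrangement in _multiset_permutations(codes.tolist()):
            total += 1
            if _kw_h(values, np.asarray(arrangement, dtype=np.intp), a) >= h - 1e-12:
                count += 1
        p_exact = count / total

    return KWResult(h=float(h), df=a - 1, p_chi2=p_chi2, p_exact=p_exact,
                    n=n, tie_correction=float(corr), degenerate=all_tied)


# ---------------------------------------------------------------------------
# Welch's t


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_t(a, b) -> TTestResult:
    """Welch's unequal-variance two-sample t-test (two-sided).

    Degrees of freedom by Welch-Satterthwaite; fractional df are the
    norm, matching t statistics reported with non-integer subscripts.
    """
    x = np.asarray(a, dtype=float).ravel()
    y = np.asarray(b, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    vx = x.var(ddof=1) / x.size
    vy = y.var(ddof=1) / y.size
    if vx + vy == 0:
        # no variance anywhere: identical constants
        return TTestResult(t=0.0, df=float(x.size + y.size - 2), p=1.0,
                           degenerate=True)
    t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx ** 2 / (x.size - 1) + vy ** 2 / (y.size - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=float(df), p=p)
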