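"""Nonparametric inference engine: Monte-Carlo permutation tests.

All hypothesis tests in the pipeline are permutation-based: the observed
statistic (t, F, rank correlation, or a difference of cell means) is compared
against a null distribution built by shuffling the exchangeable labels of the
design.  Monte-Carlo p-values include the observed labelling in the null
count, ``p = (1 + #{|s_perm| >= |s_obs|}) / (n_perm + 1)``, so p can never be
exactly zero and the estimator is valid at any permutation count.

Multiple comparisons over channel families are handled by Benjamini-Hochberg
FDR; comparisons over time-window series by a cluster-size Monte-Carlo
correction that binarizes the p-value series at alpha, measures runs of
significance, and compares them against the maximum-run distribution of
shuffled binary series.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class StatsConfig:
    """Shared settings for all permutation tests.

    ``alpha`` is the per-test significance level, ``n_permutations`` the
    Monte-Carlo iteration count, ``mcs_p`` the cluster-correction tail
    (cluster sizes must exceed the ``1 - mcs_p`` quantile of the null
    maximum-run distribution), ``fdr_alpha`` the FDR level.
    """

    alpha: float = 0.05
    n_permutations: int = 10000
    mcs_p: float = 0.001
    fdr_alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutation iterations")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class StatResult:
    statistic: float
    df: tuple
    p_mc: float
    n_permutations: int
    tails: int = 2
    kind: str = "t"
    seed: int | None = None
    flags: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)


@dataclass
class ClusterResult:
    clusters: list            # (start, end_exclusive, size) index triples
    significant: list         # bool per cluster
    threshold_size: float     # (1 - mcs_p) quantile of null max run lengths
    cluster_p: list           # tail proportion of null max runs >= size
    null_max_sizes: np.ndarray
    alpha: float


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    exact: bool
    n_permutations: int


@dataclass
class TrendResult:
    slope: float
    intercept: float
    F: float
    df: tuple
    r2: float
    r2_adjusted: float
    p_mc: float
    n_permutations: int


# ---------------------------------------------------------------------------
# paired t-test
# ---------------------------------------------------------------------------

def perm_ttest_paired(x, y, cfg: StatsConfig | None = None,
                      rng: np.random.Generator | None = None) -> StatResult:
    """Paired t-test with a sign-flip permutation null.

    Under the null of no condition difference the sign of each within-pair
    difference is exchangeable; the null distribution is built from random
    sign assignments of the differences (equivalent to permuting the
    condition affiliation within each pair).  Two-sided.
    """
    cfg = cfg or StatsConfig()
    rng = rng if rng is not None else cfg.rng()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = x - y
    if np.all(d == d[0]) and d[0] == 0:
        return StatResult(0.0, (n - 1,), 1.0, cfg.n_permutations,
                          flags=["zero-variance differences"])
    t_obs = _paired_t(d[None, :])[0]
    signs = rng.integers(0, 2, size=(cfg.n_permutations, n)) * 2 - 1
    t_perm = _paired_t(d[None, :] * signs)
    exceed = np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12)
    p = (1 + exceed) / (cfg.n_permutations + 1)
    return StatResult(float(t_obs), (n - 1,), float(p), cfg.n_permutations,
                      seed=cfg.seed)


def _paired_t(d: np.ndarray) -> np.ndarray:
    """Row-wise paired t statistic of difference matrix (n_rows, n)."""
    n = d.shape[1]
    m = d.mean(axis=1)
    s = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (s / math.sqrt(n))
    # zero-variance, nonzero-mean rows: infinitely extreme
    t[np.isnan(t)] = 0.0
    return t


# ---------------------------------------------------------------------------
# fixed-effects permutation ANOVA (Type II sums of squares)
# ---------------------------------------------------------------------------

def _sum_code(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Sum-to-zero coding: (n, k-1) matrix; last level coded -1."""
    levels = sorted(set(values))
    k = len(levels)
    idx = np.array([levels.index(v) for v in values])
    X = np.zeros((len(values), k - 1))
    for j in range(k - 1):
        X[idx == j, j] = 1.0
    X[idx == k - 1, :] = -1.0
    return X, k


def _term_columns(encoded: dict[str, np.ndarray], term: tuple[str, ...]) -> np.ndarray:
    cols = encoded[term[0]]
    for f in term[1:]:
        cols = np.einsum("ni,nj->nij", cols, encoded[f]).reshape(len(cols), -1)
    return cols


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    # reduced QR; rank-deficient designs are rejected upstream
    Q, _ = np.linalg.qr(X)
    r = y - Q @ (Q.T @ y)
    return float(r @ r)


def _anova_f(y: np.ndarray, factor_values: dict[str, np.ndarray],
             terms: list[tuple[str, ...]],
             test_terms: list[tuple[str, ...]] | None = None,
             rss_red_cache: dict | None = None):
    """Type II F statistic and numerator df for each tested term.

    For term T: SS(T) = RSS(all terms not containing T) - RSS(those + T);
    the error mean square comes from the full model with every term.
    ``terms`` defines the model; ``test_terms`` (default: all) which F
    statistics to evaluate.
    """
    n = y.size
    test_terms = test_terms if test_terms is not None else terms
    encoded = {}
    dfs = {}
    for f, v in factor_values.items():
        encoded[f], k = _sum_code(v)
        dfs[f] = k - 1
    mats = {t: _term_columns(encoded, t) for t in terms}
    intercept = np.ones((n, 1))
    X_full = np.hstack([intercept] + [mats[t] for t in terms])
    rank_full = np.linalg.matrix_rank(X_full)
    df_resid = n - rank_full
    if df_resid <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")
    rss_full = _rss(X_full, y)
    mse = rss_full / df_resid
    out = {}
    for t in test_terms:
        others = [u for u in terms if not set(t) <= set(u)]
        X_red = np.hstack([intercept] + [mats[u] for u in others])
        X_aug = np.hstack([X_red, mats[t]])
        if rss_red_cache is not None and t in rss_red_cache:
            rss_red = rss_red_cache[t]
        else:
            rss_red = _rss(X_red, y)
            if rss_red_cache is not None:
                rss_red_cache[t] = rss_red
        ss = max(rss_red - _rss(X_aug, y), 0.0)
        df_t = int(np.prod([dfs[f] for f in t]))
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss / df_t) / mse if mse > 0 else (np.inf if ss > 0 else 0.0)
        out[t] = (float(F), df_t)
    return out, df_resid


def _all_terms(factors: list[str]) -> list[tuple[str, ...]]:
    terms = []
    for order in range(1, len(factors) + 1):
        terms.extend(itertools.combinations(factors, order))
    return terms


def perm_anova(y, factors, cfg: StatsConfig | None = None,
               rng: np.random.Generator | None = None,
               terms: list[tuple[str, ...]] | None = None) -> dict:
    """Fixed-effects N-way ANOVA with Monte-Carlo permutation p-values.

    ``factors`` is a mapping (or DataFrame) of factor name -> label array
    aligned with ``y``.  Type II sums of squares; all main effects and
    interactions are tested unless ``terms`` restricts them.  The null for a
    main effect permutes that factor's labels; for an interaction, the
    first-named factor's labels are permuted within the level combinations
    of all other factors, preserving lower-order structure.
    """
    cfg = cfg or StatsConfig()
    rng = rng if rng is not None else cfg.rng()
    y = np.asarray(y, dtype=float)
    fvals = {k: np.asarray(v) for k, v in dict(factors).items()}
    names = list(fvals)
    for k, v in fvals.items():
        if v.shape != y.shape:
            raise ValueError(f"factor {k!r} not aligned with y")
    # empty-cell check over the full cross
    cells = set(zip(*[fvals[f] for f in names]))
    full = set(itertools.product(*[sorted(set(fvals[f])) for f in names]))
    if cells != full:
        raise ValueError("design has empty cells")
    all_terms = terms or _all_terms(names)
    obs, df_resid = _anova_f(y, fvals, all_terms)

    results = {}
    for t in all_terms:
        F_obs, df_t = obs[t]
        shuffle_factor = t[0]
        strata_names = [f for f in names if f != shuffle_factor]
        if len(t) == 1 or not strata_names:
            strata = np.zeros(y.size, dtype=int)
        else:
            _, strata = np.unique(
                np.stack([fvals[f] for f in strata_names]), axis=1,
                return_inverse=True)
        groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
        exceed = 0
        fp = dict(fvals)
        base = fvals[shuffle_factor]
        # for a main effect the Type II reduced model contains no term with
        # the shuffled factor, so its RSS is permutation-invariant
        cache = {t: None} if len(t) == 1 else None
        if cache is not None:
            cache.pop(t)
        for _ in range(cfg.n_permutations):
            perm = base.copy()
            for g in groups:
                perm[g] = perm[rng.permutation(g)]
            fp[shuffle_factor] = perm
            F_p = _anova_f(y, fp, all_terms, test_terms=[t],
                           rss_red_cache=cache)[0][t][0]
            if F_p >= F_obs - 1e-12:
                exceed += 1
        p = (1 + exceed) / (cfg.n_permutations + 1)
        results[t] = StatResult(F_obs, (df_t, df_resid), float(p),
                                cfg.n_permutations, kind="F", seed=cfg.seed)
    return results


def perm_posthoc(y, labels, cfg: StatsConfig | None = None,
                 rng: np.random.Generator | None = None,
                 pairs: list[tuple] | None = None) -> list[StatResult]:
    """Pairwise post-hoc comparisons after a significant ANOVA effect.

    For each pair of levels the statistic is the difference of cell means;
    the null shuffles the level labels among the two cells' observations.
    All p-values are returned uncorrected so the caller can feed them into
    one FDR family.
    """
    cfg = cfg or StatsConfig()
    rng = rng if rng is not None else cfg.rng()
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels)
    levels = sorted(set(labels))
    pairs = pairs or list(itertools.combinations(levels, 2))
    out = []
    for a, b in pairs:
        ya, yb = y[labels == a], y[labels == b]
        if min(ya.size, yb.size) < 2:
            raise ValueError(f"cell {a!r} or {b!r} has fewer than 2 observations")
        pooled = np.concatenate([ya, yb])
        na = ya.size
        d_obs = ya.mean() - yb.mean()
        idx = np.argsort(rng.random((cfg.n_permutations, pooled.size)), axis=1)
        perm = pooled[idx]
        d_perm = perm[:, :na].mean(axis=1) - perm[:, na:].mean(axis=1)
        exceed = np.sum(np.abs(d_perm) >= abs(d_obs) - 1e-12)
        p = (1 + exceed) / (cfg.n_permutations + 1)
        out.append(StatResult(float(d_obs), (na + yb.size - 2,), float(p),
                              cfg.n_permutations, kind="diff",
                              meta={"levels": (a, b)}))
    return out


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def fdr_bh(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR: (rejected flags, adjusted p-values)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value family")
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# cluster-based Monte-Carlo correction for time series
# ---------------------------------------------------------------------------

def _runs_of_ones(b: np.ndarray) -> list[tuple[int, int, int]]:
    runs = []
    start = None
    for i, v in enumerate(b):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i, i - start))
            start = None
    if start is not None:
        runs.append((start, b.size, b.size - start))
    return runs


def _max_run_lengths(shuffled: np.ndarray) -> np.ndarray:
    """Max run of ones per row of a binary matrix, vectorized over rows."""
    cur = np.zeros(shuffled.shape[0], dtype=np.int64)
    best = np.zeros(shuffled.shape[0], dtype=np.int64)
    for j in range(shuffled.shape[1]):
        cur = (cur + 1) * shuffled[:, j]
        np.maximum(best, cur, out=best)
    return best


def cluster_mcs(pvals, cfg: StatsConfig | None = None,
                rng: np.random.Generator | None = None) -> ClusterResult:
    """Cluster-size correction for an ordered p-value series.

    The series is binarized at ``cfg.alpha``; maximal runs of significant
    windows form the observed clusters.  The null randomly shuffles the
    binary sequence (preserving the number of significant windows) and
    records the maximum run length per iteration; observed clusters whose
    size exceeds the ``1 - mcs_p`` (99.9th) percentile of that distribution
    are flagged significant.
    """
    cfg = cfg or StatsConfig()
    rng = rng if rng is not None else cfg.rng()
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size < 2:
        raise ValueError("p-value series must have length >= 2")
    b = (pvals <= cfg.alpha).astype(np.int8)
    clusters = _runs_of_ones(b)
    idx = np.argsort(rng.random((cfg.n_permutations, b.size)), axis=1)
    shuffled = b[idx]
    null_max = _max_run_lengths(shuffled)
    threshold = float(np.percentile(null_max, 100 * (1 - cfg.mcs_p)))
    significant = [c[2] > threshold for c in clusters]
    cluster_p = [float(np.mean(null_max >= c[2])) for c in clusters]
    return ClusterResult(clusters, significant, threshold, cluster_p,
                         null_max, cfg.alpha)


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def perm_spearman(x, y, cfg: StatsConfig | None = None,
                  rng: np.random.Generator | None = None) -> CorrelationResult:
    """Spearman rank correlation with a permutation p-value.

    Ranks are averaged over ties.  For n <= 8 the two-sided p is exact: all
    n! orderings of y are enumerated and p is the fraction with
    ``|rho| >= |rho_obs|`` (the identity ordering included).  For larger n a
    Monte-Carlo permutation p is used.
    """
    cfg = cfg or StatsConfig()
    rng = rng if rng is not None else cfg.rng()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for constant input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = x.size

    rxc = rx - rx.mean()
    denom_x = math.sqrt(float(rxc @ rxc))

    def rho_of(r):
        rc = r - r.mean()
        return float(rxc @ rc) / (denom_x * math.sqrt(float(rc @ rc)))

    rho_obs = rho_of(ry)
    if n <= 8:
        count = 0
        total = math.factorial(n)
        for perm in itertools.permutations(ry):
            if abs(rho_of(np.array(perm))) >= abs(rho_obs) - 1e-12:
                count += 1
        return CorrelationResult(rho_obs, count / total, n, True, total)
    idx = np.argsort(rng.random((cfg.n_permutations, n)), axis=1)
    perms = ry[idx]
    pc = perms - perms.mean(axis=1, keepdims=True)
    rho_perm = (pc @ rxc) / (denom_x * np.sqrt(np.sum(pc * pc, axis=1)))
    exceed = np.sum(np.abs(rho_perm) >= abs(rho_obs) - 1e-12)
    p = (1 + exceed) / (cfg.n_permutations + 1)
    return CorrelationResult(rho_obs, float(p), n, False, cfg.n_permutations)


# ---------------------------------------------------------------------------
# linear trend regression
# ---------------------------------------------------------------------------

def r2_from_f(F: float, df2: int) -> float:
    """R-squared implied by a simple-regression F statistic with df (1, df2)."""
    return F / (F + df2)


def adjusted_r2(r2: float, n: int) -> float:
    """Adjusted R-squared for a simple regression on n points."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def linreg_trend(t, v, cfg: StatsConfig | None = None,
                 rng: np.random.Generator | None = None) -> TrendResult:
    """Ordinary least squares v = a + b*t with a permutation p for the slope.

    Reports F = MS_model / MS_residual with df (1, n-2) and the adjusted
    R-squared (which can be negative for a null fit).
    """
    cfg = cfg or StatsConfig()
    rng = rng if rng is not None else cfg.rng()
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    n = t.size
    if n < 3 or v.size != n:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.all(t == t[0]):
        raise ValueError("regressor is constant")
    res = sps.linregress(t, v)
    r2 = float(res.rvalue ** 2)
    if r2 >= 1.0:
        F = np.inf
    else:
        F = (n - 2) * r2 / (1.0 - r2)
    # permutation null: shuffle v against t; |r| is the equivalent statistic
    tc = t - t.mean()
    denom_t = math.sqrt(float(tc @ tc))
    idx = np.argsort(rng.random((cfg.n_permutations, n)), axis=1)
    perms = v[idx]
    pc = perms - perms.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        r_perm = (pc @ tc) / (denom_t * np.sqrt(np.sum(pc * pc, axis=1)))
    exceed = np.sum(np.abs(r_perm) >= abs(res.rvalue) - 1e-12)
    p = (1 + exceed) / (cfg.n_permutations + 1)
    return TrendResult(float(res.slope), float(res.intercept), float(F),
                       (1, n - 2), r2, adjusted_r2(r2, n), float(p),
                       cfg.n_permutations)


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk normality diagnostic (W, p).

    Reported descriptively only; it never switches the inference path, which
    is permutation-based throughout.
    """
    W, p = sps.shapiro(np.asarray(x, dtype=float))
    return float(W), float(p)
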