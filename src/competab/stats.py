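"""Nonparametric and permutation statistics used by every analysis stage.

The tests collected here are the ones a behavioral-ecology analysis leans on
when the response is count- or rank-shaped and no distributional model is
warranted: exact binomial and continuity-corrected proportion tests, the
rank-sum and signed-rank tests, the Friedman test, Pearson correlation,
count-matrix PCA, Bray-Curtis dissimilarity, and the permutation trio
ANOSIM / Mantel / PERMANOVA.

Conventions
-----------
* Every permutation p-value uses the ``(1 + exceedances) / (n_perm + 1)``
  estimator and a single explicit integer seed (default 1234), so results
  are reproducible bit-for-bit given ``(seed, n_perm)``.
* Two-sided exact binomial p-values follow the *minlike* convention (sum of
  the probabilities of all outcomes no more likely than the observed one).
* The rank-sum statistic is reported as ``min(U, nm - U)`` and the
  signed-rank statistic as the sum of positive-difference ranks, matching
  the conventions of R's ``wilcox.test`` output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "TestResult",
    "DistanceMatrix",
    "PCAResult",
    "binom_exact",
    "prop_test_cc",
    "prop_test_two_sample",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "friedman",
    "pearson",
    "pca_counts",
    "bray_curtis",
    "anosim",
    "mantel",
    "permanova",
    "bonferroni",
    "results_table",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 1234

ALTERNATIVES = ("two_sided", "greater", "less")
_SCIPY_ALT = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


def _check_alternative(alternative: str) -> str:
    if alternative not in ALTERNATIVES:
        raise ValueError(
            f"alternative must be one of {ALTERNATIVES}, got {alternative!r}"
        )
    return alternative


@dataclass
class TestResult:
    """Outcome of a single hypothesis test.

    ``n_perm`` is 0 for exact or analytic tests; for permutation tests it is
    the number of label permutations drawn and ``seed`` records the RNG seed.
    """

    statistic: float
    p_value: float
    n_perm: int = 0
    alternative: str = "two_sided"
    method: str = ""
    seed: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")
        if self.n_perm < 0:
            raise ValueError("n_perm must be >= 0")
        _check_alternative(self.alternative)


def results_table(results: dict[str, TestResult]) -> pd.DataFrame:
    """Flatten named test results into a serializable table."""
    rows = []
    for name, r in results.items():
        if r is None:
            continue
        rows.append(
            {
                "test": name,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "n_perm": r.n_perm,
                "seed": r.seed,
                "alternative": r.alternative,
                "method": r.method,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DistanceMatrix:
    """A labeled symmetric distance matrix with zero diagonal."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be nonnegative")

    @property
    def size(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        i, j = np.triu_indices(self.size, k=1)
        return self.values[i, j]


# ---------------------------------------------------------------------------
# one-sample count tests
# ---------------------------------------------------------------------------


def binom_exact(
    k: int, n: int, p0: float = 0.5, alternative: str = "two_sided"
) -> TestResult:
    """Exact binomial test of ``k`` successes in ``n`` trials against ``p0``.

    The two-sided p-value is the minlike tail: the sum of probabilities of
    all outcomes whose likelihood does not exceed the observed outcome's.
    """
    _check_alternative(alternative)
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    res = sps.binomtest(k, n, p0, alternative=_SCIPY_ALT[alternative])
    return TestResult(
        statistic=float(k),
        p_value=float(res.pvalue),
        n_perm=0,
        alternative=alternative,
        method="exact binomial",
        extra={"n": n, "p0": p0},
    )


def prop_test_cc(
    k: int, n: int, p0: float = 0.5, alternative: str = "two_sided"
) -> TestResult:
    """One-sample chi-square proportion test with Yates continuity correction.

    Matches R's one-sample ``prop.test``: the statistic is
    ``(|k - n p0| - 1/2)^2 / (n p0 (1 - p0))`` with the correction truncated
    at the absolute deviation; one-sided p-values halve the chi-square tail
    on the side of the observed deviation.
    """
    _check_alternative(alternative)
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    expected = n * p0
    dev = k - expected
    cc = min(0.5, abs(dev))
    chi2 = (abs(dev) - cc) ** 2 / (n * p0 * (1.0 - p0))
    if alternative == "two_sided":
        p = float(sps.chi2.sf(chi2, df=1))
    else:
        z = math.copysign(math.sqrt(chi2), dev)
        p = float(sps.norm.sf(z)) if alternative == "greater" else float(
            sps.norm.cdf(z)
        )
    return TestResult(
        statistic=float(chi2),
        p_value=p,
        n_perm=0,
        alternative=alternative,
        method="chi-square proportion test (Yates)",
        extra={"k": k, "n": n, "p0": p0},
    )


def prop_test_two_sample(
    k1: int, n1: int, k2: int, n2: int, alternative: str = "two_sided"
) -> TestResult:
    """Two-sample equal-proportions chi-square test with Yates correction.

    Matches R's two-sample ``prop.test`` on counts ``k1/n1`` vs ``k2/n2``.
    """
    _check_alternative(alternative)
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not 0 <= k <= n:
            raise ValueError("counts must satisfy 0 <= k <= n, n >= 1")
    a, b, c, d = k1, n1 - k1, k2, n2 - k2
    n_tot = n1 + n2
    cross = abs(a * d - b * c)
    cc = min(n_tot / 2.0, cross)
    denom = n1 * n2 * (a + c) * (b + d)
    if denom == 0:
        chi2 = 0.0
    else:
        chi2 = n_tot * (cross - cc) ** 2 / denom
    if alternative == "two_sided":
        p = float(sps.chi2.sf(chi2, df=1))
    else:
        dev = k1 / n1 - k2 / n2
        z = math.copysign(math.sqrt(chi2), dev)
        p = float(sps.norm.sf(z)) if alternative == "greater" else float(
            sps.norm.cdf(z)
        )
    return TestResult(
        statistic=float(chi2),
        p_value=p,
        n_perm=0,
        alternative=alternative,
        method="two-sample proportion test (Yates)",
        extra={"k1": k1, "n1": n1, "k2": k2, "n2": n2},
    )


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


def mann_whitney(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> TestResult:
    """Mann-Whitney rank-sum test.

    Uses the exact null distribution when both samples have <= 20
    observations and there are no ties, and the tie-corrected,
    continuity-corrected normal approximation otherwise. The reported
    statistic is ``min(U, nm - U)``; ``extra['u_x']`` carries U for ``x``.
    """
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    nm = x.size * y.size
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both samples; p = 1")
        return TestResult(
            statistic=nm / 2.0,
            p_value=1.0,
            alternative=alternative,
            method="rank-sum (degenerate: all values tied)",
            extra={"u_x": nm / 2.0},
        )
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 20 and y.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=_SCIPY_ALT[alternative], method=method)
    u_x = float(res.statistic)
    return TestResult(
        statistic=min(u_x, nm - u_x),
        p_value=float(res.pvalue),
        alternative=alternative,
        method=f"rank-sum ({method})",
        extra={"u_x": u_x, "n_x": int(x.size), "n_y": int(y.size)},
    )


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Optional[Sequence[float]] = None,
    alternative: str = "two_sided",
) -> TestResult:
    """Wilcoxon signed-rank test on paired samples (or a single sample).

    Zero differences are dropped (their count is recorded). The statistic V
    is the sum of the ranks of the positive differences. The exact null
    distribution is used for <= 25 nonzero untied pairs, the tie-corrected
    continuity-corrected normal approximation otherwise.
    """
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        d = x - y
    else:
        d = x
    nonzero = d[d != 0]
    n_dropped = int(d.size - nonzero.size)
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return TestResult(
            statistic=0.0,
            p_value=1.0,
            alternative=alternative,
            method="signed-rank (degenerate: all differences zero)",
            extra={"n_dropped_zeros": n_dropped},
        )
    ranks = sps.rankdata(np.abs(nonzero))
    v_pos = float(ranks[nonzero > 0].sum())
    has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
    exact = nonzero.size <= 25 and not has_ties
    res = sps.wilcoxon(
        nonzero,
        alternative=_SCIPY_ALT[alternative],
        zero_method="wilcox",
        correction=not exact,
        method="exact" if exact else "approx",
    )
    return TestResult(
        statistic=v_pos,
        p_value=float(res.pvalue),
        alternative=alternative,
        method=f"signed-rank ({'exact' if exact else 'normal approx'})",
        extra={"n_dropped_zeros": n_dropped, "n_pairs_used": int(nonzero.size)},
    )


def friedman(block_matrix: np.ndarray) -> TestResult:
    """Friedman rank-sum test on a blocks x treatments table.

    Ranks are assigned within blocks (midranks for ties); the chi-square
    statistic with ``treatments - 1`` degrees of freedom includes the
    standard tie correction, matching R's ``friedman.test``. A table in
    which every block is fully tied yields statistic 0 and p = 1.
    """
    y = np.asarray(block_matrix, dtype=float)
    if y.ndim != 2:
        raise ValueError("block_matrix must be 2-dimensional")
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 blocks and >= 2 treatments")
    r = np.apply_along_axis(sps.rankdata, 1, y)
    col_sums = r.sum(axis=0)
    num = 12.0 * float(((col_sums - n * (k + 1) / 2.0) ** 2).sum())
    ties = 0.0
    for row in y:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    den = n * k * (k + 1) - ties / (k - 1)
    if den <= 0:
        # every block fully tied: no information, no evidence
        stat, p = 0.0, 1.0
    else:
        stat = num / den
        p = float(sps.chi2.sf(stat, df=k - 1))
    return TestResult(
        statistic=stat,
        p_value=p,
        method="Friedman rank sum",
        extra={"df": k - 1, "n_blocks": n, "n_treatments": k},
    )


def pearson(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> TestResult:
    """Pearson correlation with t-distribution p-value."""
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the samples")
    res = sps.pearsonr(x, y, alternative=_SCIPY_ALT[alternative])
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
        method="Pearson correlation",
        extra={"n": int(x.size)},
    )


# ---------------------------------------------------------------------------
# ordination and dissimilarity
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    """PCA of a count matrix converted to per-row proportions."""

    scores: np.ndarray  # individuals x components
    loadings: np.ndarray  # variables x components, orthonormal columns
    variance_explained: np.ndarray  # sums to 1 over all components
    variables: tuple
    labels: tuple


def pca_counts(
    count_matrix,
    min_total_fraction: float = 0.05,
    labels: Optional[Sequence] = None,
) -> PCAResult:
    """PCA on a behavior-count matrix.

    Columns whose grand total is not more than ``min_total_fraction`` of all
    events are dropped, rows are converted to proportions, columns centered,
    and the covariance eigendecomposition taken. Component signs are fixed
    by making the largest-magnitude loading of each component positive.
    """
    if isinstance(count_matrix, pd.DataFrame):
        variables = list(count_matrix.columns)
        if labels is None:
            labels = list(count_matrix.index)
        X = count_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(count_matrix, dtype=float)
        variables = list(range(X.shape[1]))
    if labels is None:
        labels = list(range(X.shape[0]))
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 individuals")
    if (X < 0).any():
        raise ValueError("counts must be nonnegative")
    total = X.sum()
    if total <= 0:
        raise ValueError("count matrix is all zero")
    keep = X.sum(axis=0) / total > min_total_fraction
    if keep.sum() < 2:
        raise ValueError(
            "fewer than 2 behavior columns survive the abundance filter"
        )
    Xk = X[:, keep]
    variables = tuple(v for v, k in zip(variables, keep) if k)
    row_sums = Xk.sum(axis=1, keepdims=True)
    if (row_sums == 0).any():
        raise ValueError("an individual has zero events after filtering")
    P = Xk / row_sums
    C = P - P.mean(axis=0)
    _, s, vt = np.linalg.svd(C, full_matrices=False)
    eigvals = s**2 / max(C.shape[0] - 1, 1)
    ve_total = eigvals.sum()
    ve = eigvals / ve_total if ve_total > 0 else np.zeros_like(eigvals)
    loadings = vt.T
    for c in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] = -loadings[:, c]
    scores = C @ loadings
    return PCAResult(
        scores=scores,
        loadings=loadings,
        variance_explained=ve,
        variables=variables,
        labels=tuple(labels),
    )


def bray_curtis(count_matrix, labels: Optional[Sequence] = None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between rows of a raw count matrix."""
    if isinstance(count_matrix, pd.DataFrame):
        if labels is None:
            labels = list(count_matrix.index)
        X = count_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(count_matrix, dtype=float)
    if labels is None:
        labels = list(range(X.shape[0]))
    if (X < 0).any():
        raise ValueError("counts must be nonnegative")
    if (X.sum(axis=1) == 0).any():
        raise ValueError("all-zero rows are not allowed")
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(labels=tuple(labels), values=d)


# ---------------------------------------------------------------------------
# permutation tests on distance matrices
# ---------------------------------------------------------------------------


def _perm_p(exceed: int, n_perm: int) -> float:
    return (1 + exceed) / (n_perm + 1)


def anosim(
    dm: DistanceMatrix,
    groups: Sequence,
    n_perm: int = 999,
    seed: int = DEFAULT_SEED,
) -> TestResult:
    """Analysis of similarities on a distance matrix.

    ``R = (mean between-group rank - mean within-group rank) / (M / 2)`` with
    ``M = n(n-1)/2``; the p-value shuffles group labels ``n_perm`` times.
    """
    groups = np.asarray(groups)
    n = dm.size
    if groups.shape != (n,):
        raise ValueError("groups must match the distance-matrix labels")
    _, codes, counts = np.unique(groups, return_inverse=True, return_counts=True)
    if counts.size < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group must have at least 2 members")
    ranks = sps.rankdata(dm.condensed())
    i, j = np.triu_indices(n, k=1)
    m = n * (n - 1) / 2.0

    def r_stat(c: np.ndarray) -> float:
        within = c[i] == c[j]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    observed = r_stat(codes)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if r_stat(rng.permutation(codes)) >= observed:
            exceed += 1
    return TestResult(
        statistic=float(observed),
        p_value=_perm_p(exceed, n_perm),
        n_perm=n_perm,
        alternative="greater",
        method="ANOSIM",
        seed=seed,
        extra={"n_groups": int(counts.size)},
    )


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = DEFAULT_SEED,
    alternative: str = "greater",
) -> TestResult:
    """Mantel test: Pearson correlation between two distance matrices.

    The permutation null simultaneously shuffles rows and columns of the
    second matrix.
    """
    _check_alternative(alternative)
    if dm1.labels != dm2.labels:
        raise ValueError("distance matrices must share labels and order")
    n = dm1.size
    iu = np.triu_indices(n, k=1)
    v1 = dm1.values[iu]
    if np.std(v1) == 0 or np.std(dm2.values[iu]) == 0:
        raise ValueError("zero variance in a distance matrix")
    z1 = (v1 - v1.mean()) / v1.std()

    def corr(mat: np.ndarray) -> float:
        v2 = mat[iu]
        return float(z1 @ ((v2 - v2.mean()) / v2.std()) / v1.size)

    observed = corr(dm2.values)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        r = corr(dm2.values[np.ix_(p, p)])
        if alternative == "greater":
            hit = r >= observed
        elif alternative == "less":
            hit = r <= observed
        else:
            hit = abs(r) >= abs(observed)
        exceed += bool(hit)
    return TestResult(
        statistic=observed,
        p_value=_perm_p(exceed, n_perm),
        n_perm=n_perm,
        alternative=alternative,
        method="Mantel",
        seed=seed,
    )


def _design_columns(col: pd.Series) -> np.ndarray:
    """Numeric covariates pass through; factors become treatment dummies."""
    if pd.api.types.is_numeric_dtype(col) and not isinstance(
        col.dtype, pd.CategoricalDtype
    ) and col.dtype != bool:
        return col.to_numpy(dtype=float)[:, None]
    return pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)


def _orth_basis(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing SVD)."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = s.max(initial=0.0) * max(x.shape) * np.finfo(float).eps
    return u[:, s > tol]


def permanova(
    response,
    predictors: pd.DataFrame,
    n_perm: int = 999,
    seed: int = DEFAULT_SEED,
    transform: bool = True,
) -> list[TestResult]:
    """Sequential (Type-I) PERMANOVA of a multivariate response.

    The response is (optionally) ``log(x + 1)``-transformed and
    column-standardized, Euclidean distances taken, and the total sum of
    squared distances partitioned sequentially over the predictor terms via
    the Gower-centered matrix. Pseudo-F per term; p-values permute the raw
    response rows.
    """
    Y = (
        response.to_numpy(dtype=float)
        if isinstance(response, pd.DataFrame)
        else np.asarray(response, dtype=float)
    )
    if np.isnan(Y).any():
        raise ValueError("response contains missing values")
    if not isinstance(predictors, pd.DataFrame):
        raise TypeError("predictors must be a pandas DataFrame (ordered terms)")
    if predictors.isna().any().any():
        raise ValueError("predictors contain missing values")
    n = Y.shape[0]
    if len(predictors) != n:
        raise ValueError("response and predictors must have equal rows")
    if transform:
        Y = np.log1p(Y)
        sd = Y.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Y = (Y - Y.mean(axis=0)) / sd
    D = squareform(pdist(Y, metric="euclidean"))
    A = -0.5 * D**2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    G = J @ A @ J

    cum = np.ones((n, 1))
    rank_prev = 1
    hats: list[np.ndarray] = []
    terms: list[str] = []
    dfs: list[int] = []
    h_prev = np.full((n, n), 1.0 / n)
    for name in predictors.columns:
        cand = np.hstack([cum, _design_columns(predictors[name])])
        q = _orth_basis(cand)
        rank = q.shape[1]
        if rank == rank_prev:
            warnings.warn(f"term {name!r} is rank deficient and was dropped")
            continue
        cum = cand
        h = q @ q.T
        hats.append(h)
        terms.append(str(name))
        dfs.append(rank - rank_prev)
        rank_prev = rank
        h_prev = h
    if not hats:
        raise ValueError("no usable predictor terms")
    df_res = n - rank_prev
    if df_res <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")

    def f_stats(g: np.ndarray) -> np.ndarray:
        traces = [float((h * g).sum()) for h in hats]
        ss_total = float(np.trace(g))
        ss_terms = np.diff([float((np.full((n, n), 1.0 / n) * g).sum())] + traces)
        ss_res = ss_total - traces[-1]
        ms_res = ss_res / df_res
        return ss_terms / np.asarray(dfs) / ms_res, ss_terms, ss_res

    f_obs, ss_terms, ss_res = f_stats(G)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms), dtype=int)
    for _ in range(n_perm):
        p = rng.permutation(n)
        f_perm, _, _ = f_stats(G[np.ix_(p, p)])
        exceed += f_perm >= f_obs
    results = []
    for t, (term, f, df, ss, ex) in enumerate(
        zip(terms, f_obs, dfs, ss_terms, exceed)
    ):
        results.append(
            TestResult(
                statistic=float(f),
                p_value=_perm_p(int(ex), n_perm),
                n_perm=n_perm,
                alternative="greater",
                method="PERMANOVA (sequential)",
                seed=seed,
                extra={
                    "term": term,
                    "df": df,
                    "ss": float(ss),
                    "ss_residual": float(ss_res),
                    "df_residual": df_res,
                },
            )
        )
    return results


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> list[float]:
    """Bonferroni adjustment ``min(1, p * m)``; ``m`` defaults to the list length."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise ValueError("m must be at least the number of p-values")
    return [min(1.0, p * m) for p in p_values]
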