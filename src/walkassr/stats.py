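"""Inferential machinery: cluster-based permutation tests, FDR, repeated-
measures ANOVA with Greenhouse–Geisser correction, and robust Spearman
correlations with triple-method outlier rejection.

The cluster test is the paired, two-tailed, max-statistic variant: paired t
at each sample, contiguous supra-threshold runs form clusters whose mass is
the summed t, and the null is built from per-subject condition sign-flips
(1,000 permutations by default), with the plus-one correction on Monte-Carlo
p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["Cluster", "ClusterResult", "cluster_permutation_test",
           "fdr_adjust", "AnovaEffect", "rm_anova", "paired_t",
           "RobustCorrelation", "robust_spearman"]


# ---------------------------------------------------------------------------
# cluster-based permutation test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cluster:
    start_s: float
    end_s: float
    mass: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class ClusterResult:
    t_series: np.ndarray
    times: np.ndarray
    clusters: list[Cluster]
    threshold: float
    n_permutations: int
    cluster_alpha: float
    tails: int
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]


_ROW_STRUCT = np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0]])


def _row_max_cluster_mass(t: np.ndarray, thr: float) -> np.ndarray:
    """Per-row maximum |cluster mass| of a (rows × time) t matrix, clusters
    being contiguous runs with t > thr or t < −thr (two-sided)."""
    out = np.zeros(t.shape[0])
    for sign in (1.0, -1.0):
        mask = sign * t > thr
        if not mask.any():
            continue
        lab, n = ndimage.label(mask, structure=_ROW_STRUCT)
        idx = np.arange(1, n + 1)
        masses = np.abs(ndimage.sum_labels(t, lab, idx))
        rows = ndimage.minimum(
            np.broadcast_to(np.arange(t.shape[0])[:, None], t.shape), lab, idx
        ).astype(int)
        np.maximum.at(out, rows, masses)
    return out


def _clusters_1d(t: np.ndarray, thr: float, times: np.ndarray,
                 ) -> list[tuple[int, int, float]]:
    found = []
    for sign in (1.0, -1.0):
        mask = sign * t > thr
        lab, n = ndimage.label(mask)
        for k in range(1, n + 1):
            idx = np.flatnonzero(lab == k)
            found.append((int(idx[0]), int(idx[-1]), float(t[idx].sum())))
    found.sort(key=lambda c: c[0])
    return found


def cluster_permutation_test(cond_a: np.ndarray, cond_b: np.ndarray,
                             times: np.ndarray | None = None,
                             n_perm: int = 1000, cluster_alpha: float = 0.05,
                             seed: int = 0, tails: int = 2) -> ClusterResult:
    """Paired cluster-based permutation test between two subjects × time
    conditions.

    The cluster-defining threshold is the two-sided t critical value at
    ``cluster_alpha``; cluster mass is the summed t; the null distribution is
    the per-permutation maximum |mass| under per-subject sign flips.
    """
    A = np.asarray(cond_a, dtype=float)
    B = np.asarray(cond_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("conditions must have matching subjects × time shapes")
    n, T = A.shape
    if n < 2:
        raise ValueError("need at least 2 paired subjects")
    if times is None:
        times = np.arange(T, dtype=float)
    D = A - B
    thr = float(sps.t.ppf(1 - cluster_alpha / (2 if tails == 2 else 1), n - 1))

    def t_stat(mean: np.ndarray, meansq: np.ndarray) -> np.ndarray:
        var = (meansq - mean ** 2) * n / (n - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(var > 0, mean / np.sqrt(var / n), 0.0)

    meansq = (D ** 2).mean(axis=0)
    t_obs = t_stat(D.mean(axis=0), meansq)
    obs_clusters = _clusters_1d(t_obs, thr, times)

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    block = 200  # permutations per vectorized block (memory bound)
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        S = rng.choice([-1.0, 1.0], size=(b, n))
        M = (S @ D) / n
        t_perm = t_stat(M, meansq)
        null_max[done:done + b] = _row_max_cluster_mass(t_perm, thr)
        done += b

    clusters = []
    for i0, i1, mass in obs_clusters:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (n_perm + 1.0)
        clusters.append(Cluster(start_s=float(times[i0]), end_s=float(times[i1]),
                                mass=mass, p=float(p)))
    return ClusterResult(t_series=t_obs, times=np.asarray(times, float),
                         clusters=clusters, threshold=thr,
                         n_permutations=n_perm, cluster_alpha=cluster_alpha,
                         tails=tails, seed=seed)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# repeated-measures ANOVA (fully within, balanced, 1–3 factors)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaEffect:
    effect: str
    F: float
    df1: int
    df2: int
    epsilon: float
    p: float            # GG-corrected when epsilon < 1
    p_uncorrected: float
    ss_effect: float
    ss_error: float


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k × (k−1) orthonormal contrast matrix (orthogonal to the unit vector)."""
    basis = np.eye(k) - 1.0 / k
    q, _ = np.linalg.qr(basis)
    return q[:, : k - 1]


def rm_anova(values: np.ndarray, factor_names: list[str] | None = None,
             gg: bool = True) -> list[AnovaEffect]:
    """Repeated-measures ANOVA for a balanced fully-within design.

    Parameters
    ----------
    values : ndarray, shape (n_subjects, k1[, k2[, k3]])
        One cell value per subject × factor-level combination.
    factor_names : list of str
        One name per within factor (defaults A, B, C).
    gg : bool
        Apply the Greenhouse–Geisser epsilon (estimated from the covariance
        of the orthonormal contrast scores) to effects with > 1 df.

    Each effect is tested against its own effect × subject interaction via
    orthonormal-contrast projection: with contrast matrix K for the effect,
    Z = Y K, F = (n·Σ z̄²/q) / (Σᵢⱼ (z−z̄)²/(q(n−1))).
    """
    Y = np.asarray(values, dtype=float)
    if Y.ndim < 2 or Y.ndim > 4:
        raise ValueError("values must be subjects × 1–3 factor axes")
    if not np.isfinite(Y).all():
        raise ValueError("missing cells are not supported (balanced design)")
    n = Y.shape[0]
    levels = Y.shape[1:]
    k_fac = len(levels)
    names = factor_names or ["A", "B", "C"][:k_fac]
    if len(names) != k_fac:
        raise ValueError("one factor name per factor axis")
    Yf = Y.reshape(n, -1)

    effects: list[AnovaEffect] = []
    from itertools import combinations
    for r in range(1, k_fac + 1):
        for combo in combinations(range(k_fac), r):
            K = np.ones((1, 1))
            for f in range(k_fac):
                M = (_orthonormal_contrasts(levels[f]) if f in combo
                     else np.full((levels[f], 1), 1 / np.sqrt(levels[f])))
                K = np.kron(K, M)
            Z = Yf @ K                         # subjects × q
            q = Z.shape[1]
            zbar = Z.mean(axis=0)
            ss_eff = n * float(zbar @ zbar)
            R = Z - zbar
            ss_err = float((R ** 2).sum())
            df1, df2 = q, q * (n - 1)
            F = (ss_eff / df1) / (ss_err / df2) if ss_err > 0 else np.inf
            if q > 1 and n > 1:
                S = (R.T @ R) / (n - 1)
                tr = np.trace(S)
                eps = float(tr ** 2 / (q * np.trace(S @ S))) if tr > 0 else 1.0
                eps = min(1.0, max(eps, 1.0 / q))
            else:
                eps = 1.0
            p_unc = float(sps.f.sf(F, df1, df2))
            e = eps if (gg and q > 1) else 1.0
            p = float(sps.f.sf(F, df1 * e, df2 * e))
            effects.append(AnovaEffect(
                effect=" × ".join(names[f] for f in combo), F=float(F),
                df1=df1, df2=df2, epsilon=eps, p=p, p_uncorrected=p_unc,
                ss_effect=ss_eff, ss_error=ss_err))
    return effects


def paired_t(x, y, alternative: str = "two-sided"):
    """Post hoc paired t test; returns (t, df, p)."""
    res = sps.ttest_rel(np.asarray(x, float), np.asarray(y, float),
                        alternative=alternative)
    return float(res.statistic), len(np.asarray(x)) - 1, float(res.pvalue)


# ---------------------------------------------------------------------------
# robust Spearman correlation
# ---------------------------------------------------------------------------

@dataclass
class RobustCorrelation:
    rho: float
    p: float
    sided: str
    direction: str
    outliers: np.ndarray
    flags: dict = field(default_factory=dict)
    n_used: int = 0


def _sn_scale(x: np.ndarray) -> float:
    """Rousseeuw–Croux Sn robust scale (naive O(n²) medians-of-differences)."""
    n = len(x)
    d = np.abs(x[:, None] - x[None, :])
    per_point = np.array([np.median(np.delete(d[i], i)) for i in range(n)])
    return 1.1926 * float(np.median(per_point))


def _flag_univariate(x: np.ndarray, method: str, cutoff: float = 2.24) -> np.ndarray:
    med = np.median(x)
    if method == "boxplot":
        q1, q3 = np.percentile(x, [25, 75])
        iqr = q3 - q1
        return (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)
    if method == "mad":
        scale = 1.4826 * np.median(np.abs(x - med))
        return np.zeros(len(x), bool) if scale == 0 else np.abs(x - med) / scale > cutoff
    if method == "s":
        scale = _sn_scale(x)
        return np.zeros(len(x), bool) if scale == 0 else np.abs(x - med) / scale > cutoff
    raise ValueError(method)


def robust_spearman(x, y, sided: str = "one", direction: str = "negative",
                    seed: int | None = None) -> RobustCorrelation:
    """Spearman correlation after triple-method bivariate outlier rejection.

    A point is flagged by a method if it is an outlier on either variable
    under that method's rule (boxplot whiskers at 1.5·IQR; median absolute
    deviation and Sn robust scale with the 2.24 ≈ √χ²₀.₉₇₅ cutoff).  Only
    points flagged by *all three* methods are removed.  With ``sided="one"``
    the p-value is one-sided in the declared ``direction``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-D arrays")
    flags = {}
    for method in ("boxplot", "mad", "s"):
        flags[method] = _flag_univariate(x, method) | _flag_univariate(y, method)
    outliers = flags["boxplot"] & flags["mad"] & flags["s"]
    keep = ~outliers
    if keep.sum() < 5:
        raise ValueError("fewer than 5 points after outlier removal")
    if sided == "one":
        alternative = "less" if direction == "negative" else "greater"
    else:
        alternative = "two-sided"
    rho, p = sps.spearmanr(x[keep], y[keep], alternative=alternative)
    return RobustCorrelation(rho=float(rho), p=float(p), sided=sided,
                             direction=direction,
                             outliers=np.flatnonzero(outliers),
                             flags={k: np.flatnonzero(v) for k, v in flags.items()},
                             n_used=int(keep.sum()))
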