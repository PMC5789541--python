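"""Permutation-null variance-explained testing of genetic principal components
against microbiome features, plus rank-based superclass enrichment.

The core statistic is the OLS R-squared of each (log10-transformed) microbial
feature on the first five genotype principal components. Its null distribution
is built by shuffling donor labels: each permutation applies ONE shared shuffle
to the whole feature table, which preserves inter-feature correlation and
makes the site-level mean-R-squared null valid. Per-feature empirical p-values
use the add-one estimator (1 + #{permuted >= observed}) / (B + 1), bounded
below by 1/(B+1) — at B = 10,000 the floor is about 1e-4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import AbundanceTable
from .genotypes import PCAResult

__all__ = [
    "variance_explained",
    "empirical_p",
    "permutation_test",
    "bh_fdr",
    "rank_enrichment",
    "PermutationAssocResult",
    "EnrichmentResult",
    "PCVarianceModel",
]

MIN_COMPLETE_CASES = 8


def empirical_p(observed: float, permuted: np.ndarray) -> float:
    """Add-one empirical p-value: (1 + #{permuted >= observed}) / (B + 1).

    Ties count as exceedances (conservative); the result is bounded below by
    1/(B+1), so B = 10,000 can resolve p down to about 1e-4 but never zero.
    """
    permuted = np.asarray(permuted, dtype=float)
    B = permuted.size
    return (1.0 + float(np.sum(permuted >= observed))) / (B + 1.0)


def _design(pcs: np.ndarray) -> np.ndarray:
    n = pcs.shape[0]
    return np.column_stack([np.ones(n), pcs])


def variance_explained(y: np.ndarray, pcs: np.ndarray) -> float:
    """R-squared of one feature vector on an intercept plus the PC scores.

    Missing feature values are excluded pairwise; at least
    ``MIN_COMPLETE_CASES`` complete cases are required. Constant features have
    no defined R-squared and return NaN with a warning.
    """
    y = np.asarray(y, dtype=float)
    pcs = np.asarray(pcs, dtype=float)
    if y.shape[0] != pcs.shape[0]:
        raise ValueError("feature vector and PC scores must align by donor")
    ok = np.isfinite(y)
    if ok.sum() < MIN_COMPLETE_CASES:
        warnings.warn("fewer than 8 complete cases; R^2 undefined", stacklevel=2)
        return float("nan")
    yy = y[ok]
    X = _design(pcs[ok])
    ss_tot = float(((yy - yy.mean()) ** 2).sum())
    if ss_tot == 0.0:
        warnings.warn("constant feature; R^2 undefined", stacklevel=2)
        return float("nan")
    beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
    resid = yy - X @ beta
    return 1.0 - float((resid**2).sum()) / ss_tot


def _r2_all_features(Y: np.ndarray, X: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Vectorized per-column R^2 of Y on the design X (Q = orthonormal basis).

    Columns containing NaN fall back to the pairwise-deletion scalar path.
    """
    n, F = Y.shape
    out = np.full(F, np.nan)
    complete = ~np.isnan(Y).any(axis=0)
    if complete.any():
        Yc = Y[:, complete]
        col_mean = Yc.mean(axis=0)
        ss_tot = (Yc**2).sum(axis=0) - n * col_mean**2
        proj = Q.T @ Yc
        ss_fit = (proj**2).sum(axis=0) - n * col_mean**2
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(ss_tot > 0, ss_fit / ss_tot, np.nan)
        out[complete] = np.clip(r2, 0.0, 1.0)
    for f in np.flatnonzero(~complete):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[f] = variance_explained(Y[:, f], X[:, 1:])
    return out


@dataclass
class PermutationAssocResult:
    """Per-feature and site-level permutation-null association results."""

    features: list[str]
    r2_obs: np.ndarray
    p_emp: np.ndarray
    q: np.ndarray
    mean_r2_obs: float
    perm_mean_r2: np.ndarray
    z: float
    p_site: float
    B: int
    seed: int
    body_site: str = ""

    def feature_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.features, "r2_obs": self.r2_obs,
             "p_emp": self.p_emp, "q": self.q}
        )

    def ranked_features(self) -> list[str]:
        """Feature names ordered by decreasing R^2 (ties broken by name)."""
        order = sorted(
            range(len(self.features)),
            key=lambda i: (-np.nan_to_num(self.r2_obs[i], nan=-1.0), self.features[i]),
        )
        return [self.features[i] for i in order]

    def summary(self) -> str:
        lines = [
            "Permutation variance-explained test",
            "=" * 48,
            f"Body site:            {self.body_site or '-'}",
            f"Features tested:      {len(self.features)}",
            f"Permutations (B):     {self.B}",
            f"Mean R^2 (observed):  {self.mean_r2_obs:.4f}",
            f"Mean R^2 (null mean): {np.mean(self.perm_mean_r2):.4f}",
            f"Site Z-score:         {self.z:.3f}",
            f"Site empirical p:     {self.p_site:.4g}",
            f"Features with q<0.05: {int((self.q < 0.05).sum())}",
        ]
        return "\n".join(lines)


def permutation_test(
    table: AbundanceTable,
    pcs: PCAResult | pd.DataFrame,
    B: int = 10_000,
    seed: int = 0,
) -> PermutationAssocResult:
    """Permutation-null R^2 test of every feature against five genotype PCs.

    Each of the ``B`` permutations draws one shared donor-label shuffle applied
    to all features. The site statistic is the across-feature mean R^2; its
    Z-score and empirical p come from the same permuted datasets.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    scores = pcs.scores_frame() if isinstance(pcs, PCAResult) else pcs
    donors = table.donors
    missing = [d for d in donors if d not in scores.index]
    if missing:
        raise ValueError(f"donors missing PC scores: {missing[:5]}")
    P = scores.loc[donors].to_numpy(dtype=float)
    Y = table.values.to_numpy(dtype=float)
    n = Y.shape[0]
    X = _design(P)
    Q, _ = np.linalg.qr(X)

    r2_obs = _r2_all_features(Y, X, Q)
    rng = np.random.default_rng(seed)
    r2_perm = np.empty((B, Y.shape[1]))
    for b in range(B):
        Yp = Y[rng.permutation(n)]
        r2_perm[b] = _r2_all_features(Yp, X, Q)

    exceed = np.sum(r2_perm >= r2_obs[None, :], axis=0)
    p_emp = (1.0 + exceed) / (B + 1.0)  # vectorized empirical_p per feature
    p_emp[~np.isfinite(r2_obs)] = np.nan
    q = np.full_like(p_emp, np.nan)
    ok = np.isfinite(p_emp)
    q[ok] = bh_fdr(p_emp[ok])

    mean_r2_obs = float(np.nanmean(r2_obs))
    perm_mean = np.nanmean(r2_perm, axis=1)
    sd = float(np.std(perm_mean, ddof=1))
    if sd == 0.0:
        warnings.warn("permutation mean R^2 has zero spread; Z undefined",
                      stacklevel=2)
        z = float("nan")
    else:
        z = (mean_r2_obs - float(np.mean(perm_mean))) / sd
    p_site = empirical_p(mean_r2_obs, perm_mean)

    return PermutationAssocResult(
        features=table.features,
        r2_obs=r2_obs,
        p_emp=p_emp,
        q=q,
        mean_r2_obs=mean_r2_obs,
        perm_mean_r2=perm_mean,
        z=z,
        p_site=p_site,
        B=B,
        seed=seed,
        body_site=table.body_site,
    )


class PCVarianceModel:
    """Model object tying a prepared feature table to genotype PC scores.

    ``fit`` runs the permutation framework and returns a
    :class:`PermutationAssocResult`; ``enrichment`` ranks features of a fitted
    result and scores superclass skew toward the top.
    """

    def __init__(self, table: AbundanceTable, pcs: PCAResult | pd.DataFrame):
        if not table.transformed:
            raise ValueError("feature table must be log10-transformed before fitting")
        self.table = table
        self.pcs = pcs

    def fit(self, B: int = 10_000, seed: int = 0) -> PermutationAssocResult:
        return permutation_test(self.table, self.pcs, B=B, seed=seed)

    @staticmethod
    def enrichment(result: PermutationAssocResult, class_map: dict[str, str],
                   method: str = "beta") -> list["EnrichmentResult"]:
        return rank_enrichment(result.ranked_features(), class_map, method=method)


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class EnrichmentResult:
    """Skew of one superclass's members toward the top of a feature ranking."""

    superclass: str
    k: int
    ranks: np.ndarray  # sorted normalized member ranks in (0, 1]
    score: float  # minimum Beta order-statistic tail probability
    p: float


def rank_enrichment(
    feature_ranking: list[str],
    class_map: dict[str, str],
    method: str = "beta",
) -> list[EnrichmentResult]:
    """Score how strongly each superclass's members skew toward the top ranks.

    ``feature_ranking`` is ordered by decreasing association strength. For a
    class with k members at normalized ranks r_(1) <= ... <= r_(k) (rank/n),
    the robust-rank-aggregation score is rho = min_j P(Beta(j, k-j+1) <=
    r_(j)) and the reported p-value is min(1, k * rho) (Bonferroni over the
    minimum). ``method="wilcoxon"`` instead tests member ranks against
    non-member ranks with a one-sided rank-sum test.
    """
    if method not in ("beta", "wilcoxon"):
        raise ValueError(f"unknown enrichment method {method!r}")
    n = len(feature_ranking)
    rank_of = {f: i + 1 for i, f in enumerate(feature_ranking)}
    classes: dict[str, list[int]] = {}
    for f, cls in class_map.items():
        if f in rank_of:
            classes.setdefault(cls, []).append(rank_of[f])
    skipped = set(class_map.values()) - set(classes)
    for cls in sorted(skipped):
        warnings.warn(f"superclass {cls!r} has no ranked members; skipped",
                      stacklevel=2)
    out = []
    for cls, ranks in sorted(classes.items()):
        ranks = np.sort(np.asarray(ranks, dtype=float))
        r = ranks / n
        k = len(ranks)
        if method == "beta":
            j = np.arange(1, k + 1)
            tails = stats.beta.cdf(r, j, k - j + 1)
            rho = float(tails.min())
            p = min(1.0, k * rho)
        else:
            member = set(ranks.astype(int))
            others = [i for i in range(1, n + 1) if i not in member]
            if not others:
                rho, p = 1.0, 1.0
            else:
                res = stats.mannwhitneyu(ranks, others, alternative="less")
                rho = p = float(res.pvalue)
        out.append(EnrichmentResult(cls, k, r, rho, p))
    out.sort(key=lambda e: (e.p, e.superclass))
    return out
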