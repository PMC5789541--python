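"""Genotype data model, variant QC, PCA, and KING-robust kinship estimation.

Dosages count alternate alleles (0/1/2); missing calls are ``NaN``. All
downstream analyses (population-structure PCA, relatedness inference) operate
on this in-memory matrix regardless of whether it came from a VCF or a
simulation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "PCAResult",
    "KinshipResult",
    "filter_variants",
    "genotype_pca",
    "king_kinship",
    "classify_relatedness",
    "pairwise_kinship",
    "KINSHIP_DEGREE_BOUNDS",
]

#: Lower bounds of the kinship-coefficient intervals used to call relatedness
#: degree: third degree [0.0442, 0.0884), second [0.0884, 0.177), first
#: [0.177, 0.354), twin/duplicate >= 0.354; below 0.0442 is unrelated.
KINSHIP_DEGREE_BOUNDS = {
    "twin": 0.354,
    "1": 0.177,
    "2": 0.0884,
    "3": 0.0442,
}


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant with QC summary statistics.

    ``maf`` and ``call_rate`` are derived from the dosage matrix and are kept
    consistent with it by :meth:`GenotypeMatrix.recompute_stats`.
    """

    chrom: str
    pos: int
    id: str
    ref: str = "A"
    alt: str = "G"
    maf: float = float("nan")
    call_rate: float = float("nan")

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")


@dataclass
class GenotypeMatrix:
    """Donor x variant alternate-allele dosage matrix.

    Parameters
    ----------
    donors
        Ordered donor identifiers (rows).
    variants
        Ordered :class:`VariantRecord` list (columns).
    dosages
        Float array of shape ``(n_donors, n_variants)`` with values in
        {0, 1, 2} and ``NaN`` for missing calls.
    """

    donors: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.donors), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.donors)} donors x {len(self.variants)} variants"
            )
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValueError(f"malformed dosage values: {bad}")

    @property
    def n_donors(self) -> int:
        return len(self.donors)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def alt_allele_frequencies(self) -> np.ndarray:
        """Per-variant alternate-allele frequency among non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            return np.nanmean(self.dosages, axis=0) / 2.0

    def recompute_stats(self) -> "GenotypeMatrix":
        """Return a copy whose VariantRecords carry fresh MAF and call rate."""
        p = self.alt_allele_frequencies()
        maf = np.minimum(p, 1.0 - p)
        call = 1.0 - np.isnan(self.dosages).mean(axis=0)
        variants = [
            replace(v, maf=float(m), call_rate=float(c))
            for v, m, c in zip(self.variants, maf, call)
        ]
        return GenotypeMatrix(list(self.donors), variants, self.dosages.copy())

    def dosage_for(self, donor: str) -> np.ndarray:
        return self.dosages[self.donors.index(donor)]


def filter_variants(
    gm: GenotypeMatrix, maf_min: float = 0.05, call_rate_min: float = 0.95
) -> GenotypeMatrix:
    """Keep variants with MAF strictly above ``maf_min`` and call rate strictly
    above ``call_rate_min``.

    Both inequalities are strict, matching the common-variant definition
    MAF > 0.05 and call rate > 95%. Donor order is unchanged; a new matrix is
    returned. Idempotent.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0.0 <= call_rate_min <= 1.0:
        raise ValueError("call_rate_min must be in [0, 1]")
    p = gm.alt_allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    call = 1.0 - np.isnan(gm.dosages).mean(axis=0)
    keep = (maf > maf_min) & (call > call_rate_min)
    if not keep.any():
        warnings.warn("no variants pass the MAF/call-rate filter", stacklevel=2)
    variants = [
        replace(v, maf=float(m), call_rate=float(c))
        for v, m, c, k in zip(gm.variants, maf, call, keep)
        if k
    ]
    return GenotypeMatrix(list(gm.donors), variants, gm.dosages[:, keep])


@dataclass
class PCAResult:
    """Principal components of the standardized genotype matrix.

    ``scores`` are donor coordinates (donor x k), ``loadings`` variant weights
    (variant x k), ``variance_fraction`` the per-component share of total
    variance of the standardized matrix.
    """

    scores: np.ndarray
    loadings: np.ndarray
    variance_fraction: np.ndarray
    donors: list[str]

    def scores_frame(self) -> pd.DataFrame:
        k = self.scores.shape[1]
        return pd.DataFrame(
            self.scores, index=self.donors, columns=[f"PC{i + 1}" for i in range(k)]
        )


def genotype_pca(gm: GenotypeMatrix, k: int = 5) -> PCAResult:
    """PCA on the mean-imputed, allele-frequency-standardized dosage matrix.

    Missing dosages are imputed with the per-variant mean (2p̂); each column is
    centred by 2p̂ and scaled by sqrt(2p̂(1-p̂)). Monomorphic or all-missing
    variants are dropped with a warning. The sign of each component is fixed so
    the loading vector sums to a nonnegative value, making the output
    deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = gm.dosages.copy()
    p = gm.alt_allele_frequencies()
    keep = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    n_dropped = gm.n_variants - int(keep.sum())
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped} monomorphic or all-missing variants before PCA",
            stacklevel=2,
        )
    X = X[:, keep]
    p = p[keep]
    if X.shape[1] == 0:
        raise ValueError("no polymorphic variants available for PCA")
    # mean imputation == centring missing entries to 0 after standardization
    col_mean = 2.0 * p
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    Z = (X - col_mean) / np.sqrt(2.0 * p * (1.0 - p))
    rank = np.linalg.matrix_rank(Z)
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank ({rank}) of the genotype matrix")
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    total_var = float((s**2).sum())
    if total_var == 0.0:
        raise ValueError("degenerate input: all donors identical after standardization")
    # sign convention: nonnegative loading sum per component
    signs = np.where(Vt[:k].sum(axis=1) >= 0.0, 1.0, -1.0)
    scores = U[:, :k] * s[:k] * signs
    loadings = Vt[:k].T * signs
    varfrac = (s[:k] ** 2) / total_var
    return PCAResult(scores, loadings, varfrac, list(gm.donors))


@dataclass(frozen=True)
class KinshipResult:
    """KING-robust kinship estimate for one donor pair."""

    donor_i: str
    donor_j: str
    phi: float
    n_used: int
    degree: str


def king_kinship(g_i: np.ndarray, g_j: np.ndarray) -> tuple[float, int]:
    """KING-robust kinship coefficient from two dosage vectors.

    With N_Aa,Aa the number of sites heterozygous in both donors, N_AA,aa the
    number with opposite homozygotes, and N_Aa^(i), N_Aa^(j) the per-donor
    heterozygote counts (all over sites non-missing in both):

        phi = (N_Aa,Aa - 2 * N_AA,aa) / (N_Aa^(i) + N_Aa^(j))

    The sum-denominator form has expectation equal to the kinship coefficient
    for non-inbred pairs and returns exactly 0.5 for duplicate genotypes.
    Returns ``(phi, n_used)``; ``phi`` is NaN (with a warning) if neither donor
    carries a heterozygote at the shared sites.
    """
    g_i = np.asarray(g_i, dtype=float)
    g_j = np.asarray(g_j, dtype=float)
    if g_i.shape != g_j.shape:
        raise ValueError("genotype vectors must have equal length")
    ok = ~(np.isnan(g_i) | np.isnan(g_j))
    a, b = g_i[ok], g_j[ok]
    n_used = int(ok.sum())
    het_i = a == 1
    het_j = b == 1
    n_het_het = int((het_i & het_j).sum())
    n_opp_hom = int((np.abs(a - b) == 2).sum())
    denom = int(het_i.sum()) + int(het_j.sum())
    if denom == 0:
        warnings.warn("no heterozygous sites; kinship undefined", stacklevel=2)
        return float("nan"), n_used
    return (n_het_het - 2.0 * n_opp_hom) / denom, n_used


def classify_relatedness(phi: float) -> str:
    """Map a kinship coefficient to a relatedness degree label.

    Half-open intervals: [0.0442, 0.0884) third degree, [0.0884, 0.177) second,
    [0.177, 0.354) first, >= 0.354 twin/duplicate, below 0.0442 unrelated.
    phi = 0.354 itself is assigned to the twin class.
    """
    if not np.isfinite(phi):
        raise ValueError("phi must be finite")
    if phi >= KINSHIP_DEGREE_BOUNDS["twin"]:
        return "twin"
    if phi >= KINSHIP_DEGREE_BOUNDS["1"]:
        return "1"
    if phi >= KINSHIP_DEGREE_BOUNDS["2"]:
        return "2"
    if phi >= KINSHIP_DEGREE_BOUNDS["3"]:
        return "3"
    return "unrelated"


def pairwise_kinship(
    gm: GenotypeMatrix, maf_min: float = 0.05, call_rate_min: float = 0.95
) -> list[KinshipResult]:
    """KING-robust kinship for all donor pairs on common well-called variants.

    Applies the same MAF/call-rate filter used for PCA before estimation, then
    evaluates every unordered donor pair.
    """
    fm = filter_variants(gm, maf_min=maf_min, call_rate_min=call_rate_min)
    out = []
    for i, j in itertools.combinations(range(fm.n_donors), 2):
        phi, n_used = king_kinship(fm.dosages[i], fm.dosages[j])
        degree = classify_relatedness(phi) if np.isfinite(phi) else "undefined"
        out.append(KinshipResult(fm.donors[i], fm.donors[j], phi, n_used, degree))
    return out


def kinship_frame(results: list[KinshipResult]) -> pd.DataFrame:
    """Tabulate kinship results (donor_i, donor_j, phi, n_used, degree)."""
    return pd.DataFrame(
        [(r.donor_i, r.donor_j, r.phi, r.n_used, r.degree) for r in results],
        columns=["donor_i", "donor_j", "phi", "n_used", "degree"],
    )
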