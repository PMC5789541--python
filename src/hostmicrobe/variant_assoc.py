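"""Targeted genotype-taxon tests and the covariate-adjusted genome-wide scan.

Single-variant association uses ordinary linear models of transformed feature
abundance on encoded genotype with sex, self-reported ethnicity, and sample
collection site as covariates (categoricals one-hot encoded against a
reference level). The scan statistic is computed Matrix-eQTL style: feature
and genotype are both residualized on the covariate design, and the t-test on
the residual Pearson correlation is algebraically identical to the OLS
coefficient test on genotype in the full model. Post-processing covers
positional clumping of per-feature hits (min-p representative), gene
annotation within a window, Bonferroni thresholds, and Q-Q diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import AbundanceTable
from .genotypes import GenotypeMatrix, VariantRecord, filter_variants
from .pc_assoc import bh_fdr

__all__ = [
    "AssociationRecord",
    "ClumpedAssociation",
    "GeneInterval",
    "encode_genotype",
    "linear_assoc",
    "targeted_screen",
    "gwas_scan",
    "bonferroni_threshold",
    "clump_associations",
    "annotate_genes",
    "qq_points",
    "build_covariates",
    "TargetedScreen",
    "GenomeWideScan",
]


@dataclass(frozen=True)
class AssociationRecord:
    """One SNV-feature linear-model result."""

    variant: VariantRecord
    feature: str
    body_site: str
    beta: float
    t_stat: float
    p: float
    n: int
    df: int


@dataclass
class ClumpedAssociation:
    """A positional group of associations for one feature.

    Consecutive member positions differ by at most the clump gap; the
    representative is the minimum-p member (ties to the smaller position).
    """

    members: list[AssociationRecord]
    representative: AssociationRecord
    span: tuple[int, int]


@dataclass(frozen=True)
class GeneInterval:
    """A gene with 1-based inclusive genomic coordinates."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene}: start > end")


def encode_genotype(dosage: float, model: str = "additive") -> float:
    """Numeric genotype encoding for association models.

    additive: the alternate-allele dose 0/1/2. recessive_alt: 1 for alternate
    homozygotes, 0 otherwise (heterozygotes carry a working copy). Missing
    (NaN) propagates.
    """
    if isinstance(dosage, np.ndarray):
        out = np.asarray(dosage, dtype=float)
        if model == "additive":
            return out
        if model == "recessive_alt":
            return np.where(np.isnan(out), np.nan, (out == 2.0).astype(float))
        raise ValueError(f"unknown genetic model {model!r}")
    if np.isnan(dosage):
        return float("nan")
    if dosage not in (0.0, 1.0, 2.0):
        raise ValueError(f"invalid dosage {dosage!r}")
    if model == "additive":
        return float(dosage)
    if model == "recessive_alt":
        return 1.0 if dosage == 2.0 else 0.0
    raise ValueError(f"unknown genetic model {model!r}")


def build_covariates(metadata: pd.DataFrame, donors: list[str]) -> np.ndarray:
    """Covariate design from donor metadata: sex, ethnicity, collection site.

    Categorical columns are one-hot encoded with the first level as reference,
    matching an ordinary linear model with factor covariates. Returns the
    covariate matrix without intercept, aligned to ``donors``.
    """
    cols = [c for c in ("sex", "ethnicity", "collection_site") if c in metadata]
    if not cols:
        raise ValueError("metadata must contain sex/ethnicity/collection_site")
    sub = metadata.loc[donors, cols]
    dummies = pd.get_dummies(sub, columns=cols, drop_first=True, dtype=float)
    return dummies.to_numpy(dtype=float)


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def linear_assoc(
    y: np.ndarray,
    g: np.ndarray,
    covars: np.ndarray | None,
    variant: VariantRecord | None = None,
    feature: str = "",
    body_site: str = "",
) -> AssociationRecord:
    """Covariate-adjusted linear association of one feature with one genotype.

    Complete-case analysis over (y, g, covars). Both y and g are residualized
    on [intercept | covars]; with r the Pearson correlation of residuals and
    df = n - rank(design) - 1, t = r * sqrt(df / (1 - r^2)) and p is the
    two-sided Student-t tail. beta = cov(res_y, res_g) / var(res_g), exactly
    the OLS coefficient on g in the full model.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    n_all = y.shape[0]
    if g.shape[0] != n_all:
        raise ValueError("y and g must align")
    if covars is not None:
        covars = np.asarray(covars, dtype=float)
        if covars.ndim == 1:
            covars = covars[:, None]
        if covars.shape[0] != n_all:
            raise ValueError("covariates must align with y")
        ok = np.isfinite(y) & np.isfinite(g) & np.isfinite(covars).all(axis=1)
    else:
        ok = np.isfinite(y) & np.isfinite(g)
    yy, gg = y[ok], g[ok]
    n = int(ok.sum())
    design = np.ones((n, 1))
    if covars is not None:
        C = covars[ok]
        full = np.column_stack([design, C])
        rank = np.linalg.matrix_rank(full)
        if rank < full.shape[1]:
            # identify collinear columns by incremental rank
            bad = []
            kept = design
            for j in range(C.shape[1]):
                cand = np.column_stack([kept, C[:, j]])
                if np.linalg.matrix_rank(cand) == kept.shape[1]:
                    bad.append(j)
                else:
                    kept = cand
            raise ValueError(f"rank-deficient covariates: columns {bad} collinear")
        design = full
    k = design.shape[1]
    if n < k + 3:
        raise ValueError(f"too few complete cases (n={n}) for {k} design columns")
    if np.ptp(gg) == 0.0:
        raise ValueError("genotype constant after complete-case deletion")
    res_g = _residualize(gg, design)
    # residual variance at float-noise scale means g lies in the covariate span
    if float(res_g @ res_g) <= 1e-10 * float(gg @ gg):
        raise ValueError("genotype collinear with covariates")
    res_y = _residualize(yy, design)
    df = n - k - 1
    var_g = float(res_g @ res_g)
    var_y = float(res_y @ res_y)
    cov_yg = float(res_y @ res_g)
    beta = cov_yg / var_g
    if var_y == 0.0:
        r = 0.0
    else:
        r = cov_yg / np.sqrt(var_y * var_g)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df)
    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    return AssociationRecord(
        variant=variant or VariantRecord("?", 1, "?"),
        feature=feature,
        body_site=body_site,
        beta=float(beta),
        t_stat=float(t),
        p=p,
        n=n,
        df=int(df),
    )


def targeted_screen(
    table: AbundanceTable,
    g: np.ndarray,
    donors: list[str],
    covars: np.ndarray | None = None,
    test: str = "regression",
    variant: VariantRecord | None = None,
) -> pd.DataFrame:
    """Test one encoded genotype against every feature of a prepared table.

    ``regression`` fits the covariate-adjusted linear model per feature;
    ``t_test`` compares transformed abundance between the two encoded groups
    with an equal-variance two-sample Student t-test (``g`` must be binary).
    Returns a DataFrame with one row per feature and a BH q-value across the
    screen. Features whose test is undefined (constant genotype after case
    deletion, or a group of < 2 in t_test mode) are skipped with a warning.
    """
    if not table.transformed:
        raise ValueError("targeted_screen expects a log10-transformed table")
    if test not in ("regression", "t_test", "welch_t_test"):
        raise ValueError(f"unknown test {test!r}")
    g = np.asarray(g, dtype=float)
    donor_pos = {d: i for i, d in enumerate(donors)}
    try:
        rows = [donor_pos[d] for d in table.donors]
    except KeyError as e:
        raise ValueError(f"table donor {e} has no genotype") from None
    gg = g[rows]
    C = covars[rows] if covars is not None else None
    records = []
    for feat in table.features:
        y = table.values[feat].to_numpy(dtype=float)
        try:
            if test == "regression":
                rec = linear_assoc(y, gg, C, variant=variant, feature=feat,
                                   body_site=table.body_site)
                records.append((feat, rec.beta, rec.t_stat, rec.p, rec.n))
            else:
                ok = np.isfinite(y) & np.isfinite(gg)
                groups = np.unique(gg[ok])
                if len(groups) != 2:
                    raise ValueError("t-test requires a binary genotype encoding")
                a = y[ok & (gg == groups[1])]
                b = y[ok & (gg == groups[0])]
                if len(a) < 2 or len(b) < 2:
                    raise ValueError("group with fewer than 2 members")
                res = stats.ttest_ind(a, b, equal_var=(test == "t_test"))
                records.append(
                    (feat, float(a.mean() - b.mean()), float(res.statistic),
                     float(res.pvalue), int(ok.sum()))
                )
        except ValueError as err:
            warnings.warn(f"feature {feat!r} skipped: {err}", stacklevel=2)
    out = pd.DataFrame(records, columns=["feature", "beta", "t", "p", "n"])
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    else:
        out["q"] = []
    return out


def gwas_scan(
    gm: GenotypeMatrix,
    table: AbundanceTable,
    metadata: pd.DataFrame | None = None,
    maf_min: float = 0.1,
    variant_subset: list[str] | None = None,
    covars: np.ndarray | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted linear scan over every (variant, feature) pair.

    Variants are filtered to MAF strictly above ``maf_min`` computed on the
    donors present in the table; ``variant_subset`` (a list of variant ids,
    e.g. a GWAS-catalog-style panel) restricts the scan to those variants
    before filtering. Returns one record per pair in a long DataFrame; the
    attribute ``.attrs["n_tests"]`` carries the exact test count for
    Bonferroni control.
    """
    if not table.transformed:
        raise ValueError("gwas_scan expects a log10-transformed table")
    donors = table.donors
    missing = [d for d in donors if d not in gm.donors]
    if missing:
        raise ValueError(f"donors missing genotypes: {missing[:5]}")
    rows = [gm.donors.index(d) for d in donors]
    sub = GenotypeMatrix(donors, list(gm.variants), gm.dosages[rows])
    if variant_subset is not None:
        keep = [i for i, v in enumerate(sub.variants) if v.id in set(variant_subset)]
        sub = GenotypeMatrix(donors, [sub.variants[i] for i in keep],
                             sub.dosages[:, keep])
    sub = filter_variants(sub, maf_min=maf_min, call_rate_min=0.0)
    if covars is None and metadata is not None:
        covars = build_covariates(metadata, donors)
    Y = table.values.to_numpy(dtype=float)
    records = []
    for vi, variant in enumerate(sub.variants):
        g = sub.dosages[:, vi]
        for fi, feat in enumerate(table.features):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rec = linear_assoc(Y[:, fi], g, covars, variant=variant,
                                       feature=feat, body_site=table.body_site)
            except ValueError:
                continue
            records.append((variant.chrom, variant.pos, variant.id, feat,
                            table.body_site, rec.beta, rec.t_stat, rec.p, rec.n))
    out = pd.DataFrame(
        records,
        columns=["chrom", "pos", "id", "feature", "body_site",
                 "beta", "t", "p", "n"],
    )
    out.attrs["n_tests"] = len(out)
    return out


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def clump_associations(
    records: list[AssociationRecord], max_gap: int = 10_000
) -> list[ClumpedAssociation]:
    """Greedy positional clumping of one feature's associations.

    Records must share one feature and contig and be sorted ascending by
    position. A new group starts whenever the gap to the previous variant
    exceeds ``max_gap`` (a gap of exactly ``max_gap`` stays in the group). The
    representative is the smallest-p member, ties to the smaller position.
    """
    if not records:
        return []
    feats = {r.feature for r in records}
    chroms = {r.variant.chrom for r in records}
    if len(feats) > 1 or len(chroms) > 1:
        raise ValueError("clumping operates on one feature and one contig")
    positions = [r.variant.pos for r in records]
    if positions != sorted(positions):
        raise ValueError("records must be sorted ascending by position")
    groups: list[list[AssociationRecord]] = [[records[0]]]
    for prev, rec in zip(records, records[1:]):
        if rec.variant.pos - prev.variant.pos > max_gap:
            groups.append([rec])
        else:
            groups[-1].append(rec)
    out = []
    for members in groups:
        rep = min(members, key=lambda r: (r.p, r.variant.pos))
        out.append(
            ClumpedAssociation(
                members=members,
                representative=rep,
                span=(members[0].variant.pos, members[-1].variant.pos),
            )
        )
    return out


def annotate_genes(
    v: VariantRecord, genes: list[GeneInterval], window: int = 50_000
) -> list[str]:
    """Genes whose interval lies within ``window`` bp of the variant.

    A variant inside a gene has distance 0; otherwise distance is measured to
    the nearest interval edge and must be <= window.
    """
    out = []
    for g in genes:
        if g.chrom != v.chrom:
            continue
        if g.start - window <= v.pos <= g.end + window:
            out.append(g.gene)
    return out


def qq_points(pvals: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Expected vs observed -log10 p-values for a Q-Q plot, plus slope.

    Expected quantiles use the plotting positions (i - 0.5)/m; observed are
    the sorted -log10 p in decreasing order. The returned slope is the
    least-squares slope of observed on expected through the origin, a
    genomic-inflation-style diagnostic (~1 under the null).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("zero p-values clipped to machine minimum", stacklevel=2)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    m = p.size
    observed = -np.log10(np.sort(p))
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    slope = float((expected @ observed) / (expected @ expected))
    return expected, observed, slope


class TargetedScreen:
    """Model: one candidate variant against all features of one body site.

    Mirrors hypothesis-driven lookups (e.g. a secretor-status variant vs every
    stool species by dosage regression, or a recessive variant by two-group
    t-test of alternate homozygotes against everyone else).
    """

    def __init__(
        self,
        table: AbundanceTable,
        gm: GenotypeMatrix,
        variant_id: str,
        metadata: pd.DataFrame | None = None,
        model: str = "additive",
    ):
        self.table = table
        self.gm = gm
        self.metadata = metadata
        self.model = model
        idx = [i for i, v in enumerate(gm.variants) if v.id == variant_id]
        if not idx:
            raise KeyError(f"variant {variant_id!r} not in genotype matrix")
        self.variant = gm.variants[idx[0]]
        self._dosage = gm.dosages[:, idx[0]]

    def fit(self, test: str = "regression") -> "TargetedScreenResults":
        enc = "recessive_alt" if test != "regression" else (
            "recessive_alt" if self.model == "recessive" else "additive"
        )
        g = encode_genotype(self._dosage, enc)
        covars = (
            build_covariates(self.metadata, self.gm.donors)
            if self.metadata is not None and test == "regression"
            else None
        )
        frame = targeted_screen(
            self.table, g, self.gm.donors, covars=covars, test=test,
            variant=self.variant,
        )
        return TargetedScreenResults(self.variant, test, frame)


@dataclass
class TargetedScreenResults:
    variant: VariantRecord
    test: str
    frame: pd.DataFrame

    def top(self, n: int = 5) -> pd.DataFrame:
        return self.frame.nsmallest(n, "p").reset_index(drop=True)

    def summary(self) -> str:
        best = self.frame.loc[self.frame["p"].idxmin()]
        return "\n".join([
            f"Targeted screen: variant {self.variant.id} "
            f"({self.variant.chrom}:{self.variant.pos}), test={self.test}",
            f"Features tested:  {len(self.frame)}",
            f"Top feature:      {best['feature']}",
            f"  beta/delta:     {best['beta']:.4f}",
            f"  t, p, q:        {best['t']:.3f}, {best['p']:.3g}, {best['q']:.3g}",
        ])


class GenomeWideScan:
    """Model: all common variants against all features, with covariates."""

    def __init__(
        self,
        gm: GenotypeMatrix,
        table: AbundanceTable,
        metadata: pd.DataFrame | None = None,
        maf_min: float = 0.1,
        variant_subset: list[str] | None = None,
    ):
        self.gm = gm
        self.table = table
        self.metadata = metadata
        self.maf_min = maf_min
        self.variant_subset = variant_subset

    def fit(self, alpha: float = 0.05) -> "GenomeWideScanResults":
        frame = gwas_scan(
            self.gm, self.table, metadata=self.metadata,
            maf_min=self.maf_min, variant_subset=self.variant_subset,
        )
        return GenomeWideScanResults(frame, alpha)


@dataclass
class GenomeWideScanResults:
    frame: pd.DataFrame
    alpha: float = 0.05

    @property
    def n_tests(self) -> int:
        return int(self.frame.attrs.get("n_tests", len(self.frame)))

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.n_tests, self.alpha)

    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["p"] < self.threshold]

    def clump(self, feature: str, max_gap: int = 10_000) -> list[ClumpedAssociation]:
        sub = self.frame[self.frame["feature"] == feature].sort_values("pos")
        records = [
            AssociationRecord(
                VariantRecord(r.chrom, int(r.pos), r.id), r.feature, r.body_site,
                r.beta, r.t, r.p, int(r.n), int(r.n) - 2,
            )
            for r in sub.itertuples()
        ]
        return clump_associations(records, max_gap=max_gap)

    def qq(self) -> tuple[np.ndarray, np.ndarray, float]:
        return qq_points(self.frame["p"].to_numpy())

    def summary(self) -> str:
        _, _, slope = self.qq() if len(self.frame) else (None, None, float("nan"))
        return "\n".join([
            "Genome-wide variant-feature scan",
            "=" * 48,
            f"Tests performed:      {self.n_tests}",
            f"Bonferroni threshold: {self.threshold:.3g} (alpha={self.alpha})",
            f"Significant pairs:    {len(self.significant())}",
            f"Q-Q slope:            {slope:.3f}",
            f"Minimum p:            {self.frame['p'].min():.3g}"
            if len(self.frame) else "Minimum p:            -",
        ])
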