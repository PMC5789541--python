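"""Synthetic cohort generator: structured genotypes, pedigree pairs, and
zero-inflated compositional microbiome profiles with planted genetic effects.

The generator emulates the data structure of a multi-ancestry human cohort
profiled at one body site: genotypes follow a Balding-Nichols model (ancestral
allele frequency drawn per variant, population-specific frequencies Beta-drifted
around it with divergence F), a handful of donor pairs are replaced by
pedigree-simulated relatives, and microbial feature abundances are log-normal
latent variables onto which principal-component-level and single-variant
effects can be planted. Every stage derives its random stream from the one
config seed, so a config reproduces the cohort bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance import AbundanceTable
from .genotypes import GenotypeMatrix, VariantRecord, filter_variants, genotype_pca

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_genotypes",
    "simulate_related_pair",
    "simulate_microbiome",
    "simulate_cohort",
]

# fixed per-stage offsets expanding the global seed into independent streams
_STAGE_GENOTYPES = 1
_STAGE_PEDIGREE = 2
_STAGE_MICROBIOME = 3
_STAGE_METADATA = 4

_CHROM = "chrS"
_CHROM_LENGTH = 50_000_000

RELATEDNESS_DEGREES = ("twin", "1", "2", "3")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults mirror the structure of the cohort the pipeline targets: ~300
    donors from five self-reported ancestry groups dominated by one (71%),
    recruited at two collection sites, with a dozen cryptically related pairs
    (eleven first-degree, one third-degree) and one body site of zero-inflated
    species and pathway profiles.
    """

    n_donors: int = 300
    n_variants: int = 5000
    n_populations: int = 5
    fst: float = 0.1
    population_weights: tuple[float, ...] = (0.71, 0.06, 0.09, 0.11, 0.03)
    related_pairs: tuple[tuple[str, int], ...] = (("1", 11), ("3", 1))
    n_species: int = 150
    n_pathways: int = 400
    prevalence_range: tuple[float, float] = (0.3, 0.95)
    zero_inflation: float = 0.3
    planted_pc_effects: tuple[tuple[int, int, float], ...] = ()
    planted_variant_effects: tuple[tuple[int, int, str, float], ...] = ()
    replicates_per_donor: int = 1
    sigma_feature: float = 1.0
    sigma_replicate: float = 0.1
    body_site: str = "stool"
    seed: int = 0

    def __post_init__(self):
        for name in ("n_donors", "n_variants", "n_populations", "n_species",
                     "n_pathways", "replicates_per_donor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie strictly inside (0, 1)")
        w = np.asarray(self.population_weights, dtype=float)
        if len(w) != self.n_populations:
            raise ValueError("population_weights length must equal n_populations")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("population_weights must sum to 1")
        lo, hi = self.prevalence_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("prevalence_range must be an ordered pair in (0, 1]")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must be a probability")
        for degree, count in self.related_pairs:
            if degree not in RELATEDNESS_DEGREES:
                raise ValueError(f"unknown relatedness degree {degree!r}")
            if count < 0:
                raise ValueError("related pair counts must be >= 0")
        for fi, pc, slope in self.planted_pc_effects:
            if not (0 <= fi < self.n_species):
                raise ValueError("planted PC effect feature index out of bounds")
            if not (0 <= pc < 5):
                raise ValueError("planted PC index must be in [0, 5)")
            if not np.isfinite(slope):
                raise ValueError("planted slopes must be finite")
        for vi, fi, model, slope in self.planted_variant_effects:
            if not (0 <= vi < self.n_variants):
                raise ValueError("planted variant index out of bounds")
            if not (0 <= fi < self.n_species):
                raise ValueError("planted variant effect feature index out of bounds")
            if model not in ("additive", "recessive"):
                raise ValueError(f"unknown genetic model {model!r}")
            if not np.isfinite(slope):
                raise ValueError("planted slopes must be finite")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent generator for one pipeline stage under the global seed."""
        return np.random.default_rng([self.seed, stage])


@dataclass
class SyntheticCohort:
    """A complete simulated study: genotypes, tables, metadata, and truth."""

    genotypes: GenotypeMatrix
    species_table: AbundanceTable
    pathway_table: AbundanceTable
    metadata: pd.DataFrame
    truth: dict


def _population_sizes(n: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n donors to populations."""
    raw = weights * n
    sizes = np.floor(raw).astype(int)
    short = n - sizes.sum()
    order = np.argsort(-(raw - sizes))
    sizes[order[:short]] += 1
    return sizes


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Balding-Nichols genotypes for a multi-population cohort.

    Per variant, the ancestral frequency is Uniform(0.05, 0.95); each
    population drifts it with Beta(p0(1-F)/F, (1-p0)(1-F)/F); each donor draws
    Binomial(2, p_pop). Variant positions are placed uniformly along one
    synthetic 50-Mb chromosome and sorted.
    """
    rng = config.rng(_STAGE_GENOTYPES)
    F = config.fst
    p0 = rng.uniform(0.05, 0.95, size=config.n_variants)
    shape = (1.0 - F) / F
    pop_freqs = rng.beta(
        p0 * shape, (1.0 - p0) * shape, size=(config.n_populations, config.n_variants)
    )
    pop_freqs = np.clip(pop_freqs, 1e-6, 1.0 - 1e-6)
    # planted single-variant effects emulate validated common-variant
    # associations; keep those variants common in every population so they
    # survive downstream MAF filters
    planted = sorted({vi for vi, *_ in config.planted_variant_effects})
    if planted:
        pop_freqs[:, planted] = np.clip(pop_freqs[:, planted], 0.2, 0.8)
    sizes = _population_sizes(
        config.n_donors, np.asarray(config.population_weights, dtype=float)
    )
    pop_of_donor = np.repeat(np.arange(config.n_populations), sizes)
    dosages = rng.binomial(2, pop_freqs[pop_of_donor, :]).astype(float)
    positions = np.sort(rng.integers(1, _CHROM_LENGTH + 1, size=config.n_variants))
    variants = [
        VariantRecord(_CHROM, int(pos), f"var{i}") for i, pos in enumerate(positions)
    ]
    donors = [f"D{i:04d}" for i in range(config.n_donors)]
    gm = GenotypeMatrix(donors, variants, dosages)
    gm.population_of_donor = pop_of_donor  # simulation-truth annotation
    gm.population_freqs = pop_freqs
    return gm


def _mendel_allele(rng: np.random.Generator, dosage: np.ndarray) -> np.ndarray:
    """One allele transmitted from a parent genotype (Mendelian segregation)."""
    return (rng.random(dosage.shape) < dosage / 2.0).astype(float)


def simulate_related_pair(
    freqs: np.ndarray,
    degree: str,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one pair of relatives from per-variant allele frequencies.

    twin: a duplicated genotype vector. 1 (parent-offspring): the child
    inherits one parental allele and one population allele. 2 (half-sibs): two
    children of one shared mother and independent fathers. 3 (first cousins):
    a four-founder pedigree — a shared grandparental couple has two children
    who each mate with an independent founder.
    """
    freqs = np.asarray(freqs, dtype=float)
    if not ((freqs > 0) & (freqs < 1)).all():
        raise ValueError("allele frequencies must lie strictly inside (0, 1)")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )

    def founder():
        return rng.binomial(2, freqs).astype(float)

    if degree == "twin":
        g = founder()
        return g, g.copy()
    if degree == "1":
        parent = founder()
        child = _mendel_allele(rng, parent) + rng.binomial(1, freqs)
        return parent, child
    if degree == "2":
        mother = founder()
        sibs = tuple(
            _mendel_allele(rng, mother) + _mendel_allele(rng, founder())
            for _ in range(2)
        )
        return sibs
    if degree == "3":
        grandma, grandpa = founder(), founder()
        cousins = []
        for _ in range(2):
            sib = _mendel_allele(rng, grandma) + _mendel_allele(rng, grandpa)
            spouse = founder()
            cousins.append(_mendel_allele(rng, sib) + _mendel_allele(rng, spouse))
        return cousins[0], cousins[1]
    raise ValueError(f"unknown relatedness degree {degree!r}")


def _plant_relatives(
    gm: GenotypeMatrix, config: SimulationConfig
) -> list[tuple[str, str, str]]:
    """Overwrite donor pairs with pedigree-simulated relatives, in place.

    Pairs are taken as consecutive donors within the largest population so both
    members share population allele frequencies. Returns the truth list of
    (donor_i, donor_j, degree).
    """
    rng = config.rng(_STAGE_PEDIGREE)
    pop_of_donor = gm.population_of_donor
    pop = int(np.bincount(pop_of_donor).argmax())
    members = np.flatnonzero(pop_of_donor == pop)
    freqs = gm.population_freqs[pop]
    truth = []
    cursor = 0
    for degree, count in config.related_pairs:
        for _ in range(count):
            if cursor + 1 >= len(members):
                raise ValueError("not enough donors to host the requested related pairs")
            i, j = int(members[cursor]), int(members[cursor + 1])
            cursor += 2
            g_i, g_j = simulate_related_pair(freqs, degree, rng)
            gm.dosages[i] = g_i
            gm.dosages[j] = g_j
            truth.append((gm.donors[i], gm.donors[j], degree))
    return truth


def _encode(dosage_col: np.ndarray, model: str) -> np.ndarray:
    filled = np.where(np.isnan(dosage_col), np.nanmean(dosage_col), dosage_col)
    if model == "additive":
        return filled
    return (filled == 2.0).astype(float)


def simulate_microbiome(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[AbundanceTable, AbundanceTable, dict]:
    """Zero-inflated compositional profiles with planted genetic effects.

    Each feature's latent log10 abundance per donor is a Normal(mu_f,
    sigma_feature) baseline plus any planted effects: PC effects add
    slope x (standardized donor PC score); variant effects add
    slope x encoded genotype. Replicate samples add Normal(0, sigma_replicate)
    within-donor noise. Zeros are introduced independently per entry with
    probability zero_inflation * (1 - pi_f), pi_f ~ Uniform(prevalence_range),
    after which species rows are renormalized to relative abundance; pathway
    values stay on the reads-per-million scale.

    Returns (species table, pathway table, truth-warnings record).
    """
    rng = config.rng(_STAGE_MICROBIOME)
    n = genotypes.n_donors
    warnings_record: list[str] = []

    pc_scores = None
    if config.planted_pc_effects:
        common = filter_variants(genotypes, 0.05, 0.95)
        pca = genotype_pca(common, k=5)
        pc_scores = pca.scores / pca.scores.std(axis=0, ddof=0)

    tables = {}
    for kind, n_feat, mu_range in (
        ("species", config.n_species, (-4.0, -1.0)),
        ("pathway", config.n_pathways, (1.0, 4.0)),
    ):
        mu = rng.uniform(*mu_range, size=n_feat)
        latent = mu + rng.normal(0.0, config.sigma_feature, size=(n, n_feat))
        if kind == "species":
            for fi, pc, slope in config.planted_pc_effects:
                latent[:, fi] += slope * pc_scores[:, pc]
            for vi, fi, model, slope in config.planted_variant_effects:
                latent[:, fi] += slope * _encode(genotypes.dosages[:, vi], model)
        # replicate samples
        reps = config.replicates_per_donor
        sample_latent = np.repeat(latent, reps, axis=0)
        if reps > 1:
            sample_latent = sample_latent + rng.normal(
                0.0, config.sigma_replicate, size=sample_latent.shape
            )
        sample_ids = [
            f"{d}_{config.body_site}_r{r}"
            for d in genotypes.donors
            for r in range(reps)
        ]
        donor_of_sample = {
            s: d for s, d in zip(sample_ids, np.repeat(genotypes.donors, reps))
        }
        abundance = np.power(10.0, sample_latent)
        pi = rng.uniform(*config.prevalence_range, size=n_feat)
        zero_prob = config.zero_inflation * (1.0 - pi)
        zero_mask = rng.random(abundance.shape) < zero_prob
        abundance[zero_mask] = 0.0
        planted_feats = {fi for fi, *_ in config.planted_pc_effects} | {
            fi for _, fi, *_ in config.planted_variant_effects
        }
        if kind == "species":
            for fi in planted_feats:
                if not abundance[:, fi].any():
                    warnings_record.append(
                        f"planted effect on species index {fi} zeroed in all samples"
                    )
            row_sums = abundance.sum(axis=1, keepdims=True)
            np.divide(abundance, row_sums, out=abundance, where=row_sums > 0)
        values = pd.DataFrame(
            abundance,
            index=sample_ids,
            columns=[f"{kind}_{i}" for i in range(n_feat)],
        )
        tables[kind] = AbundanceTable(
            values, donor_of_sample, config.body_site, kind=kind
        )
    for msg in warnings_record:
        warnings.warn(msg, stacklevel=2)
    return tables["species"], tables["pathway"], {"warnings": warnings_record}


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the full synthetic study for one body site."""
    gm = simulate_genotypes(config)
    related_truth = _plant_relatives(gm, config)
    species, pathways, micro_truth = simulate_microbiome(gm, config)

    meta_rng = config.rng(_STAGE_METADATA)
    ethnicity = [f"pop{p}" for p in gm.population_of_donor]
    metadata = pd.DataFrame(
        {
            "donor": gm.donors,
            "sex": meta_rng.choice(["female", "male"], size=gm.n_donors),
            "ethnicity": ethnicity,
            "collection_site": meta_rng.choice(["siteA", "siteB"], size=gm.n_donors),
        }
    ).set_index("donor")

    truth = {
        "related_pairs": related_truth,
        "planted_pc_effects": [list(e) for e in config.planted_pc_effects],
        "planted_variant_effects": [list(e) for e in config.planted_variant_effects],
        "warnings": micro_truth["warnings"],
        "seed": config.seed,
    }
    return SyntheticCohort(gm, species, pathways, metadata, truth)
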