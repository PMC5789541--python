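"""Readers, writers, and pipeline configuration.

On-disk conventions: genotypes travel as minimal VCFv4.2 with a GT field;
abundance tables as TSV with features in rows, samples in columns, and "NA"
for missing; metadata as one TSV row per sample (sample_id, donor, body_site,
sex, ethnicity, collection_site); gene intervals as BED (0-based half-open on
disk, 1-based inclusive in memory). All writes are atomic (temp file then
rename).
"""

from __future__ import annotations

import json
import os
import tempfile
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .abundance import AbundanceTable
from .genotypes import GenotypeMatrix, KinshipResult, PCAResult, VariantRecord
from .variant_assoc import GeneInterval

__all__ = [
    "PipelineConfig",
    "read_vcf",
    "write_vcf",
    "read_abundance",
    "write_abundance",
    "read_metadata",
    "write_metadata",
    "write_kinship",
    "write_pca_scores",
    "read_gene_bed",
    "read_class_map",
    "atomic_write_text",
]


@dataclass
class PipelineConfig:
    """All fixed thresholds of the pipeline, with their standard defaults."""

    vcf: str | None = None
    species_table: str | None = None
    pathway_table: str | None = None
    metadata: str | None = None
    gene_bed: str | None = None
    class_map: str | None = None
    maf_min_pca: float = 0.05
    call_rate_min: float = 0.95
    maf_min_gwas: float = 0.1
    species_prevalence: float = 0.25
    pathway_prevalence: float = 0.75
    pseudocount: float = 1e-5
    clump_gap: int = 10_000
    gene_window: int = 50_000
    B: int = 10_000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.maf_min_pca <= 0.5 or not 0.0 <= self.maf_min_gwas <= 0.5:
            raise ValueError("MAF thresholds must be in [0, 0.5]")
        if not 0.0 <= self.call_rate_min <= 1.0:
            raise ValueError("call_rate_min must be in [0, 1]")
        for name in ("species_prevalence", "pathway_prevalence"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.clump_gap < 0 or self.gene_window < 0:
            raise ValueError("genomic windows must be nonnegative")
        if self.B < 100:
            raise ValueError("B must be at least 100")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        atomic_write_text(path, yaml.safe_dump(asdict(self), sort_keys=False))


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text to ``path`` via a temp file in the same directory + rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_vcf(gm: GenotypeMatrix, path: str | Path, contig_length: int = 50_000_000):
    """Write a minimal VCFv4.2 (GT only) for one synthetic contig."""
    chroms = {v.chrom for v in gm.variants}
    lines = [
        "##fileformat=VCFv4.2",
        *(f"##contig=<ID={c},length={contig_length}>" for c in sorted(chroms)),
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.donors),
    ]
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j, v in enumerate(gm.variants):
        calls = [
            gt_of.get(d, "./.") if not np.isnan(d) else "./."
            for d in gm.dosages[:, j]
        ]
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
            + "\t".join(calls)
        )
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read genotypes from a VCF with GT calls.

    Dosage counts alternate alleles; "./." becomes missing. Multi-allelic
    records are skipped with a warning. Donor order follows the VCF header.
    """
    vcf = VCF(str(path), gts012=False)
    donors = list(vcf.samples)
    variants, rows = [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        dos = np.full(len(donors), np.nan)
        for i, gt in enumerate(rec.genotypes):
            a = [x for x in gt[:-1] if x is not None and x >= 0]
            if len(a) == 2:
                dos[i] = float(sum(1 for x in a if x > 0))
        variants.append(
            VariantRecord(rec.CHROM, rec.POS, rec.ID or f"{rec.CHROM}:{rec.POS}",
                          rec.REF, rec.ALT[0])
        )
        rows.append(dos)
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic records", stacklevel=2)
    if not variants:
        raise ValueError(f"no usable biallelic records in {path}")
    gm = GenotypeMatrix(donors, variants, np.array(rows).T)
    return gm.recompute_stats()


def write_abundance(t: AbundanceTable, path: str | Path) -> None:
    """Feature x sample TSV, first column the feature name, missing as NA."""
    frame = t.values.T  # features in rows
    frame.index.name = "feature"
    atomic_write_text(path, frame.to_csv(sep="\t", na_rep="NA"))


def read_abundance(
    path: str | Path,
    kind: str,
    sample_map: pd.DataFrame,
    body_site: str | None = None,
    transformed: bool = False,
) -> AbundanceTable:
    """Read a feature x sample TSV into an :class:`AbundanceTable`.

    ``sample_map`` is the per-sample metadata frame (from
    :func:`read_metadata`); if ``body_site`` is given the table is restricted
    to that site's samples.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup = {s for i, s in enumerate(header) if s in header[:i]}
    if dup:
        raise ValueError(f"duplicated sample columns: {sorted(dup)}")
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    bad = frame.map(lambda v: isinstance(v, str)).to_numpy().any()
    if bad:
        raise ValueError("non-numeric abundance cells found")
    values = frame.T  # samples in rows
    sm = sample_map.set_index("sample_id") if "sample_id" in sample_map else sample_map
    if body_site is not None:
        keep = [s for s in values.index
                if s in sm.index and sm.loc[s, "body_site"] == body_site]
        values = values.loc[keep]
    else:
        sites = {sm.loc[s, "body_site"] for s in values.index if s in sm.index}
        if len(sites) != 1:
            raise ValueError("table spans multiple body sites; pass body_site")
        body_site = sites.pop()
    donor_of = {s: sm.loc[s, "donor"] for s in values.index}
    return AbundanceTable(values, donor_of, body_site, kind=kind,
                          transformed=transformed)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    atomic_write_text(path, meta.to_csv(sep="\t", index=False))


def read_metadata(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read per-sample metadata; returns (sample frame, donor-level frame).

    The TSV must have columns sample_id, donor, body_site, sex, ethnicity,
    collection_site.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "donor", "body_site", "sex", "ethnicity",
                "collection_site"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if frame["sample_id"].duplicated().any():
        dups = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicated sample ids: {dups}")
    donor_level = (
        frame[["donor", "sex", "ethnicity", "collection_site"]]
        .drop_duplicates("donor")
        .set_index("donor")
    )
    return frame, donor_level


def sample_metadata_from_cohort(cohort) -> pd.DataFrame:
    """Flatten a SyntheticCohort into the per-sample metadata TSV layout."""
    rows = []
    for table in (cohort.species_table, cohort.pathway_table):
        for s in table.samples:
            d = table.sample_donor[s]
            rows.append({
                "sample_id": s,
                "donor": d,
                "body_site": table.body_site,
                **cohort.metadata.loc[d].to_dict(),
            })
    return pd.DataFrame(rows).drop_duplicates("sample_id")


def write_kinship(results: list[KinshipResult], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(r.donor_i, r.donor_j, r.phi, r.n_used, r.degree) for r in results],
        columns=["donor_i", "donor_j", "phi", "n_used", "degree"],
    )
    atomic_write_text(path, frame.to_csv(sep="\t", index=False))


def write_pca_scores(pca: PCAResult, path: str | Path) -> None:
    frame = pca.scores_frame()
    frame.index.name = "donor"
    atomic_write_text(path, frame.to_csv(sep="\t"))


def read_pca_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gene_bed(path: str | Path) -> list[GeneInterval]:
    """Read BED gene intervals, converting to 1-based inclusive coordinates."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            out.append(GeneInterval(name, chrom, start + 1, end))
    return out


def read_class_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (feature, superclass) TSV with a header line."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError("class map needs feature and superclass columns")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def write_truth(truth: dict, path: str | Path) -> None:
    atomic_write_text(path, json.dumps(truth, indent=2, sort_keys=True) + "\n")
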