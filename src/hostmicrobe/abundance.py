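"""Abundance-table data model and microbiome feature preparation.

Species tables hold relative abundances (fractions summing to <= 1 per
sample); pathway tables hold reads-per-million-scale abundances. Preparation
for association testing follows the pipeline: average replicate samples per
donor on the raw scale, prevalence-filter features, then log10-transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "average_replicates",
    "prevalence_filter",
    "log_transform",
    "bray_curtis",
    "prepare_features",
]


@dataclass
class AbundanceTable:
    """Sample x feature nonnegative abundance matrix for one body site.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, one column per feature. ``NaN`` marks
        a value excluded from model fits (only produced by the present-only
        log transform).
    sample_donor
        Mapping of every sample id to its donor id (total map).
    body_site
        The single body site all samples come from.
    kind
        ``"species"`` (relative abundance) or ``"pathway"`` (reads per
        million).
    transformed
        True once values are on the log10 scale.
    """

    values: pd.DataFrame
    sample_donor: dict[str, str]
    body_site: str
    kind: str = "species"
    transformed: bool = False

    def __post_init__(self):
        if self.kind not in ("species", "pathway"):
            raise ValueError(f"unknown table kind {self.kind!r}")
        missing = set(self.values.index) - set(self.sample_donor)
        if missing:
            raise ValueError(f"samples without a donor mapping: {sorted(missing)}")
        if not self.transformed:
            v = self.values.to_numpy(dtype=float)
            if np.nanmin(v, initial=0.0) < 0.0:
                raise ValueError("untransformed abundances must be nonnegative")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    @property
    def donors(self) -> list[str]:
        return [self.sample_donor[s] for s in self.samples]

    def copy_with(self, values: pd.DataFrame, **kw) -> "AbundanceTable":
        base = dict(
            sample_donor=dict(self.sample_donor),
            body_site=self.body_site,
            kind=self.kind,
            transformed=self.transformed,
        )
        base.update(kw)
        return AbundanceTable(values, **base)


def average_replicates(t: AbundanceTable) -> AbundanceTable:
    """Average replicate samples of the same donor on the raw abundance scale.

    Returns a table with one row per donor, indexed by donor id. Donors with a
    single sample pass through unchanged. Rejects transformed input: averaging
    is defined on relative abundances, not their logarithms.
    """
    if t.transformed:
        raise ValueError("average_replicates requires untransformed abundances")
    donor = pd.Series({s: t.sample_donor[s] for s in t.samples})
    averaged = t.values.groupby(donor.reindex(t.values.index)).mean()
    averaged = averaged.loc[pd.unique(donor.to_numpy())]  # keep first-seen order
    return t.copy_with(averaged, sample_donor={d: d for d in averaged.index})


def prevalence_filter(
    t: AbundanceTable, threshold: float, strict: bool | None = None
) -> AbundanceTable:
    """Drop features below a prevalence threshold (presence = value > 0).

    Species mode keeps features present in at least ``threshold`` of samples
    (non-strict, default threshold 0.25); pathway mode keeps those present in
    more than ``threshold`` (strict, default 0.75). ``strict`` overrides the
    kind-based default.
    """
    if t.transformed:
        raise ValueError("prevalence_filter requires untransformed abundances")
    if strict is None:
        strict = t.kind == "pathway"
    prevalence = (t.values > 0).mean(axis=0)
    keep = prevalence > threshold if strict else prevalence >= threshold
    if not keep.any():
        warnings.warn("no features pass the prevalence filter", stacklevel=2)
    return t.copy_with(t.values.loc[:, keep])


def log_transform(
    t: AbundanceTable,
    pseudocount: float = 1e-5,
    mode: str | None = None,
) -> AbundanceTable:
    """Log10-transform abundances.

    ``add_pseudocount`` (species default): value <- log10(value + pseudocount),
    defined everywhere; a zero relative abundance maps to log10(pseudocount).
    ``present_only`` (pathway default): value <- log10(value) where value > 0,
    zeros become NaN and are dropped from downstream model fits sample-wise.
    """
    if t.transformed:
        raise ValueError("table is already on the log10 scale")
    if mode is None:
        mode = "add_pseudocount" if t.kind == "species" else "present_only"
    if mode == "add_pseudocount":
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        out = np.log10(t.values + pseudocount)
    elif mode == "present_only":
        vals = t.values.where(t.values > 0)
        out = np.log10(vals)
    else:
        raise ValueError(f"unknown transform mode {mode!r}")
    return t.copy_with(out, transformed=True)


def prepare_features(
    t: AbundanceTable,
    species_prevalence: float = 0.25,
    pathway_prevalence: float = 0.75,
    pseudocount: float = 1e-5,
    donor_level_prevalence: bool = True,
) -> AbundanceTable:
    """Full feature-preparation pipeline for one body site.

    Averages replicates per donor, applies the kind-appropriate prevalence
    filter (donor-level by default, sample-level with
    ``donor_level_prevalence=False``), then the kind-appropriate log10
    transform.
    """
    if donor_level_prevalence:
        t = average_replicates(t)
        threshold = species_prevalence if t.kind == "species" else pathway_prevalence
        t = prevalence_filter(t, threshold)
    else:
        threshold = species_prevalence if t.kind == "species" else pathway_prevalence
        t = prevalence_filter(t, threshold)
        t = average_replicates(t)
    return log_transform(t, pseudocount=pseudocount)


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity between two nonnegative abundance vectors.

    BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i), in [0, 1]; 0 for identical
    profiles, 1 for disjoint supports. Similarity is reported as 1 - BC.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = float((x + y).sum())
    if total == 0.0:
        raise ValueError("Bray-Curtis undefined for two all-zero profiles")
    return float(np.abs(x - y).sum()) / total
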