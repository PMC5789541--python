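"""Microbiome similarity between related, same-ethnicity, and
different-ethnicity donor pairs at one body site.

Pairwise community similarity is 1 minus the Bray-Curtis dissimilarity of
untransformed relative-abundance profiles (whole-community, pre-filter).
Pairs are grouped by genetic relatedness first — any pair at third degree or
closer (kinship coefficient >= 0.0442) is a relative regardless of ethnicity —
and the remaining pairs split by equality of self-reported ethnicity. The
headline test contrasts relatives against ALL other pairs with a two-sample
t-test; the same- vs different-ethnicity mean gap is reported descriptively.
Pairwise similarities are not independent observations, so the t-test p-value
is approximate by construction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import AbundanceTable, bray_curtis
from .genotypes import KINSHIP_DEGREE_BOUNDS, KinshipResult

__all__ = [
    "PairGroupAssignment",
    "assign_pair_groups",
    "compare_groups",
    "RelatednessSimilarity",
    "RelatednessSimilarityResults",
]

RELATIVE_PHI_MIN = KINSHIP_DEGREE_BOUNDS["3"]  # third degree or closer


@dataclass(frozen=True)
class PairGroupAssignment:
    """One unordered donor pair with its group label and similarity."""

    donor_i: str
    donor_j: str
    group: str  # relatives | same ethnicity | different ethnicity
    body_site: str
    similarity: float


def assign_pair_groups(
    kinship: list[KinshipResult],
    metadata: pd.DataFrame,
    table: AbundanceTable,
) -> list[PairGroupAssignment]:
    """Group every profiled donor pair and attach its community similarity.

    Pairs with kinship phi >= 0.0442 (third degree or closer) are relatives;
    the rest split on ethnicity equality. Pairs where either donor lacks a
    profile at the table's body site are excluded (distance undefined); pairs
    with missing ethnicity are dropped with a warning. The table must hold
    untransformed relative abundances with one row per donor.
    """
    if table.transformed:
        raise ValueError("similarity is defined on untransformed abundances")
    phi_of = {}
    for r in kinship:
        key = frozenset((r.donor_i, r.donor_j))
        phi_of[key] = r.phi
    profiled = {table.sample_donor[s]: s for s in table.samples}
    values = table.values
    out = []
    for d_i, d_j in itertools.combinations(sorted(profiled), 2):
        if d_i not in metadata.index or d_j not in metadata.index:
            warnings.warn(f"pair ({d_i}, {d_j}) dropped: missing metadata",
                          stacklevel=2)
            continue
        eth_i = metadata.loc[d_i, "ethnicity"]
        eth_j = metadata.loc[d_j, "ethnicity"]
        if pd.isna(eth_i) or pd.isna(eth_j):
            warnings.warn(f"pair ({d_i}, {d_j}) dropped: missing ethnicity",
                          stacklevel=2)
            continue
        phi = phi_of.get(frozenset((d_i, d_j)), float("-inf"))
        if np.isfinite(phi) and phi >= RELATIVE_PHI_MIN:
            group = "relatives"
        elif eth_i == eth_j:
            group = "same ethnicity"
        else:
            group = "different ethnicity"
        bc = bray_curtis(
            values.loc[profiled[d_i]].to_numpy(),
            values.loc[profiled[d_j]].to_numpy(),
        )
        out.append(
            PairGroupAssignment(d_i, d_j, group, table.body_site, 1.0 - bc)
        )
    return out


def compare_groups(assignments: list[PairGroupAssignment]) -> pd.DataFrame:
    """Per-site comparison of similarity between relatives and all other pairs.

    Returns one row per group with n_pairs and mean similarity, plus the
    relatives-vs-rest Student t statistic and p-value attached to the
    relatives row (NaN when fewer than two relative pairs exist — the means
    are still reported). The same- minus different-ethnicity mean gap is in
    ``.attrs["ethnicity_gap"]``.
    """
    if not assignments:
        raise ValueError("no pair assignments to compare")
    sites = {a.body_site for a in assignments}
    if len(sites) > 1:
        raise ValueError("compare_groups operates on one body site at a time")
    sim = {g: [] for g in ("relatives", "same ethnicity", "different ethnicity")}
    for a in assignments:
        sim[a.group].append(a.similarity)
    rel = np.asarray(sim["relatives"])
    others = np.asarray(sim["same ethnicity"] + sim["different ethnicity"])
    t = p = float("nan")
    if len(rel) >= 2 and len(others) >= 2:
        res = stats.ttest_ind(rel, others, equal_var=True)
        t, p = float(res.statistic), float(res.pvalue)
    elif len(rel) < 2:
        warnings.warn("fewer than 2 relative pairs; reporting means only",
                      stacklevel=2)
    rows = []
    for g in ("relatives", "same ethnicity", "different ethnicity"):
        vals = np.asarray(sim[g])
        rows.append({
            "body_site": assignments[0].body_site,
            "group": g,
            "n_pairs": len(vals),
            "mean_similarity": float(vals.mean()) if len(vals) else float("nan"),
            "t": t if g == "relatives" else float("nan"),
            "p": p if g == "relatives" else float("nan"),
        })
    out = pd.DataFrame(rows)
    same = np.asarray(sim["same ethnicity"])
    diff = np.asarray(sim["different ethnicity"])
    out.attrs["ethnicity_gap"] = (
        float(same.mean() - diff.mean()) if len(same) and len(diff) else float("nan")
    )
    return out


class RelatednessSimilarity:
    """Model: kinship calls + metadata + one body site's abundance table."""

    def __init__(
        self,
        kinship: list[KinshipResult],
        metadata: pd.DataFrame,
        table: AbundanceTable,
    ):
        self.kinship = kinship
        self.metadata = metadata
        self.table = table

    def fit(self) -> "RelatednessSimilarityResults":
        assignments = assign_pair_groups(self.kinship, self.metadata, self.table)
        return RelatednessSimilarityResults(assignments, compare_groups(assignments))


@dataclass
class RelatednessSimilarityResults:
    assignments: list[PairGroupAssignment]
    frame: pd.DataFrame

    def summary(self) -> str:
        lines = [
            "Relatedness vs microbiome similarity",
            "=" * 48,
            f"Body site: {self.frame['body_site'].iloc[0]}",
        ]
        for r in self.frame.itertuples():
            lines.append(
                f"  {r.group:<20} n={r.n_pairs:<6} mean similarity="
                f"{r.mean_similarity:.4f}"
            )
        t = self.frame["t"].iloc[0]
        p = self.frame["p"].iloc[0]
        if np.isfinite(t):
            lines.append(f"Relatives vs all other pairs: t={t:.3f}, p={p:.3g}")
        else:
            lines.append("Relatives vs all other pairs: too few pairs for a t-test")
        return "\n".join(lines)
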