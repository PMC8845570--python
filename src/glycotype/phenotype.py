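"""Phenotype-level analyses: strain clustering, species coherence, co-occurrence.

Strains are clustered by their normalized carbohydrate-utilization profiles
with complete-linkage agglomeration on Euclidean distances.  Species
coherence in the resulting dendrogram is scored with a clustering index:
the number of strains of a species divided by the leaf count of the smallest
clade containing all of them (1.0 = the species forms a pure clade).
Substrate co-occurrence is the pairwise Pearson correlation of normalized
growth values across strains, with |r| >= 0.40 flagged by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree

from .growth import PhenotypeMatrix

__all__ = [
    "Dendrogram",
    "SpeciesClusterScore",
    "CorrelationMatrix",
    "cluster_strains",
    "species_clustering_index",
    "substrate_cooccurrence",
    "degrader_summary",
]


@dataclass
class Dendrogram:
    """A rooted binary merge tree over strains.

    Wraps a scipy linkage matrix together with the leaf labels; exposes the
    clade leaf-sets (for the species index) and Newick serialization.
    """

    labels: list[str]
    linkage_matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.linkage_matrix.shape != (len(self.labels) - 1, 4):
            raise ValueError("linkage matrix inconsistent with label count")

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def clades(self) -> list[frozenset[str]]:
        """Leaf-label sets of every node (leaves included), root last."""
        n = len(self.labels)
        sets: list[frozenset[str]] = [frozenset({lab}) for lab in self.labels]
        for a, b, _, _ in self.linkage_matrix:
            sets.append(sets[int(a)] | sets[int(b)])
        return sets

    def to_newick(self) -> str:
        root = to_tree(self.linkage_matrix)

        def render(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left = render(node.left)
            right = render(node.right)
            bl_l = node.dist - node.left.dist
            bl_r = node.dist - node.right.dist
            return f"({left}:{bl_l:.6g},{right}:{bl_r:.6g})"

        return render(root) + ";"


@dataclass(frozen=True)
class SpeciesClusterScore:
    species_id: str
    n_strains: int
    n_branches: int
    index: float
    uninformative: bool = False


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    flag_threshold: float = 0.40

    def flagged_pairs(self) -> pd.DataFrame:
        """Long-format table of substrate pairs with |r| >= flag_threshold."""
        subs = list(self.r.index)
        rows = []
        for i, a in enumerate(subs):
            for b in subs[i + 1 :]:
                val = self.r.loc[a, b]
                if pd.notna(val) and abs(val) >= self.flag_threshold:
                    rows.append({"substrate_a": a, "substrate_b": b, "r": float(val)})
        return pd.DataFrame(rows, columns=["substrate_a", "substrate_b", "r"])


def _feature_table(m: PhenotypeMatrix, features: str) -> pd.DataFrame:
    if features == "growth":
        return m.growth
    if features == "rate":
        return m.rate
    if features == "both":
        g = m.growth.add_suffix(":growth")
        r = m.rate.add_suffix(":rate")
        return pd.concat([g, r], axis=1)
    raise ValueError("features must be one of {'growth', 'rate', 'both'}")


def cluster_strains(m: PhenotypeMatrix, features: str = "both") -> Dendrogram:
    """Complete-linkage hierarchical clustering of strain profiles.

    ``features='both'`` concatenates the normalized growth and rate blocks
    column-wise (both already on [0, 1], no rescaling).  Distances are
    Euclidean between strain rows.
    """
    if m.stage not in ("strain_normalized", "substrate_normalized"):
        raise ValueError("cluster_strains expects a normalized matrix")
    table = _feature_table(m, features)
    if len(table) < 2:
        raise ValueError("need at least 2 strains to cluster")
    Z = linkage(table.to_numpy(dtype=float), method="complete", metric="euclidean")
    return Dendrogram(labels=[str(i) for i in table.index], linkage_matrix=Z)


def species_clustering_index(
    d: Dendrogram, labels: dict[str, str]
) -> list[SpeciesClusterScore]:
    """Score how coherently each species clusters in the dendrogram.

    For each species, ``n_branches`` is the leaf count of the smallest clade
    containing every strain of that species, and the index is
    ``n_strains / n_branches`` (perfect score 1 when the species forms a pure
    clade).  Single-strain species score 1 by definition and are marked
    uninformative.
    """
    missing = [leaf for leaf in d.labels if leaf not in labels]
    if missing:
        raise ValueError(f"unlabeled leaves: {', '.join(missing)}")
    clades = d.clades()
    scores = []
    by_species: dict[str, set[str]] = {}
    for strain, sp in labels.items():
        if strain in set(d.labels):
            by_species.setdefault(sp, set()).add(strain)
    for sp in sorted(by_species):
        members = by_species[sp]
        containing = [c for c in clades if members <= c]
        smallest = min(containing, key=len)
        n_branches = len(smallest)
        scores.append(
            SpeciesClusterScore(
                species_id=sp,
                n_strains=len(members),
                n_branches=n_branches,
                index=len(members) / n_branches,
                uninformative=len(members) == 1,
            )
        )
    return scores


def substrate_cooccurrence(
    m: PhenotypeMatrix, flag_threshold: float = 0.40
) -> CorrelationMatrix:
    """Pairwise Pearson correlation of normalized growth across strains.

    Constant (zero-variance) substrate columns yield missing entries.
    """
    if m.stage not in ("strain_normalized", "substrate_normalized"):
        raise ValueError("substrate_cooccurrence expects a normalized matrix")
    if len(m.growth) < 3:
        raise ValueError("need at least 3 strains for correlations")
    r = m.growth.corr(method="pearson")
    # pandas leaves constant columns as NaN rows/cols, including the diagonal
    const = m.growth.std(axis=0) == 0
    for sub in m.growth.columns[const]:
        r.loc[sub, :] = np.nan
        r.loc[:, sub] = np.nan
    return CorrelationMatrix(r=r, flag_threshold=flag_threshold)


def degrader_summary(
    calls: PhenotypeMatrix, labels: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Summarize which species degrade which substrates, and how penetrant.

    Returns (per-substrate table, per-strain table, overall stats).  For each
    substrate the per-substrate table counts species with at least one
    degrading strain and lists per-species penetrance (fraction of that
    species' strains that degrade it).  The per-strain table counts
    substrates degraded; overall stats report the mean / min / max of that
    count across all strains.
    """
    if calls.is_growth is None:
        raise ValueError("degrader_summary requires is_growth calls (called stage)")
    ig = calls.is_growth
    species = pd.Series({s: labels[s] for s in ig.index})

    sub_rows = []
    for sub in ig.columns:
        col = ig[sub]
        pen = col.groupby(species).mean()
        degrading = pen[pen > 0]
        sub_rows.append(
            {
                "substrate_id": sub,
                "n_degrading_species": int(len(degrading)),
                "penetrance": {sp: float(v) for sp, v in degrading.items()},
            }
        )
    per_substrate = pd.DataFrame(sub_rows)

    counts = ig.sum(axis=1).astype(int)
    per_strain = pd.DataFrame(
        {"strain_id": counts.index, "species_id": species.values, "n_degraded": counts.values}
    )
    stats = {
        "mean_degraded": float(counts.mean()),
        "min_degraded": int(counts.min()),
        "max_degraded": int(counts.max()),
    }
    return per_substrate, per_strain, stats
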