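"""Pangenome construction: gene families, core/accessory partition, PULs.

Gene families are connected components of the reciprocal-best-hit graph
between genomes at >=90% amino acid identity (global alignment, identity =
matches / alignment columns including gaps); within-genome duplicates at the
same cutoff are merged into their family.  The family x genome copy-number
matrix yields the gene-sharing spectrum and the core (present in all
genomes) / accessory / singleton partition.

Polysaccharide utilization loci (PULs) are called from gene order and
functional labels: an adjacent susC-susD transporter/binding-protein pair
seeds a locus that is extended over PUL-typical genes (susC/susD, GH/PL/CE
CAZymes, sulfatases, regulators) allowing short runs of unrelated genes, and
is kept only if it contains at least one degradative CAZyme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "Gene",
    "AnnotatedGenome",
    "GeneFamily",
    "FamilyMatrix",
    "PUL",
    "pairwise_identity",
    "build_gene_families",
    "family_matrix",
    "partition_core_accessory",
    "spectrum_fractions",
    "call_puls",
    "classify_puls_by_group",
    "activated_puls",
    "orf_size_check",
]

CAZYME_PREFIXES = ("GH", "PL", "CE")
PUL_LABELS_EXTEND = frozenset({"susC", "susD", "sulfatase", "regulator"})


def _is_cazyme(label: str) -> bool:
    return label.startswith(CAZYME_PREFIXES)


def _is_pulish(labels: frozenset[str]) -> bool:
    return bool(labels & PUL_LABELS_EXTEND) or any(_is_cazyme(l) for l in labels)


@dataclass(frozen=True)
class Gene:
    """One annotated gene: 1-based inclusive coordinates, protein sequence,
    functional labels (susC, susD, GH<n>/PL<n>/CE<n>, sulfatase, regulator,
    other) and optionally the nucleotide sequence."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    protein: str
    labels: frozenset[str] = frozenset({"other"})
    dna: str | None = None

    def __post_init__(self) -> None:
        if not self.protein:
            raise ValueError(f"gene {self.gene_id}: empty protein sequence")
        if self.start > self.end or self.start < 1:
            raise ValueError(f"gene {self.gene_id}: bad coordinates")


@dataclass
class AnnotatedGenome:
    genome_id: str
    species_id: str
    genes: list[Gene]

    def __post_init__(self) -> None:
        # gene order must follow coordinates within each contig
        by_contig: dict[str, list[Gene]] = {}
        for g in self.genes:
            by_contig.setdefault(g.contig, []).append(g)
        for contig, genes in by_contig.items():
            starts = [g.start for g in genes]
            if starts != sorted(starts):
                raise ValueError(f"{self.genome_id}/{contig}: genes out of coordinate order")

    def contigs(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.contig, []).append(g)
        return out


@dataclass
class GeneFamily:
    family_id: str
    members: list[tuple[str, str]]  # (genome_id, gene_id)
    representative: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("gene family must be nonempty")


_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=0,
    open_gap_score=-1,
    extend_gap_score=-1,
)


def pairwise_identity(p: str, q: str) -> float:
    """Global-alignment identity: matches / alignment columns (gaps included).

    Scoring is match=1, mismatch=0, gap=-1; among co-optimal alignments the
    aligner's first (deterministic) traceback is used.
    """
    if not p or not q:
        raise ValueError("sequences must be nonempty")
    if p == q:
        return 1.0
    aln = _aligner.align(p, q)[0]
    counts = aln.counts()
    columns = aln.length
    return counts.identities / columns


def _identity_at_least(p: str, q: str, cutoff: float) -> bool:
    """Cheap sound prefilter: identity >= cutoff implies the edit distance is
    at most (1 - cutoff) * (len(p) + len(q)), since every non-match column of
    the optimal alignment is one edit and columns <= len(p) + len(q)."""
    la, lb = len(p), len(q)
    if min(la, lb) / max(la, lb) < cutoff:  # identity <= min/max length
        return False
    k = math.floor((1 - cutoff) * (la + lb))
    return edlib.align(p, q, mode="NW", task="distance", k=k)["editDistance"] != -1


def build_gene_families(
    genomes: list[AnnotatedGenome], cutoff: float = 0.90
) -> list[GeneFamily]:
    """Cluster genes into families via reciprocal best hits at >= cutoff identity.

    For every ordered genome pair, each gene's best hit in the other genome is
    found (ties broken by gene id for determinism); mutual best hits with
    identity >= cutoff become edges.  Within-genome duplicates are joined when
    they reach the cutoff against another gene of the same genome.  Families
    are the connected components, so relatedness is transitively closed.
    The result is invariant to genome input order.
    """
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    genomes = sorted(genomes, key=lambda g: g.genome_id)
    seqs: dict[tuple[str, str], str] = {}
    for g in genomes:
        for gene in g.genes:
            seqs[(g.genome_id, gene.gene_id)] = gene.protein

    graph = nx.Graph()
    graph.add_nodes_from(seqs)

    def candidate_identity(a: tuple[str, str], b: tuple[str, str]) -> float | None:
        pa, pb = seqs[a], seqs[b]
        if not _identity_at_least(pa, pb, cutoff):
            return None
        ident = pairwise_identity(pa, pb)
        return ident if ident >= cutoff else None

    ident_cache: dict[tuple[tuple[str, str], tuple[str, str]], float | None] = {}

    def ident(a, b):
        key = (a, b) if a <= b else (b, a)
        if key not in ident_cache:
            ident_cache[key] = candidate_identity(*key)
        return ident_cache[key]

    for i, ga in enumerate(genomes):
        ids_a = sorted((ga.genome_id, gene.gene_id) for gene in ga.genes)
        for gb in genomes[i + 1 :]:
            ids_b = sorted((gb.genome_id, gene.gene_id) for gene in gb.genes)
            best_ab: dict[tuple[str, str], tuple[str, str]] = {}
            best_ba: dict[tuple[str, str], tuple[str, str]] = {}
            score_ab: dict[tuple[str, str], float] = {}
            score_ba: dict[tuple[str, str], float] = {}
            for a in ids_a:
                for b in ids_b:
                    s = ident(a, b)
                    if s is None:
                        continue
                    if s > score_ab.get(a, -1.0):
                        score_ab[a], best_ab[a] = s, b
                    if s > score_ba.get(b, -1.0):
                        score_ba[b], best_ba[b] = s, a
            for a, b in best_ab.items():
                if best_ba.get(b) == a:
                    graph.add_edge(a, b)
        # within-genome duplicate merge
        for j, a in enumerate(ids_a):
            for b in ids_a[j + 1 :]:
                if ident(a, b) is not None:
                    graph.add_edge(a, b)

    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    families = []
    for idx, comp in enumerate(components, start=1):
        members = sorted(comp)
        rep = max(members, key=lambda m: (len(seqs[m]), m))[1]
        families.append(
            GeneFamily(family_id=f"F{idx:05d}", members=members, representative=rep)
        )
    return families


@dataclass
class FamilyMatrix:
    """Family x genome copy-number matrix (rows = family ids)."""

    copy_number: pd.DataFrame

    @property
    def families(self) -> list[str]:
        return list(self.copy_number.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.copy_number.columns)

    def sharing_spectrum(self) -> dict[int, int]:
        """s(k) = number of families present (copy >= 1) in exactly k genomes."""
        presence = (self.copy_number > 0).sum(axis=1)
        return {int(k): int(v) for k, v in presence.value_counts().sort_index().items()}


def family_matrix(families: list[GeneFamily], genome_ids: list[str]) -> FamilyMatrix:
    data = pd.DataFrame(
        0, index=[f.family_id for f in families], columns=list(genome_ids), dtype=int
    )
    for fam in families:
        for genome_id, _ in fam.members:
            data.loc[fam.family_id, genome_id] += 1
    return FamilyMatrix(copy_number=data)


def spectrum_fractions(spectrum: dict[int, int], n_genomes: int) -> dict[str, float]:
    """Core / singleton counts and percentages (one decimal) from a spectrum."""
    total = sum(spectrum.values())
    core = spectrum.get(n_genomes, 0)
    singleton = spectrum.get(1, 0)
    return {
        "total": total,
        "core": core,
        "singleton": singleton,
        "core_pct": round(100.0 * core / total, 1),
        "singleton_pct": round(100.0 * singleton / total, 1),
    }


def partition_core_accessory(fm: FamilyMatrix) -> dict:
    """Partition families into core / accessory / singleton with fractions.

    Core families are present (copy >= 1) in every genome; singletons in
    exactly one; the remaining accessory families in 2..n-1.  Percentages are
    reported to one decimal.
    """
    presence = (fm.copy_number > 0).sum(axis=1)
    n = len(fm.genomes)
    core = sorted(presence.index[presence == n])
    singleton = sorted(presence.index[presence == 1])
    accessory = sorted(presence.index[(presence > 1) & (presence < n)])
    spectrum = fm.sharing_spectrum()
    return {
        "core": core,
        "accessory": accessory,
        "singleton": singleton,
        "spectrum": spectrum,
        "fractions": spectrum_fractions(spectrum, n),
    }


@dataclass
class PUL:
    """A called polysaccharide utilization locus: a contiguous gene-index span
    containing >=1 adjacent susC-susD pair and >=1 GH/PL/CE CAZyme."""

    pul_id: str
    genome_id: str
    contig: str
    start_index: int  # inclusive, index into the contig's gene list
    end_index: int  # inclusive
    gene_ids: list[str] = field(default_factory=list)
    susCD_pairs: list[tuple[str, str]] = field(default_factory=list)
    cazymes: list[tuple[str, str]] = field(default_factory=list)  # (gene_id, label)

    def __post_init__(self) -> None:
        if not self.susCD_pairs:
            raise ValueError(f"{self.pul_id}: PUL requires an adjacent susC-susD pair")
        if not self.cazymes:
            raise ValueError(f"{self.pul_id}: PUL requires a GH/PL/CE gene")


def _extend(genes: list[Gene], seed_lo: int, seed_hi: int, max_gap: int) -> tuple[int, int]:
    lo = seed_lo
    gap = 0
    i = seed_lo - 1
    while i >= 0:
        if _is_pulish(genes[i].labels):
            lo = i
            gap = 0
        else:
            gap += 1
            if gap > max_gap:
                break
        i -= 1
    hi = seed_hi
    gap = 0
    i = seed_hi + 1
    while i < len(genes):
        if _is_pulish(genes[i].labels):
            hi = i
            gap = 0
        else:
            gap += 1
            if gap > max_gap:
                break
        i += 1
    return lo, hi


def call_puls(g: AnnotatedGenome, max_gap: int = 2) -> list[PUL]:
    """Call PULs from gene order and labels.

    Each adjacent susC-susD pair (either order, any strand) seeds a span that
    is extended in both directions over PUL-typical genes, tolerating at most
    ``max_gap`` consecutive unrelated genes; trailing unrelated genes are not
    included.  Spans lacking a GH/PL/CE CAZyme are dropped; overlapping spans
    on a contig are merged.
    """
    puls: list[PUL] = []
    counter = 1
    for contig, genes in g.contigs().items():
        seeds = [
            i
            for i in range(len(genes) - 1)
            if ("susC" in genes[i].labels and "susD" in genes[i + 1].labels)
            or ("susD" in genes[i].labels and "susC" in genes[i + 1].labels)
        ]
        spans = [_extend(genes, i, i + 1, max_gap) for i in seeds]
        # merge overlapping spans
        merged: list[list[int]] = []
        for lo, hi in sorted(spans):
            if merged and lo <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        for lo, hi in merged:
            span = genes[lo : hi + 1]
            pairs = [
                (span[k].gene_id, span[k + 1].gene_id)
                for k in range(len(span) - 1)
                if ("susC" in span[k].labels and "susD" in span[k + 1].labels)
                or ("susD" in span[k].labels and "susC" in span[k + 1].labels)
            ]
            cazymes = [
                (gene.gene_id, lab)
                for gene in span
                for lab in sorted(gene.labels)
                if _is_cazyme(lab)
            ]
            if not pairs or not cazymes:
                continue
            puls.append(
                PUL(
                    pul_id=f"{g.genome_id}:PUL{counter:03d}",
                    genome_id=g.genome_id,
                    contig=contig,
                    start_index=lo,
                    end_index=hi,
                    gene_ids=[gene.gene_id for gene in span],
                    susCD_pairs=pairs,
                    cazymes=cazymes,
                )
            )
            counter += 1
    return puls


def classify_puls_by_group(
    puls: list[PUL],
    gene_to_family: dict[tuple[str, str], str],
    groups: dict[str, str],
    share_threshold: float = 0.5,
) -> dict[str, list[str]]:
    """Partition PULs into unique-to-degraders / unique-to-nondegraders / shared.

    Two PULs in different genomes are homologous when at least
    ``share_threshold`` of one PUL's gene families also occur in the other.
    A PUL is "shared" when it has a homolog in a genome of the opposite
    group, otherwise unique to its own group.
    """
    fam_sets = {
        p.pul_id: {
            gene_to_family[(p.genome_id, gid)]
            for gid in p.gene_ids
            if (p.genome_id, gid) in gene_to_family
        }
        for p in puls
    }
    out = {"unique_to_degraders": [], "unique_to_nondegraders": [], "shared": []}
    for p in puls:
        own = groups[p.genome_id]
        fams = fam_sets[p.pul_id]
        shared = False
        for q in puls:
            if q.genome_id == p.genome_id or groups[q.genome_id] == own:
                continue
            if fams and len(fams & fam_sets[q.pul_id]) / len(fams) >= share_threshold:
                shared = True
                break
        if shared:
            out["shared"].append(p.pul_id)
        elif own == "degrader":
            out["unique_to_degraders"].append(p.pul_id)
        else:
            out["unique_to_nondegraders"].append(p.pul_id)
    return out


def activated_puls(
    fold_changes: dict[str, float], puls: list[PUL], threshold: float = 10.0
) -> dict:
    """Count genes activated more than ``threshold``-fold and the PULs they hit.

    The published rule is strict: a gene at exactly the threshold is not
    activated.  A PUL is activated when at least one member gene is.
    """
    if any(v < 0 for v in fold_changes.values()):
        raise ValueError("fold changes must be >= 0")
    activated_genes = {g for g, v in fold_changes.items() if v > threshold}
    activated_ids = sorted(
        p.pul_id for p in puls if any(g in activated_genes for g in p.gene_ids)
    )
    return {"n_activated_genes": len(activated_genes), "activated_pul_ids": activated_ids}


def orf_size_check(fam: GeneFamily, lengths: dict[tuple[str, str], int]) -> bool:
    """Flag families whose member ORF lengths vary by more than 50%.

    Flagged when the shortest member is strictly shorter than half the longest
    (a proxy for frameshifts or mis-joined assemblies worth manual review).
    """
    ls = [lengths[m] for m in fam.members]
    if len(ls) < 2:
        raise ValueError("ORF size check requires >= 2 members")
    return min(ls) < 0.5 * max(ls)
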