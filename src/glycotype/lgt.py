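"""Interspecies lateral gene transfer detection from a two-species pangenome.

The screen follows the cophylogenetic-distance logic used for the
B. ovatus / B. xylanisolvens core genome: identify gene families present as a
single copy in every genome of both species, align each family, build a
per-family gene tree, and for every genome compute the median patristic
distance from its allele to all other alleles within its own species and
within the opposite species.  An allele with median distance > 0.1
substitutions/site to its own species and < 0.1 to the opposite species
bears the signature of interspecies transfer (both inequalities strict).

Co-transferred accessory loci are then recovered by partitioning each genome
into inter-node intervals bounded by consecutive single-copy core genes and
retaining accessory families that are observed, pangenome-wide, only
adjacent to transfer-flagged core genes.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from skbio import DistanceMatrix
from skbio.tree import nj

from .pangenome import AnnotatedGenome, FamilyMatrix

__all__ = [
    "CoreGeneAlignment",
    "GeneTree",
    "LgtCall",
    "TransferLocus",
    "identify_single_copy_core",
    "align_core_family",
    "jc_distance_matrix",
    "build_gene_tree",
    "patristic_distances",
    "median_cophylo_distances",
    "classify_lgt",
    "scan_lgt",
    "extract_transfer_loci",
]


def identify_single_copy_core(fm: FamilyMatrix, species_map: dict[str, str]) -> list[str]:
    """Families with copy number exactly 1 in every genome of both species."""
    species = {species_map[g] for g in fm.genomes}
    if len(species) != 2:
        raise ValueError("expected genomes from exactly two species")
    counts = Counter(species_map[g] for g in fm.genomes)
    if min(counts.values()) < 2:
        raise ValueError("need at least 2 genomes per species")
    cn = fm.copy_number
    return sorted(cn.index[(cn == 1).all(axis=1)])


@dataclass
class CoreGeneAlignment:
    """One single-copy core family's alignment, one sequence per genome."""

    family_id: str
    sequences: dict[str, str]
    species_map: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.family_id}: unequal alignment lengths")
        species = {self.species_map[g] for g in self.sequences}
        if len(species) != 2:
            raise ValueError(f"{self.family_id}: both species must be represented")

    @property
    def genomes(self) -> list[str]:
        return sorted(self.sequences)


_dna_aligner = Align.PairwiseAligner(
    mode="global", match_score=1, mismatch_score=0, open_gap_score=-1, extend_gap_score=-1
)


def _kmer_distance(a: str, b: str, k: int = 5) -> float:
    ka = {a[i : i + k] for i in range(max(1, len(a) - k + 1))}
    kb = {b[i : i + k] for i in range(max(1, len(b) - k + 1))}
    union = ka | kb
    return 1.0 - len(ka & kb) / len(union) if union else 0.0


def _pair_blocks(center: str, other: str) -> tuple[list[str], list[str]]:
    """Align ``other`` against ``center``; return per-slot insertion blocks and
    the other-row characters matched to each center position.

    Slot i holds other-sequence characters aligned to gaps in the center row
    after i center characters have been consumed (slot 0 = before the first).
    """
    aln = _dna_aligner.align(center, other)[0]
    c_row, o_row = str(aln[0]), str(aln[1])
    blocks: list[str] = [""]
    chars: list[str] = []
    for cc, oc in zip(c_row, o_row):
        if cc == "-":
            blocks[-1] += oc
        else:
            chars.append(oc)
            blocks.append("")
    return blocks, chars


def align_core_family(
    seqs: dict[str, str],
    family_id: str = "core",
    species_map: dict[str, str] | None = None,
    prealigned: bool = False,
) -> CoreGeneAlignment:
    """Deterministic star-progressive alignment of one sequence per genome.

    The center sequence minimizes the total k-mer distance to the others;
    every other sequence is globally aligned to it and the pairwise
    alignments are merged under the once-a-gap-always-a-gap rule.  With
    ``prealigned=True`` the input is accepted verbatim (lengths must match).
    """
    if any(len(s) == 0 for s in seqs.values()):
        raise ValueError("zero-length sequence in core family")
    species_map = species_map or {g: "sp" for g in seqs}
    if prealigned or len({len(s) for s in seqs.values()}) == 1 and len(set(seqs.values())) == 1:
        return CoreGeneAlignment(family_id=family_id, sequences=dict(seqs), species_map=species_map)
    ids = sorted(seqs)
    totals = {
        g: sum(_kmer_distance(seqs[g], seqs[h]) for h in ids if h != g) for g in ids
    }
    center = min(ids, key=lambda g: (totals[g], g))
    others = [g for g in ids if g != center]
    pair = {g: _pair_blocks(seqs[center], seqs[g]) for g in others}
    n = len(seqs[center])
    widths = [
        max([len(pair[g][0][i]) for g in others] + [0]) for i in range(n + 1)
    ]
    aligned: dict[str, str] = {}
    center_row = ""
    for i, ch in enumerate(seqs[center]):
        center_row += "-" * widths[i] + ch
    center_row += "-" * widths[n]
    aligned[center] = center_row
    for g in others:
        blocks, chars = pair[g]
        row = ""
        for i in range(n):
            row += blocks[i].ljust(widths[i], "-") + chars[i]
        row += blocks[n].ljust(widths[n], "-")
        aligned[g] = row
    return CoreGeneAlignment(family_id=family_id, sequences=aligned, species_map=species_map)


def jc_distance_matrix(a: CoreGeneAlignment) -> pd.DataFrame:
    """Jukes-Cantor-corrected pairwise distances, gap columns excluded pairwise.

    Raises on saturated pairs (p-distance >= 0.75), which the correction
    cannot map to a finite distance.
    """
    ids = a.genomes
    arrs = {g: np.frombuffer(a.sequences[g].encode(), dtype="S1") for g in ids}
    gap = np.array([b"-"], dtype="S1")
    d = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, gi in enumerate(ids):
        for gj in ids[i + 1 :]:
            x, y = arrs[gi], arrs[gj]
            keep = (x != gap) & (y != gap)
            if keep.sum() == 0:
                raise ValueError(f"no comparable sites between {gi} and {gj}")
            p = float(np.mean(x[keep] != y[keep]))
            if p >= 0.75:
                raise ValueError(
                    f"saturated pair ({gi}, {gj}): p-distance {p:.3f} >= 0.75"
                )
            dist = -0.75 * math.log(1 - 4 * p / 3) if p > 0 else 0.0
            d.loc[gi, gj] = d.loc[gj, gi] = dist
    return d


@dataclass
class GeneTree:
    """Unrooted NJ tree over genomes with branch lengths in subs/site."""

    family_id: str
    tree: object  # skbio.TreeNode

    def patristic(self) -> pd.DataFrame:
        dm = self.tree.tip_tip_distances()
        return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def build_gene_tree(a: CoreGeneAlignment) -> GeneTree:
    """Neighbor joining on JC-corrected distances; negative branches clamped."""
    if len(a.sequences) < 4:
        raise ValueError("need >= 4 sequences for a gene tree")
    d = jc_distance_matrix(a)
    dm = DistanceMatrix(d.to_numpy(), ids=list(d.index))
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return GeneTree(family_id=a.family_id, tree=tree)


def patristic_distances(t: GeneTree) -> pd.DataFrame:
    return t.patristic()


def median_cophylo_distances(
    dist: pd.DataFrame | GeneTree, species_map: dict[str, str], genome_id: str
) -> tuple[float, float]:
    """Median distance from one genome's allele to each species' other alleles.

    ``dist`` is either a patristic-distance table from a gene tree or a
    corrected distance matrix used directly.  The focal genome is excluded
    from its own-species median.  Raises if the genome's species has no
    other member in the table.
    """
    if isinstance(dist, GeneTree):
        dist = dist.patristic()
    if genome_id not in dist.index:
        raise KeyError(f"{genome_id} not in distance table")
    own = species_map[genome_id]
    same = [g for g in dist.index if g != genome_id and species_map[g] == own]
    opp = [g for g in dist.index if species_map[g] != own]
    if not same:
        raise ValueError(f"{genome_id}: no other member of species {own}")
    if not opp:
        raise ValueError(f"{genome_id}: no opposite-species alleles")
    return (
        float(np.median([dist.loc[genome_id, g] for g in same])),
        float(np.median([dist.loc[genome_id, g] for g in opp])),
    )


@dataclass(frozen=True)
class LgtCall:
    genome_id: str
    family_id: str
    median_same: float
    median_opposite: float
    is_lgt: bool


def classify_lgt(
    genome_id: str,
    family_id: str,
    median_same: float,
    median_opposite: float,
    threshold: float = 0.1,
) -> LgtCall:
    """Apply the distance-threshold rule: transferred alleles sit farther than
    the threshold from their own species and closer than it to the other
    (both inequalities strict, so the boundary value is not a call)."""
    if median_same < 0 or median_opposite < 0:
        raise ValueError("median distances must be >= 0")
    return LgtCall(
        genome_id=genome_id,
        family_id=family_id,
        median_same=median_same,
        median_opposite=median_opposite,
        is_lgt=(median_same > threshold) and (median_opposite < threshold),
    )


def scan_lgt(
    genomes: list[AnnotatedGenome],
    gene_to_family: dict[tuple[str, str], str],
    core_families: list[str],
    species_map: dict[str, str],
    threshold: float = 0.1,
    distances: str = "tree",
    prealigned: bool = False,
) -> pd.DataFrame:
    """Run the full allele screen over the single-copy core families.

    For every core family: gather the one nucleotide sequence per genome,
    align (or accept pre-aligned input), derive distances either from an NJ
    gene tree (``distances='tree'``, patristic) or from the JC-corrected
    matrix directly (``distances='raw'``), and classify every genome's
    allele.  Returns a tidy table of calls.
    """
    if distances not in ("tree", "raw"):
        raise ValueError("distances must be 'tree' or 'raw'")
    by_genome = {g.genome_id: g for g in genomes}
    rows = []
    for fam in core_families:
        seqs: dict[str, str] = {}
        for gid, genome in by_genome.items():
            for gene in genome.genes:
                if gene_to_family.get((gid, gene.gene_id)) == fam:
                    if gene.dna is None:
                        raise ValueError(f"{gid}/{gene.gene_id}: missing nucleotide sequence")
                    seqs[gid] = gene.dna
        if set(seqs) != set(by_genome):
            warnings.warn(f"{fam}: not single-copy in all genomes, skipped")
            continue
        aln = align_core_family(seqs, family_id=fam, species_map=species_map, prealigned=prealigned)
        if distances == "tree":
            table = build_gene_tree(aln).patristic()
        else:
            table = jc_distance_matrix(aln)
        for gid in sorted(seqs):
            ms, mo = median_cophylo_distances(table, species_map, gid)
            call = classify_lgt(gid, fam, ms, mo, threshold)
            rows.append(call.__dict__)
    return pd.DataFrame(rows, columns=["genome_id", "family_id", "median_same", "median_opposite", "is_lgt"])


@dataclass
class TransferLocus:
    """A co-transfer locus: a run of transfer-flagged core-gene nodes plus the
    accessory families observed only adjacent to flagged nodes."""

    locus_id: str
    flanking_core_families: tuple[str | None, str | None]
    lgt_core_families: list[str]
    accessory_families: dict[str, list[str]] = field(default_factory=dict)  # fam -> genomes
    recipient_species: str = ""
    n_accessory_genes: int = 0


def _genome_intervals(
    genome: AnnotatedGenome,
    gene_to_family: dict[tuple[str, str], str],
    core: set[str],
) -> list[dict]:
    """Split a genome into inter-node intervals bounded by single-copy core
    genes; contig ends truncate intervals (bound None)."""
    intervals = []
    for contig, genes in genome.contigs().items():
        fams = [gene_to_family.get((genome.genome_id, g.gene_id)) for g in genes]
        node_pos = [i for i, f in enumerate(fams) if f in core]
        bounds = [None] + [fams[i] for i in node_pos] + [None]
        cuts = [-1] + node_pos + [len(genes)]
        for k in range(len(cuts) - 1):
            inside = [
                (genes[i].gene_id, fams[i]) for i in range(cuts[k] + 1, cuts[k + 1])
            ]
            intervals.append(
                {
                    "genome_id": genome.genome_id,
                    "contig": contig,
                    "left": bounds[k],
                    "right": bounds[k + 1],
                    "genes": inside,
                }
            )
    return intervals


def extract_transfer_loci(
    calls: pd.DataFrame,
    genomes: list[AnnotatedGenome],
    gene_to_family: dict[tuple[str, str], str],
    core_families: list[str],
    species_map: dict[str, str],
) -> list[TransferLocus]:
    """Recover co-transferred accessory loci around flagged core genes.

    Each genome is partitioned into inter-node intervals bounded by
    consecutive single-copy core genes.  An accessory family qualifies when
    every one of its occurrences, across all genomes, lies in an interval
    bounded by a core family flagged as transferred (in at least one
    genome).  Flagged core families adjacent in node order are merged into a
    single locus; a locus is reported when it carries at least one
    qualifying accessory family.
    """
    core = set(core_families)
    flagged = set(calls.loc[calls.is_lgt, "family_id"]) if len(calls) else set()
    if not flagged:
        return []
    flagged_by_genome = {
        g: set(grp.family_id) for g, grp in calls[calls.is_lgt].groupby("genome_id")
    }

    intervals = []
    for genome in genomes:
        intervals.extend(_genome_intervals(genome, gene_to_family, core))

    def interval_flank_flagged(iv) -> bool:
        return (iv["left"] in flagged) or (iv["right"] in flagged)

    # accessory families whose every occurrence flanks a flagged node family
    occurrences: dict[str, list[dict]] = {}
    for iv in intervals:
        for _, fam in iv["genes"]:
            if fam is not None and fam not in core:
                occurrences.setdefault(fam, []).append(iv)
    qualifying = {
        fam
        for fam, ivs in occurrences.items()
        if all(interval_flank_flagged(iv) for iv in ivs)
    }

    # node order from the genome with the most core genes on one contig
    ref_order: list[str] = []
    seen: set[str] = set()
    for genome in genomes:
        for contig, genes in genome.contigs().items():
            for g in genes:
                fam = gene_to_family.get((genome.genome_id, g.gene_id))
                if fam in core and fam not in seen:
                    ref_order.append(fam)
                    seen.add(fam)
    pos = {f: i for i, f in enumerate(ref_order)}

    runs: list[list[str]] = []
    for fam in sorted(flagged, key=lambda f: pos.get(f, -1)):
        if runs and pos.get(fam, -10) == pos.get(runs[-1][-1], -20) + 1:
            runs[-1].append(fam)
        else:
            runs.append([fam])

    loci = []
    for idx, run in enumerate(runs, start=1):
        run_set = set(run)
        acc: dict[str, set[str]] = {}
        n_acc_genes = 0
        recipients: set[str] = set()
        for gid, fams in flagged_by_genome.items():
            if fams & run_set:
                recipients.add(species_map[gid])
        for iv in intervals:
            if (iv["left"] in run_set) or (iv["right"] in run_set):
                for gene_id, fam in iv["genes"]:
                    if fam in qualifying:
                        acc.setdefault(fam, set()).add(iv["genome_id"])
                        if species_map[iv["genome_id"]] in recipients:
                            n_acc_genes += 1
        if not acc:
            continue
        lo, hi = pos.get(run[0]), pos.get(run[-1])
        flank_left = ref_order[lo - 1] if lo is not None and lo > 0 else None
        flank_right = (
            ref_order[hi + 1] if hi is not None and hi + 1 < len(ref_order) else None
        )
        loci.append(
            TransferLocus(
                locus_id=f"L{idx:03d}",
                flanking_core_families=(flank_left, flank_right),
                lgt_core_families=list(run),
                accessory_families={f: sorted(gs) for f, gs in sorted(acc.items())},
                recipient_species=",".join(sorted(recipients)),
                n_accessory_genes=n_acc_genes,
            )
        )
    return loci
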