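"""Core-gene screen: alignment, NJ trees, median distances, transfer loci."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from glycotype import simulate
from glycotype.lgt import (
    CoreGeneAlignment,
    align_core_family,
    build_gene_tree,
    classify_lgt,
    extract_transfer_loci,
    identify_single_copy_core,
    jc_distance_matrix,
    median_cophylo_distances,
    scan_lgt,
)
from glycotype.pangenome import AnnotatedGenome, FamilyMatrix, Gene

SPECIES = {"a": "s1", "b": "s1", "c": "s2", "d": "s2"}


class TestSingleCopyCore:
    def make_fm(self, rows):
        return FamilyMatrix(
            copy_number=pd.DataFrame(rows, index=["F1", "F2", "F3"], columns=list("abcd"))
        )

    def test_selection_rules(self):
        fm = self.make_fm(
            [[1, 1, 1, 1],  # single copy everywhere -> core
             [1, 1, 0, 1],  # missing from c -> excluded
             [1, 2, 1, 1]]  # duplicated in b -> excluded
        )
        assert identify_single_copy_core(fm, SPECIES) == ["F1"]

    def test_requires_two_genomes_per_species(self):
        fm = FamilyMatrix(
            copy_number=pd.DataFrame([[1, 1, 1]], index=["F1"], columns=["a", "b", "c"])
        )
        with pytest.raises(ValueError):
            identify_single_copy_core(fm, {"a": "s1", "b": "s1", "c": "s2"})


class TestAlignCoreFamily:
    def test_identical_sequences_gapless(self):
        seqs = {g: "ACGTACGTAC" for g in "abcd"}
        aln = align_core_family(seqs, species_map=SPECIES)
        assert all(s == "ACGTACGTAC" for s in aln.sequences.values())

    def test_single_indel_produces_one_gap_block(self):
        seqs = {"a": "ACGTACGTACGT", "b": "ACGTACGT", "c": "ACGTACGTACGT", "d": "ACGTACGTACGT"}
        aln = align_core_family(seqs, species_map=SPECIES)
        assert len(set(len(s) for s in aln.sequences.values())) == 1
        assert aln.sequences["b"].count("-") == 4
        gap_start = aln.sequences["b"].index("-")
        assert aln.sequences["b"][gap_start : gap_start + 4] == "----"

    def test_prealigned_bypass_is_identity(self):
        seqs = {"a": "AC-GT", "b": "ACGGT", "c": "AC-GT", "d": "ACTGT"}
        aln = align_core_family(seqs, species_map=SPECIES, prealigned=True)
        assert aln.sequences == seqs

    def test_zero_length_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_core_family({"a": "", "b": "ACGT", "c": "ACGT", "d": "ACGT"}, species_map=SPECIES)


def additive_alignment_free_tree():
    """Patristic distances of a known 4-taxon tree:
    ((a:1,b:2):1,(c:3,d:4)) scaled to substitutions/site."""
    s = 0.01
    d = pd.DataFrame(0.0, index=list("abcd"), columns=list("abcd"))
    d.loc["a", "b"] = d.loc["b", "a"] = 3 * s
    d.loc["a", "c"] = d.loc["c", "a"] = 5 * s
    d.loc["a", "d"] = d.loc["d", "a"] = 6 * s
    d.loc["b", "c"] = d.loc["c", "b"] = 6 * s
    d.loc["b", "d"] = d.loc["d", "b"] = 7 * s
    d.loc["c", "d"] = d.loc["d", "c"] = 7 * s
    return d


def tree_from_matrix(d):
    from skbio import DistanceMatrix
    from skbio.tree import nj

    return nj(DistanceMatrix(d.to_numpy(), ids=list(d.index)))


class TestGeneTree:
    def test_nj_recovers_additive_matrix_exactly(self):
        d = additive_alignment_free_tree()
        tree = tree_from_matrix(d)
        dm = tree.tip_tip_distances()
        got = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
        for x, y in itertools.combinations("abcd", 2):
            assert got.loc[x, y] == pytest.approx(d.loc[x, y], abs=1e-12)

    def test_patristic_matches_shortest_path_recomputation(self):
        tree = tree_from_matrix(additive_alignment_free_tree())
        g = nx.Graph()
        for i, node in enumerate(tree.traverse(include_self=True)):
            node._idx = i
        for node in tree.traverse(include_self=False):
            g.add_edge(node.parent._idx, node._idx, weight=node.length or 0.0)
        tips = {t.name: t._idx for t in tree.tips()}
        dm = tree.tip_tip_distances()
        got = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
        for x, y in itertools.combinations(tips, 2):
            sp = nx.shortest_path_length(g, tips[x], tips[y], weight="weight")
            assert got.loc[x, y] == pytest.approx(sp, abs=1e-12)

    def test_four_point_condition_on_additive_patristic(self):
        tree = tree_from_matrix(additive_alignment_free_tree())
        dm = tree.tip_tip_distances()
        d = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
        x, y, z, w = "abcd"
        sums = sorted(
            [d.loc[x, y] + d.loc[z, w], d.loc[x, z] + d.loc[y, w], d.loc[x, w] + d.loc[y, z]]
        )
        assert sums[1] == pytest.approx(sums[2], abs=1e-12)

    def test_identical_sequences_make_zero_cherry(self):
        base = "ACGT" * 25
        other = "GTAC" * 3 + base[12:]
        seqs = {"a": base, "b": base, "c": other, "d": other}
        aln = align_core_family(seqs, species_map=SPECIES, prealigned=True)
        tree = build_gene_tree(aln).tree
        got = tree.tip_tip_distances()
        table = pd.DataFrame(got.data, index=list(got.ids), columns=list(got.ids))
        assert table.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_star_distances_give_zero_internal_branch(self):
        d = pd.DataFrame(0.02, index=list("abcd"), columns=list("abcd"))
        np.fill_diagonal(d.values, 0.0)
        tree = tree_from_matrix(d)
        internal = [n.length for n in tree.traverse(include_self=False) if not n.is_tip()]
        assert all(abs(l) < 1e-12 for l in internal)

    def test_saturated_pair_raises(self):
        seqs = {"a": "A" * 100, "b": "A" * 100, "c": "C" * 100, "d": "C" * 100}
        aln = CoreGeneAlignment("f", seqs, SPECIES)
        with pytest.raises(ValueError, match="saturated"):
            jc_distance_matrix(aln)

    def test_requires_four_sequences(self):
        aln = CoreGeneAlignment(
            "f", {"a": "ACGT", "c": "ACGT"}, {"a": "s1", "c": "s2"}
        )
        with pytest.raises(ValueError):
            build_gene_tree(aln)


class TestMedianDistances:
    def test_median_of_two_conspecifics(self):
        d = pd.DataFrame(
            [[0.0, 0.02, 0.04, 0.3],
             [0.02, 0.0, 0.03, 0.3],
             [0.04, 0.03, 0.0, 0.3],
             [0.3, 0.3, 0.3, 0.0]],
            index=list("abcd"), columns=list("abcd"),
        )
        ms, mo = median_cophylo_distances(d, {"a": "s1", "b": "s1", "c": "s1", "d": "s2"}, "a")
        assert ms == pytest.approx(0.03)
        assert mo == pytest.approx(0.3)

    def test_identical_conspecifics_give_zero(self):
        d = pd.DataFrame(0.0, index=list("abcd"), columns=list("abcd"))
        d.loc[["a", "b"], ["c", "d"]] = 0.2
        d.loc[["c", "d"], ["a", "b"]] = 0.2
        ms, _ = median_cophylo_distances(d, SPECIES, "a")
        assert ms == 0.0

    def test_missing_conspecific_raises(self):
        d = pd.DataFrame(0.1, index=list("acd"), columns=list("acd"))
        with pytest.raises(ValueError, match="no other member"):
            median_cophylo_distances(d, {"a": "s1", "c": "s2", "d": "s2"}, "a")


class TestClassify:
    @pytest.mark.parametrize(
        "same,opp,expected",
        [(0.15, 0.05, True), (0.05, 0.20, False), (0.10, 0.10, False)],
    )
    def test_threshold_rule_is_strict(self, same, opp, expected):
        assert classify_lgt("g", "f", same, opp).is_lgt is expected

    def test_monotone_in_threshold(self):
        """Among thresholds above the opposite-species median, raising the
        threshold never converts a non-call into a call (the call window is
        the open interval (median_opposite, median_same))."""
        same, opp = 0.18, 0.07
        grid = [t for t in np.linspace(0.0, 0.5, 51) if t > opp]
        calls = [classify_lgt("g", "f", same, opp, t).is_lgt for t in grid]
        assert not any(not a and b for a, b in zip(calls, calls[1:]))


def toy_genome(gid, species, fams_labels):
    genes = []
    for k, fam in enumerate(fams_labels):
        genes.append(
            Gene(
                gene_id=f"{gid}_{k}", contig="c1", start=1 + 1000 * k, end=900 + 1000 * k,
                strand="+", protein="M" * 10, labels=frozenset({"other"}), dna="ACGT" * 25,
            )
        )
    return AnnotatedGenome(genome_id=gid, species_id=species, genes=genes)


class TestTransferLoci:
    def setup_case(self, extra_y_near_unflagged):
        # node order N1 N2 N3; accessory X between N2 and N3 in two genomes,
        # accessory Y between N1 and N2 in one genome
        layouts = {
            "a": ["N1", "N2", "X", "N3"],
            "b": ["N1", "Y", "N2", "N3"],
            "c": ["N1", "N2", "X", "N3"],
            "d": ["N1", "N2", "N3"],
        }
        if extra_y_near_unflagged:
            layouts["d"] = ["N1", "Y", "N2", "N3"]
        genomes = [toy_genome(g, SPECIES[g], layouts[g]) for g in "abcd"]
        g2f = {
            (g, f"{g}_{k}"): fam
            for g, fams in layouts.items()
            for k, fam in enumerate(fams)
        }
        calls = pd.DataFrame(
            [
                {"genome_id": "a", "family_id": "N3", "median_same": 0.2,
                 "median_opposite": 0.02, "is_lgt": True},
                {"genome_id": "b", "family_id": "N2", "median_same": 0.2,
                 "median_opposite": 0.02, "is_lgt": True},
            ]
        )
        return calls, genomes, g2f

    def test_accessory_only_next_to_flagged_nodes_is_reported(self):
        calls, genomes, g2f = self.setup_case(extra_y_near_unflagged=False)
        loci = extract_transfer_loci(calls, genomes, g2f, ["N1", "N2", "N3"], SPECIES)
        (locus,) = loci  # N2 and N3 are adjacent nodes -> one merged locus
        assert set(locus.lgt_core_families) == {"N2", "N3"}
        assert "X" in locus.accessory_families
        assert sorted(locus.accessory_families["X"]) == ["a", "c"]

    def test_accessory_also_near_unflagged_core_is_excluded(self):
        calls, genomes, g2f = self.setup_case(extra_y_near_unflagged=False)
        loci = extract_transfer_loci(calls, genomes, g2f, ["N1", "N2", "N3"], SPECIES)
        fams = set().union(set(), *(l.accessory_families for l in loci))
        assert "Y" in fams  # every Y occurrence flanks the flagged N2
        # drop the N2 flag: Y now sits only between unflagged N1 and N2
        calls2 = calls[calls.family_id != "N2"]
        loci2 = extract_transfer_loci(calls2, genomes, g2f, ["N1", "N2", "N3"], SPECIES)
        fams2 = set().union(set(), *(l.accessory_families for l in loci2))
        assert "Y" not in fams2 and "X" in fams2

    def test_no_flags_no_loci(self):
        calls, genomes, g2f = self.setup_case(False)
        empty = calls[calls.family_id == "nope"]
        assert extract_transfer_loci(empty, genomes, g2f, ["N1", "N2", "N3"], SPECIES) == []


class TestEndToEnd:
    def test_transfer_recovery_on_default_pangenome(self, default_pangenome):
        """Precision and recall >= 0.9 for transferred-allele detection on the
        default two-species pangenome, and every locus at an injected site."""
        spec, genomes, families, truth = default_pangenome
        calls = scan_lgt(
            genomes,
            families["gene_to_family"],
            families["core_families"],
            families["species_map"],
            prealigned=True,
        )
        pred = set(map(tuple, calls.loc[calls.is_lgt, ["genome_id", "family_id"]].values))
        true = truth["transferred_alleles"]
        tp = len(pred & true)
        assert tp / max(len(pred), 1) >= 0.9
        assert tp / len(true) >= 0.9
        loci = extract_transfer_loci(
            calls, genomes, families["gene_to_family"], families["core_families"],
            families["species_map"],
        )
        event_nodes = [set(e["nodes"]) for e in truth["events"]]
        assert len(loci) >= 9
        for locus in loci:
            assert any(set(locus.lgt_core_families) & nodes for nodes in event_nodes)

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_zero_transfers_zero_calls(self, seed):
        spec = simulate.PangenomeSpec(n_core=100, n_transfers=0, seed=seed)
        genomes, families, _ = simulate.simulate_pangenome_pair(spec)
        calls = scan_lgt(
            genomes,
            families["gene_to_family"],
            families["core_families"],
            families["species_map"],
            prealigned=True,
        )
        assert int(calls.is_lgt.sum()) == 0
        assert (
            extract_transfer_loci(
                calls, genomes, families["gene_to_family"], families["core_families"],
                families["species_map"],
            )
            == []
        )
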