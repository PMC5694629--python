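import math

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

import oracles
from cyanotax.signatures import SignatureMatrices
from cyanotax.taxonomy import (Thresholds, Verdict, aai_linkage,
                               check_monophyly, classify_pair, delimit_genera,
                               delimit_species, reassignment_report)

NAN = float("nan")


def make_matrices(ids, aai, ggd=None, s16=None):
    """Build SignatureMatrices from {frozenset(pair): value} dicts."""
    def mat(pairs, default=NAN):
        m = pd.DataFrame(np.nan, index=ids, columns=ids)
        np.fill_diagonal(m.values, 100.0)
        for (a, b) in [(a, b) for i, a in enumerate(ids)
                       for b in ids[i + 1:]]:
            value = (pairs or {}).get(frozenset((a, b)), default)
            m.loc[a, b] = m.loc[b, a] = value
        return m

    return SignatureMatrices(list(ids), mat(aai, default=40.0),
                             mat(ggd, default=NAN), mat(s16, default=NAN))


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


_VERDICT_RANK = {Verdict.distinct: 0, Verdict.same_genus: 1,
                 Verdict.same_species: 2}


class TestClassifyPair:
    @pytest.mark.parametrize("aai, ggd, s16, expected", [
        (96.0, 75.0, 99.0, Verdict.same_species),
        (95.0, 70.0, 98.8, Verdict.same_species),  # inclusive bounds
        (80.0, 20.0, 97.0, Verdict.same_genus),
        (94.9, 75.0, 99.0, Verdict.same_genus),
        (96.0, 69.9, 99.0, Verdict.same_genus),
        (96.0, 75.0, 98.7, Verdict.same_genus),
        (69.9, 10.0, 90.0, Verdict.distinct),
    ])
    def test_thresholds(self, aai, ggd, s16, expected):
        assert classify_pair(aai, ggd, s16).verdict is expected

    def test_missing_ggd_blocks_species(self):
        verdict = classify_pair(97.0, NAN, 99.5)
        assert verdict.verdict is Verdict.same_genus
        assert "ggd" in verdict.missing

    def test_missing_s16_tolerated(self):
        verdict = classify_pair(97.0, 80.0, NAN)
        assert verdict.verdict is Verdict.same_species
        assert "s16" in verdict.missing

    def test_species_implies_genus_evidence(self):
        verdict = classify_pair(96.0, 75.0, 99.0)
        assert verdict.evidence["aai_species"]
        assert verdict.evidence["aai_genus"]

    @settings(max_examples=200, derandomize=True)
    @given(aai=st.floats(0, 100), ggd=st.floats(0, 100),
           s16=st.floats(0, 100), bump=st.floats(0, 30),
           which=st.sampled_from(["aai", "ggd", "s16"]))
    def test_monotone_in_each_signature(self, aai, ggd, s16, bump, which):
        base = classify_pair(aai, ggd, s16).verdict
        bumped = {"aai": aai, "ggd": ggd, "s16": s16}
        bumped[which] = min(bumped[which] + bump, 100.0)
        raised = classify_pair(bumped["aai"], bumped["ggd"],
                               bumped["s16"]).verdict
        assert _VERDICT_RANK[raised] >= _VERDICT_RANK[base]


class TestDelimitSpecies:
    def test_full_triangle_single_cluster(self):
        mats = make_matrices(["A", "B", "C"],
                             aai={frozenset(p): 97.0 for p in
                                  [("A", "B"), ("B", "C"), ("A", "C")]},
                             ggd={frozenset(p): 80.0 for p in
                                  [("A", "B"), ("B", "C"), ("A", "C")]})
        species, warnings = delimit_species(mats)
        assert len(set(species.values())) == 1
        assert warnings == []

    def test_chain_kept_whole_with_warning(self):
        aai = {frozenset(("A", "B")): 97.0, frozenset(("B", "C")): 97.0,
               frozenset(("A", "C")): 90.0}
        ggd = {frozenset(("A", "B")): 80.0, frozenset(("B", "C")): 80.0,
               frozenset(("A", "C")): 75.0}
        species, warnings = delimit_species(make_matrices(["A", "B", "C"],
                                                          aai, ggd))
        assert len(set(species.values())) == 1
        assert warnings == [("A", "B", "C")]

    def test_no_qualifying_pairs_all_singletons(self):
        ids = list("ABCDE")
        species, warnings = delimit_species(
            make_matrices(ids, aai={}, ggd={}))
        assert len(set(species.values())) == 5
        assert warnings == []

    def test_input_order_invariance(self):
        aai = {frozenset(("A", "B")): 97.0}
        ggd = {frozenset(("A", "B")): 80.0}
        fwd, _ = delimit_species(make_matrices(["A", "B", "C"], aai, ggd))
        rev, _ = delimit_species(make_matrices(["C", "B", "A"], aai, ggd))
        fwd_sets = {frozenset(g for g in fwd if fwd[g] == c)
                    for c in set(fwd.values())}
        rev_sets = {frozenset(g for g in rev if rev[g] == c)
                    for c in set(rev.values())}
        assert fwd_sets == rev_sets


class TestMonophyly:
    def test_clade_is_monophyletic(self):
        assert check_monophyly(_tree("((A,B),C);"), {"A", "B"})

    def test_paraphyletic_set(self):
        assert not check_monophyly(_tree("((A,B),C);"), {"A", "C"})

    def test_full_leaf_set(self):
        assert check_monophyly(_tree("((A,B),C);"), {"A", "B", "C"})

    def test_unknown_leaf_errors(self):
        with pytest.raises(ValueError, match="unknown leaf"):
            check_monophyly(_tree("((A,B),C);"), {"A", "Z"})


class TestDelimitGenera:
    def test_aai_components_matching_clades(self):
        mats = make_matrices(["A", "B", "C"],
                             aai={frozenset(("A", "B")): 80.0})
        partition = delimit_genera(mats, _tree("((A,B),C);"))
        assert partition.genus_of["A"] == partition.genus_of["B"]
        assert partition.genus_of["C"] != partition.genus_of["A"]
        assert partition.monophyly_splits == []

    def test_non_monophyletic_component_split(self):
        mats = make_matrices(["A", "B", "C"],
                             aai={frozenset(("A", "C")): 80.0})
        partition = delimit_genera(mats, _tree("((A,B),C);"))
        assert partition.genus_of["A"] != partition.genus_of["C"]
        assert len(partition.monophyly_splits) == 1

    def test_species_cluster_never_divided(self):
        # A+B same species; AAI joins all three; tree separates A from B
        aai = {frozenset(p): 80.0 for p in
               [("A", "B"), ("B", "C"), ("A", "C")]}
        aai[frozenset(("A", "B"))] = 97.0
        ggd = {frozenset(("A", "B")): 85.0}
        mats = make_matrices(["A", "B", "C"], aai, ggd)
        partition = delimit_genera(mats, _tree("((A,C),(B,D));"))
        assert partition.species_of["A"] == partition.species_of["B"]
        assert partition.genus_of["A"] == partition.genus_of["B"]
        partition.validate()

    def test_genome_absent_from_tree_flagged(self):
        mats = make_matrices(["A", "B", "Z"],
                             aai={frozenset(("A", "B")): 80.0,
                                  frozenset(("A", "Z")): 80.0,
                                  frozenset(("B", "Z")): 80.0})
        partition = delimit_genera(mats, _tree("((A,B),C);"))
        assert "not_in_tree" in partition.flags["Z"]

    def test_species_refines_genus(self, clade_scene, clade_matrices):
        tree = _tree(clade_scene.newick)
        partition = delimit_genera(clade_matrices, tree)
        partition.validate()

    def test_planted_partition_recovered(self, clade_scene, clade_matrices):
        tree = _tree(clade_scene.newick)
        partition = delimit_genera(clade_matrices, tree)
        ids = sorted(partition.species_of)
        truth = clade_scene.truth
        assert adjusted_rand_score(
            [truth.species_of[g] for g in ids],
            [partition.species_of[g] for g in ids]) == 1.0
        assert adjusted_rand_score(
            [truth.genus_of[g] for g in ids],
            [partition.genus_of[g] for g in ids]) == 1.0


class TestAaiLinkage:
    def test_identical_rows_merge_first(self):
        aai = {frozenset(("A", "B")): 90.0, frozenset(("A", "C")): 50.0,
               frozenset(("B", "C")): 50.0}
        mats = make_matrices(["A", "B", "C"], aai)
        # A and B rows are permutation-identical only in their mutual entries;
        # make them exactly equal by symmetry of the construction
        dendro = aai_linkage(mats)
        merges = dendro.merge_order()
        assert merges[0] == (frozenset({"A"}), frozenset({"B"}))

    def test_merge_order_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(21)
        ids = [f"g{i}" for i in range(6)]
        aai = {}
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                aai[frozenset((a, b))] = float(rng.uniform(40, 99))
        mats = make_matrices(ids, aai)
        dendro = aai_linkage(mats)
        dist = squareform([(abs(mats.aai.loc[a] - mats.aai.loc[b])).sum()
                           for i, a in enumerate(ids) for b in ids[i + 1:]])
        assert dendro.merge_order() == oracles.complete_linkage_merges(
            dist, ids)

    def test_relabeling_invariance(self):
        aai = {frozenset(("A", "B")): 90.0, frozenset(("A", "C")): 50.0,
               frozenset(("B", "C")): 60.0}
        mats = make_matrices(["A", "B", "C"], aai)
        renamed = make_matrices(["X", "Y", "Z"],
                                {frozenset(("X", "Y")): 90.0,
                                 frozenset(("X", "Z")): 50.0,
                                 frozenset(("Y", "Z")): 60.0})
        z1 = aai_linkage(mats).linkage_matrix
        z2 = aai_linkage(renamed).linkage_matrix
        assert np.allclose(z1, z2)

    def test_newick_export(self):
        aai = {frozenset(("A", "B")): 90.0, frozenset(("A", "C")): 50.0,
               frozenset(("B", "C")): 60.0}
        newick = aai_linkage(make_matrices(["A", "B", "C"], aai)).to_newick()
        tree = _tree(newick)
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == \
            {"A", "B", "C"}


class TestReassignment:
    def _partition(self):
        mats = make_matrices(
            ["A", "B", "C", "D"],
            aai={frozenset(("A", "B")): 97.0, frozenset(("C", "D")): 80.0},
            ggd={frozenset(("A", "B")): 85.0})
        return delimit_genera(mats)

    def test_matching_labels_no_reassignment(self):
        partition = self._partition()
        labels = pd.DataFrame({
            "genus": ["Anabaena", "Anabaena", "Lyngbya", "Lyngbya"],
            "species": ["cylindrica", "cylindrica", "limosa", "confervoides"],
        }, index=pd.Index(["A", "B", "C", "D"], name="genome_id"))
        report = reassignment_report(labels, partition)
        assert report.n_reassigned == 0
        assert report.n_genera == 2
        assert report.n_species == 3

    def test_genus_label_spanning_clusters_counted(self):
        partition = self._partition()
        labels = pd.DataFrame({
            "genus": ["Anabaena", "Anabaena", "Anabaena", "Lyngbya"],
            "species": ["cylindrica", "cylindrica", "limosa", "confervoides"],
        }, index=pd.Index(["A", "B", "C", "D"], name="genome_id"))
        report = reassignment_report(labels, partition)
        frame = report.per_genome
        assert frame.loc["C", "needs_genus_reassignment"]
        assert not frame.loc["D", "needs_genus_reassignment"]

    def test_all_unclassified_counted(self):
        partition = self._partition()
        labels = pd.DataFrame({
            "genus": ["sp."] * 4, "species": [""] * 4,
        }, index=pd.Index(["A", "B", "C", "D"], name="genome_id"))
        report = reassignment_report(labels, partition)
        assert report.n_reassigned == 4
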