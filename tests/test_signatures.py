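import math

import numpy as np
import pytest

import oracles
from cyanotax.io import Alphabet, SequenceRecord, SequenceSet
from cyanotax.signatures import (AAIUndefinedError, MarkerAlignmentSet,
                                 align_protein_pair, compute_aai, compute_ggd,
                                 concatenate_markers, find_rbh_pairs,
                                 sixteen_s_identity, tajima_nei_distance)
from cyanotax.synthetic import (evolve_sequences, random_sequence,
                                realized_identity)

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _prot(rec_id, residues):
    return SequenceRecord(rec_id, residues, Alphabet.protein)


def _nuc(rec_id, residues):
    return SequenceRecord(rec_id, residues, Alphabet.nucleotide)


def _random_protein(rng, length, rec_id="p"):
    return _prot(rec_id, "".join(rng.choice(list(_AA), size=length)))


def _substituted(residues, positions, rng):
    out = list(residues)
    for i in positions:
        out[i] = rng.choice([c for c in _AA if c != out[i]])
    return "".join(out)


class TestProteinAlignment:
    def test_identical_sequences(self):
        rng = np.random.default_rng(0)
        rec = _random_protein(rng, 100)
        aln = align_protein_pair(rec, rec)
        assert aln.identity_percent == 100.0
        assert aln.coverage_a == aln.coverage_b == 1.0

    def test_no_positive_segment(self):
        # BLOSUM62 scores W-P and W-G negative at every column
        aln = align_protein_pair(_prot("a", "WWWWWW"), _prot("b", "PPPPPP"))
        assert aln is None

    def test_fixed_pair_matches_dp_oracle(self):
        rng = np.random.default_rng(42)
        a = _random_protein(rng, 50, "a")
        # 5 internal substitutions, no gaps: identity 90 over the full length
        b = _prot("b", _substituted(a.residues, [7, 15, 23, 31, 44], rng))
        aln = align_protein_pair(a, b)
        score, ga, gb = oracles.gotoh_local(a.residues, b.residues)
        assert aln.score == pytest.approx(score)
        assert aln.identity_percent == pytest.approx(
            oracles.identity_percent(ga, gb))
        assert aln.identity_percent == pytest.approx(90.0)


class TestRBH:
    def test_self_pairing(self):
        rng = np.random.default_rng(1)
        proteome = SequenceSet(_random_protein(rng, 80, f"p{i}")
                               for i in range(5))
        pairs = find_rbh_pairs(proteome, proteome)
        assert {(p.id_a, p.id_b) for p in pairs} == \
            {(f"p{i}", f"p{i}") for i in range(5)}
        assert all(p.identity_percent == 100.0 for p in pairs)

    def test_no_homology_empty(self):
        a = SequenceSet([_prot("x", "WWWWWWWWWW")])
        b = SequenceSet([_prot("y", "PPPPPPPPPP")])
        assert find_rbh_pairs(a, b) == []

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        base = [_random_protein(rng, 60, f"a{i}") for i in range(5)]
        proteome_a = SequenceSet(base)
        evolved = []
        for i, rec in enumerate(base):
            mutated = _substituted(rec.residues,
                                   rng.choice(60, size=6, replace=False), rng)
            evolved.append(_prot(f"b{i}", mutated))
        # planted paralog: near-copy of a0 competing with b0
        paralog = _substituted(base[0].residues,
                               rng.choice(60, size=9, replace=False), rng)
        evolved.append(_prot("b9_paralog", paralog))
        proteome_b = SequenceSet(evolved)
        pairs = {(p.id_a, p.id_b)
                 for p in find_rbh_pairs(proteome_a, proteome_b)}
        assert pairs == oracles.brute_force_rbh(proteome_a, proteome_b)


class TestAAI:
    def test_self_comparison_is_100(self):
        rng = np.random.default_rng(2)
        proteome = SequenceSet(_random_protein(rng, 90, f"p{i}")
                               for i in range(4))
        assert compute_aai(proteome, proteome) == pytest.approx(100.0)

    def test_mean_of_pair_identities(self):
        rng = np.random.default_rng(3)
        p1 = _random_protein(rng, 100, "p1")
        p2 = _random_protein(rng, 50, "p2")
        # p1 kept identical (100%), p2 mutated at 10/50 sites (80%)
        mutated = _substituted(p2.residues,
                               rng.choice(50, size=10, replace=False), rng)
        a = SequenceSet([p1, p2])
        b = SequenceSet([p1, _prot("p2", mutated)])
        assert compute_aai(a, b) == pytest.approx(90.0)

    def test_undefined_when_no_pairs(self):
        a = SequenceSet([_prot("x", "WWWWWWWWWW")])
        b = SequenceSet([_prot("y", "PPPPPPPPPP")])
        with pytest.raises(AAIUndefinedError, match="AAI undefined"):
            compute_aai(a, b)

    def test_planted_identity_recovered(self):
        rng = np.random.default_rng(4)
        ancestor = SequenceSet(_random_protein(rng, 150, f"p{i:02d}")
                               for i in range(12))
        evolved, _ = evolve_sequences(ancestor, 90.0, seed=5)
        planted = realized_identity(ancestor, evolved)
        assert compute_aai(ancestor, evolved) == pytest.approx(planted,
                                                               abs=1.5)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(6)
        records = [_random_protein(rng, 80, f"p{i}") for i in range(6)]
        evolved, _ = evolve_sequences(SequenceSet(records), 85.0, seed=6)
        shuffled = SequenceSet([records[i] for i in [3, 0, 5, 1, 4, 2]])
        assert compute_aai(SequenceSet(records), evolved) == \
            pytest.approx(compute_aai(shuffled, evolved))

    def test_monotone_in_planted_divergence(self):
        bands = [95.0, 90.0, 80.0, 70.0]
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            ancestor = SequenceSet(_random_protein(rng, 120, f"p{i}")
                                   for i in range(10))
            values = [compute_aai(ancestor,
                                  evolve_sequences(ancestor, b, seed=seed)[0])
                      for b in bands]
            assert values == sorted(values, reverse=True)


class TestGGD:
    def test_self_comparison_is_100(self):
        rng = np.random.default_rng(8)
        genome = SequenceSet([random_sequence(5000, Alphabet.nucleotide, rng,
                                              "chr")])
        res = compute_ggd(genome, genome)
        assert res.percent == pytest.approx(100.0)
        assert res.has_homology

    def test_duplicated_genome_vs_self_is_100(self):
        rng = np.random.default_rng(9)
        chrom = random_sequence(4000, Alphabet.nucleotide, rng, "chr")
        genome = SequenceSet([chrom])
        doubled = SequenceSet([chrom,
                               _nuc("chr_copy", chrom.residues)])
        assert compute_ggd(doubled, genome).percent == pytest.approx(100.0)

    def test_planted_substitution_rate(self):
        rng = np.random.default_rng(10)
        genome = SequenceSet([random_sequence(30000, Alphabet.nucleotide,
                                              rng, "chr")])
        evolved, _ = evolve_sequences(genome, 95.0, seed=10)
        assert compute_ggd(genome, evolved).percent == pytest.approx(95.0,
                                                                     abs=0.5)

    def test_unrelated_genomes_below_species_bound(self):
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            a = SequenceSet([random_sequence(20000, Alphabet.nucleotide, rng,
                                             "a")])
            b = SequenceSet([random_sequence(20000, Alphabet.nucleotide, rng,
                                             "b")])
            assert compute_ggd(a, b).percent < 70.0


class TestSixteenS:
    def test_identical(self):
        rng = np.random.default_rng(11)
        rec = random_sequence(1200, Alphabet.nucleotide, rng, "16S")
        assert sixteen_s_identity(rec, rec) == pytest.approx(100.0)

    def test_twelve_differences_in_1kb(self):
        rng = np.random.default_rng(12)
        a = random_sequence(1000, Alphabet.nucleotide, rng, "a")
        sites = rng.choice(np.arange(20, 980), size=12, replace=False)
        out = list(a.residues)
        for i in sites:
            out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
        b = _nuc("b", "".join(out))
        assert sixteen_s_identity(a, b) == pytest.approx(98.8)

    def test_internal_deletion_matches_dp_oracle(self):
        rng = np.random.default_rng(13)
        a = random_sequence(1000, Alphabet.nucleotide, rng, "a")
        b = _nuc("b", a.residues[:500] + a.residues[510:])
        _, ga, gb = oracles.gotoh_endsfree(a.residues, b.residues)
        assert sixteen_s_identity(a, b) == pytest.approx(
            oracles.identity_percent(ga, gb))

    def test_fragment_too_short(self):
        rng = np.random.default_rng(14)
        short = random_sequence(300, Alphabet.nucleotide, rng, "frag")
        full = random_sequence(1200, Alphabet.nucleotide, rng, "full")
        with pytest.raises(ValueError, match="fragment too short"):
            sixteen_s_identity(short, full)


class TestTajimaNei:
    def test_identical_pair_zero(self):
        rng = np.random.default_rng(15)
        rec = random_sequence(500, Alphabet.nucleotide, rng, "a")
        aln = SequenceSet([rec, _nuc("b", rec.residues)])
        mat = tajima_nei_distance(aln)
        assert mat.loc["a", "b"] == 0.0

    def test_three_differences_matches_formula_oracle(self):
        rng = np.random.default_rng(16)
        a = random_sequence(100, Alphabet.nucleotide, rng, "a")
        out = list(a.residues)
        for i in (10, 50, 90):
            out[i] = {"A": "G", "G": "A", "C": "T", "T": "C"}[out[i]]
        b = "".join(out)
        mat = tajima_nei_distance(SequenceSet([a, _nuc("b", b)]))
        assert mat.loc["a", "b"] == pytest.approx(
            oracles.tajima_nei(a.residues, b))

    def test_symmetric_and_gap_exclusion(self):
        aln = SequenceSet([_nuc("a", "ACGTAC-TAC"),
                           _nuc("b", "ACGTACGTAC"),
                           _nuc("c", "ACGAACGTTC")])
        mat = tajima_nei_distance(aln)
        assert (mat.values == mat.values.T).all()
        assert mat.loc["a", "b"] == 0.0  # only the gap column differs


class TestMarkerConcatenation:
    def _markers(self):
        genes = {
            "rpsA": SequenceSet([_prot("g1", "MKVLAWQTYP"),
                                 _prot("g2", "MKVLAWQSYP"),
                                 _prot("g3", "MKVLAWESYP")]),
            "rplB": SequenceSet([_prot("g1", "ACDEFGHIKLMNPQRSTVWY"),
                                 _prot("g2", "ACDEFGHIKLMNPQRSTVWF")]),
        }
        return MarkerAlignmentSet(genes)

    def test_genome_missing_a_marker_is_excluded(self):
        result = concatenate_markers(self._markers())
        assert result.excluded == ["g3"]
        assert set(result.alignment.ids) == {"g1", "g2"}

    def test_width_is_sum_of_gene_widths(self):
        result = concatenate_markers(self._markers())
        assert len(result.alignment["g1"].residues) == 30
        assert result.coordinates == {"rpsA": (0, 10), "rplB": (10, 30)}

    def test_single_gene_identity(self):
        genes = {"rpsA": SequenceSet([_prot("g1", "MKVLAW"),
                                      _prot("g2", "MKVLAY")])}
        result = concatenate_markers(MarkerAlignmentSet(genes))
        assert result.alignment["g2"].residues == "MKVLAY"

    def test_empty_intersection_errors(self):
        genes = {"a": SequenceSet([_prot("g1", "MK")]),
                 "b": SequenceSet([_prot("g2", "MK")])}
        with pytest.raises(ValueError, match="complete marker set"):
            concatenate_markers(MarkerAlignmentSet(genes))


class TestSignatureMatrices:
    def test_symmetry_and_diagonal(self, clade_matrices):
        clade_matrices.validate(tol=0.1)
        for mat in (clade_matrices.aai, clade_matrices.ggd,
                    clade_matrices.s16):
            assert np.allclose(np.diag(mat.to_numpy()), 100.0)

    def test_planted_band_structure(self, clade_scene, clade_matrices):
        truth = clade_scene.truth
        ids = clade_matrices.genome_ids
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                aai = clade_matrices.aai.loc[a, b]
                if truth.species_of[a] == truth.species_of[b]:
                    assert aai >= 95.0
                elif truth.genus_of[a] == truth.genus_of[b]:
                    assert 70.0 <= aai < 95.0
                else:
                    assert aai < 70.0
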