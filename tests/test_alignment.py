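"""Alignment data model: I/O, reweighting, clustering, splits, profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepfunnel.alignment import (
    Alignment,
    AlignmentShapeError,
    cluster_representatives,
    profile_matrix,
    read_alignment,
    sequence_weights,
    train_validation_split,
    write_alignment,
)
from pepfunnel.alphabet import ALPHABET, Q, AlphabetError


def aln_from(seqs, ids=None):
    ids = ids or [f"s{k}" for k in range(len(seqs))]
    return Alignment(ids=ids, sequences=seqs)


class TestIO:
    def test_fasta_roundtrip_with_annotations(self, tmp_path):
        aln = read_alignment(">a|gene=NFATc2|organism=Homo sapiens\nPRIEIT\n>b\nPVIVIT\n")
        assert aln.ids == ["a", "b"]
        assert aln.n_columns == 6
        assert aln.annotation("gene")[0] == "NFATc2"
        path = tmp_path / "out.fasta"
        write_alignment(aln, path)
        again = read_alignment(path)
        assert again.sequences == aln.sequences
        assert again.annotation("organism")[0] == "Homo sapiens"

    def test_ragged_lengths_rejected(self):
        with pytest.raises(AlignmentShapeError):
            aln_from(["ACDE", "ACD"])

    def test_illegal_symbol_rejected(self):
        with pytest.raises(AlphabetError):
            aln_from(["ACBE", "ACDE"])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(AlignmentShapeError):
            aln_from(["ACDE", "ACDE"], ids=["x", "x"])


class TestSequenceWeights:
    def test_identical_records_share_weight(self):
        w = sequence_weights(aln_from(["ACDE", "ACDE", "ACDE"]))
        assert np.allclose(w, 1 / 3)

    def test_distant_records_keep_unit_weight(self):
        w = sequence_weights(aln_from(["AAAAA", "CDEFG"]))
        assert np.allclose(w, 1.0)

    def test_mixed_neighbourhoods(self):
        # pair at Hamming distance 1 plus two isolated records
        w = sequence_weights(aln_from(["AAAA", "AAAC", "WWWW", "YYYY"]))
        assert np.allclose(w, [0.5, 0.5, 1.0, 1.0])

    def test_gap_counts_as_symbol(self):
        # one substitution to gap = distance 1
        w = sequence_weights(aln_from(["AC-E", "ACDE"]))
        assert np.allclose(w, 0.5)

    @settings(max_examples=25, deadline=None)
    @given(st.permutations(list(range(5))))
    def test_permutation_invariance(self, perm):
        seqs = ["AAAA", "AAAC", "AACC", "WWWW", "WWWY"]
        base = sequence_weights(aln_from(seqs))
        shuffled = sequence_weights(aln_from([seqs[i] for i in perm]))
        assert np.allclose(shuffled, base[perm])

    def test_duplicating_a_record_shrinks_its_weight(self):
        seqs = ["AAAA", "WWWW"]
        w1 = sequence_weights(aln_from(seqs))
        w2 = sequence_weights(aln_from(seqs + ["AAAA"]))
        assert np.isclose(w1[0], 1.0) and np.isclose(w2[0], 0.5)


class TestClustering:
    def test_identical_records_one_representative(self):
        aln = aln_from(["ACDE"] * 4)
        reps = cluster_representatives(aln, 2, scores=[0.1, 0.9, 0.3, 0.2])
        assert reps == ["s1"]

    def test_two_separated_groups(self):
        # groups mutually >= 3 apart, cut at 2
        aln = aln_from(["AAAAA", "AAAAC", "WWWWW", "WWWWY"])
        reps = cluster_representatives(aln, 2, scores=[1, 2, 4, 3])
        assert reps == ["s1", "s2"]

    def test_representative_maximizes_score_within_cluster(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list(ALPHABET[:20]), 6)) for _ in range(12)]
        aln = aln_from(seqs)
        scores = rng.random(12)
        reps = cluster_representatives(aln, 3, scores)
        from pepfunnel.alignment import cluster_labels

        labels = cluster_labels(aln, 3)
        for rep in reps:
            k = aln.ids.index(rep)
            members = np.flatnonzero(labels == labels[k])
            assert scores[k] == scores[members].max()

    def test_score_tie_breaks_to_smallest_id(self):
        aln = aln_from(["ACDE", "ACDE"], ids=["b", "a"])
        assert cluster_representatives(aln, 2, scores=[1.0, 1.0]) == ["a"]

    def test_negative_cut_rejected(self):
        with pytest.raises(ValueError):
            cluster_representatives(aln_from(["ACDE"]), -1, scores=[1.0])


class TestTrainValidationSplit:
    def _aln(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        # singleton-ish clusters: random sequences of length 12
        return aln_from(["".join(rng.choice(list(ALPHABET[:20]), 12)) for _ in range(n)])

    def test_min_cross_distance_exceeds_cut(self):
        aln = self._aln()
        train, val = train_validation_split(aln, cut_distance=2, seed=1)
        tcodes = aln.subset(train).codes()
        vcodes = aln.subset(val).codes()
        cross = (tcodes[:, None, :] != vcodes[None, :, :]).sum(axis=2)
        assert cross.min() >= 3

    def test_cluster_count_arithmetic(self):
        aln = self._aln(10)
        train, val = train_validation_split(aln, cut_distance=0, val_fraction=0.2, seed=0)
        assert len(val) == 2 and len(train) == 8

    def test_deterministic_given_seed(self):
        aln = self._aln()
        assert train_validation_split(aln, seed=7) == train_validation_split(aln, seed=7)

    def test_single_cluster_is_infeasible(self):
        aln = aln_from(["ACDE", "ACDF", "ACDG"])
        with pytest.raises(ValueError, match="single cluster"):
            train_validation_split(aln, cut_distance=5)


class TestProfileMatrix:
    def test_single_sequence_delta(self):
        profile = profile_matrix(aln_from(["AAAA"]), pseudocount=0.0)
        assert np.allclose(profile[:, 0], 1.0)

    def test_large_pseudocount_limit_uniform(self):
        profile = profile_matrix(aln_from(["AAAA"]), pseudocount=1e9)
        assert np.allclose(profile, 1 / Q, atol=1e-6)

    def test_even_split_column(self):
        profile = profile_matrix(aln_from(["AADE", "ACDE"]), pseudocount=0.0)
        a, c = ALPHABET.index("A"), ALPHABET.index("C")
        assert profile[1, a] == pytest.approx(0.5)
        assert profile[1, c] == pytest.approx(0.5)

    @pytest.mark.parametrize("pc", [0.0, 0.3, 5.0])
    def test_rows_sum_to_one(self, pc):
        rng = np.random.default_rng(3)
        aln = aln_from(["".join(rng.choice(list(ALPHABET), 8)) for _ in range(20)])
        profile = profile_matrix(aln, weights=rng.random(20) + 0.1, pseudocount=pc)
        assert np.allclose(profile.sum(axis=1), 1.0, atol=1e-12)
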