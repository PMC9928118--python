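"""Interolog-consistency (mirror-tree) filtering of homolog triplets."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, pearsonr

from pepfunnel.interolog import (
    DegenerateCorrelationError,
    Triplet,
    TripletSet,
    extract_fragments,
    filter_triplets,
    pairwise_identity,
    select_species_copies,
    similarity_tensor,
    triplet_consistency,
)
from pepfunnel.synthetic import make_triplets


def _trip(tid, org, cna, cnb, sp, cna_id="c1", cnb_id="b1"):
    return Triplet(tid, org, cna, cnb, sp, cna_id=cna_id, cnb_id=cnb_id)


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACDE", "ACDE") == 1.0

    def test_double_gap_column_excluded(self):
        assert pairwise_identity("AC-D", "AG-D") == pytest.approx(2 / 3)

    def test_gap_vs_residue_is_mismatch(self):
        assert pairwise_identity("A-DE", "ACDE") == pytest.approx(3 / 4)

    def test_symmetry(self):
        assert pairwise_identity("ACDE", "AGDW") == pairwise_identity("AGDW", "ACDE")

    def test_empty_overlap_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            pairwise_identity("--", "--")


class TestConsistency:
    def _seeds(self):
        return [
            _trip("seed0", "o0", "AAAA", "CCCC", "DDDD"),
            _trip("seed1", "o1", "AAAC", "CCCA", "DDDA"),
            _trip("seed2", "o2", "AACC", "CCAA", "DDAA"),
            _trip("seed3", "o3", "ACCC", "CAAA", "DAAA"),
        ]

    def test_similarity_tensor_shape_and_symmetric_seed_block(self):
        ts = TripletSet("SP", self._seeds(), [])
        sim = similarity_tensor(ts)
        assert sim.shape == (4, 4, 3)
        for k in range(3):
            assert np.allclose(sim[:4, :, k], sim[:4, :, k].T)

    def test_perfectly_mirrored_candidate_scores_one(self):
        # all three similarity profiles affine transforms of each other
        ts = TripletSet("SP", self._seeds(), [_trip("cand", "oc", "AAAA", "CCCC", "DDDD")])
        sim = np.zeros((5, 4, 3))
        base = np.array([0.9, 0.7, 0.5, 0.3])
        for l in range(5):
            profile = np.roll(base, l % 4)
            for k, (a, b) in enumerate([(1.0, 0.0), (0.5, 0.2), (2.0, -0.1)]):
                sim[l, :, k] = a * profile + b
        scores = triplet_consistency(ts, sim)
        assert scores.r_mean[-1] == pytest.approx(1.0)

    def test_anticorrelated_component_gives_minus_third(self):
        ts = TripletSet("SP", self._seeds(), [_trip("cand", "oc", "AAAA", "CCCC", "DDDD")])
        sim = np.zeros((5, 4, 3))
        rng = np.random.default_rng(0)
        sim[:4] = rng.uniform(0.2, 0.9, size=(4, 4, 3))
        up = np.array([0.2, 0.4, 0.6, 0.8])
        sim[4, :, 0] = up
        sim[4, :, 1] = up
        sim[4, :, 2] = up[::-1]
        scores = triplet_consistency(ts, sim)
        assert scores.r_mean[-1] == pytest.approx((1 - 1 - 1) / 3)

    def test_seed_order_relabeling_leaves_r_invariant(self):
        ts, _ = make_triplets(n_seeds=5, n_true=3, n_decoys=0, seed=3)
        r1 = triplet_consistency(ts).r_mean[-3:]
        shuffled = TripletSet(ts.substrate_id, ts.seeds[::-1], ts.candidates, ts.slim_start)
        r2 = triplet_consistency(shuffled).r_mean[-3:]
        assert np.allclose(r1, r2)

    def test_constant_profile_raises_degenerate(self):
        ts = TripletSet("SP", self._seeds(), [_trip("cand", "oc", "AAAA", "CCCC", "DDDD")])
        sim = np.full((5, 4, 3), 0.5)
        with pytest.raises(DegenerateCorrelationError):
            triplet_consistency(ts, sim)


class TestCopySelectionAndFilter:
    def test_single_copy_passthrough(self):
        ts, _ = make_triplets(n_seeds=5, n_true=4, n_decoys=0, seed=1)
        scores = triplet_consistency(ts)
        kept = select_species_copies(ts, scores)
        assert [t.triplet_id for t in kept.candidates] == [
            t.triplet_id for t in ts.candidates
        ]

    def test_better_copy_retained(self):
        ts, _ = make_triplets(n_seeds=5, n_true=2, n_decoys=0, seed=2)
        good = ts.candidates[0]
        # a second, scrambled CnA copy in the same organism
        bad = Triplet(
            "cand_bad", good.organism, good.cna[::-1], good.cnb, good.sp,
            cna_id=good.cna_id.replace("cna1", "cna2"), cnb_id=good.cnb_id,
        )
        ts2 = TripletSet(ts.substrate_id, ts.seeds, [good, bad, ts.candidates[1]])
        scores = triplet_consistency(ts2)
        kept = select_species_copies(ts2, scores)
        kept_ids = [t.triplet_id for t in kept.candidates]
        assert good.triplet_id in kept_ids and "cand_bad" not in kept_ids

    def test_all_seeds_survive_their_own_filter(self):
        ts, _ = make_triplets(n_seeds=6, n_true=10, n_decoys=10, seed=0)
        kept, scores = filter_triplets(ts)
        assert len(kept.seeds) == 6
        threshold = scores.r_mean[:6].min()
        assert all(scores.r_mean[6:][scores.kept[6:]] >= threshold)

    def test_kept_set_is_monotone_in_score(self):
        ts, _ = make_triplets(n_seeds=6, n_true=10, n_decoys=10, seed=4)
        kept, scores = filter_triplets(ts)
        kept_r = scores.r_mean[6:][scores.kept[6:]]
        dropped_r = scores.r_mean[6:][~scores.kept[6:]]
        if kept_r.size and dropped_r.size:
            assert kept_r.min() > dropped_r.max()

    def test_filter_is_idempotent(self):
        ts, _ = make_triplets(n_seeds=6, n_true=15, n_decoys=15, seed=5)
        once, _ = filter_triplets(ts)
        twice, _ = filter_triplets(once)
        assert [t.triplet_id for t in twice.candidates] == [
            t.triplet_id for t in once.candidates
        ]

    def test_decoys_score_below_true_interologs(self):
        ts, labels = make_triplets(n_seeds=8, n_true=25, n_decoys=25, seed=0)
        scores = triplet_consistency(ts)
        r = scores.r_mean[8:]
        mask = labels["is_true"].to_numpy()
        assert r[mask].mean() > r[~mask].mean()
        p = mannwhitneyu(r[mask], r[~mask], alternative="greater").pvalue
        assert p < 0.01


class TestExtractFragments:
    def _ts(self, slim_start, seqs):
        seeds = [
            _trip(f"t{k}", f"o{k}", "AAAA", "CCCC", "DDDD") for k in range(len(seqs))
        ]
        ts = TripletSet("SP", seeds, [], slim_start=slim_start)
        return ts, {f"t{k}": s for k, s in enumerate(seqs)}

    def test_window_arithmetic(self):
        row = "".join("ACDEFGHIKLMNPQRSTVWY" [k % 20] for k in range(40))
        ts, alnmap = self._ts(11, [row])
        ids, frags = extract_fragments(ts, alnmap)
        assert frags == [row[0:27]]

    def test_insertion_lengthens_fragment(self):
        # the second row is gapped where the first carries an insertion, so
        # the first fragment keeps the extra residues and comes out longer
        with_insert = "AAAAACWCAAAAAAAA"
        gapped = "AAAAA--CAAAAAAAA"
        ts, alnmap = self._ts(6, [with_insert, gapped])
        ids, frags = extract_fragments(ts, alnmap, window_left=2, window_right=4)
        assert frags[0] == "AACWCAA"
        assert frags[1] == "AACAA"
        assert len(frags[0]) > len(frags[1])

    def test_fully_gapped_window_dropped(self):
        ts, alnmap = self._ts(3, ["--------"])
        with pytest.warns(UserWarning, match="fully gapped"):
            ids, frags = extract_fragments(ts, alnmap, window_left=2, window_right=2)
        assert frags == []

    def test_out_of_bounds_window_clipped(self):
        ts, alnmap = self._ts(2, ["ACDEFGHI"])
        with pytest.warns(UserWarning, match="clipped"):
            ids, frags = extract_fragments(ts, alnmap, window_left=5, window_right=3)
        assert frags == ["ACDEF"]
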