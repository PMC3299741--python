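import numpy as np
import pytest

from structmsa import default_weights, make_family
from structmsa.consistency import PosteriorStore, transform
from structmsa.distance import distance_matrix, optimal_alignment
from structmsa.guidetree import SequenceWeights, sequence_weights, upgma
from structmsa.pipeline import align, compute_pair_posteriors
from structmsa.progressive import (Profile, align_profiles, iterative_refine,
                                   profile_posterior, progressive_align)
from structmsa.seqio import GAP, MultipleAlignment


@pytest.fixture
def toy_store(rng):
    store = PosteriorStore(3)
    store.set(0, 1, rng.random((4, 4)) * 0.3)
    store.set(0, 2, rng.random((4, 5)) * 0.3)
    store.set(1, 2, rng.random((4, 5)) * 0.3)
    return store


class TestProfilePosterior:
    def test_singleton_profiles_return_pair_matrix(self, toy_store):
        A = Profile(ids=("a",), rows=("ACDE",))
        B = Profile(ids=("b",), rows=("ACDE",))
        w = SequenceWeights(weights={"a": 1.0, "b": 1.0, "c": 1.0})
        M = profile_posterior(A, B, toy_store, w, {"a": 0, "b": 1, "c": 2})
        np.testing.assert_allclose(M, toy_store.get(0, 1), atol=1e-15)

    def test_mean_of_equal_terms_is_unchanged(self, rng):
        store = PosteriorStore(3)
        P = rng.random((4, 4)) * 0.5
        store.set(0, 2, P)
        store.set(1, 2, P)
        store.set(0, 1, np.eye(4))
        A = Profile(ids=("a", "b"), rows=("ACDE", "ACDE"))
        B = Profile(ids=("c",), rows=("ACDE",))
        w = SequenceWeights(weights={"a": 1.0, "b": 1.0, "c": 1.0})
        M = profile_posterior(A, B, store, w, {"a": 0, "b": 1, "c": 2})
        np.testing.assert_allclose(M, P, atol=1e-15)

    def test_weighted_mean_hand_computed(self):
        store = PosteriorStore(3)
        P02 = np.full((2, 2), 0.4)
        P12 = np.full((2, 2), 0.8)
        store.set(0, 2, P02)
        store.set(1, 2, P12)
        store.set(0, 1, np.eye(2))
        A = Profile(ids=("a", "b"), rows=("AC", "AC"))
        B = Profile(ids=("c",), rows=("AC",))
        w = SequenceWeights(weights={"a": 3.0, "b": 1.0, "c": 2.0})
        M = profile_posterior(A, B, store, w, {"a": 0, "b": 1, "c": 2})
        # (3*2*0.4 + 1*2*0.8) / (3*2 + 1*2)
        np.testing.assert_allclose(M, (6 * 0.4 + 2 * 0.8) / 8, atol=1e-15)

    def test_gap_occupants_contribute_zero(self):
        store = PosteriorStore(2)
        store.set(0, 1, np.ones((2, 2)))
        A = Profile(ids=("a",), rows=("A-C",))
        B = Profile(ids=("b",), rows=("AC",))
        w = SequenceWeights(weights={"a": 1.0, "b": 1.0})
        M = profile_posterior(A, B, store, w, {"a": 0, "b": 1})
        assert np.all(M[1, :] == 0)
        assert np.all(M[[0, 2], :] == 1)

    def test_overlapping_profiles_rejected(self, toy_store):
        A = Profile(ids=("a",), rows=("ACDE",))
        w = SequenceWeights(weights={"a": 1.0})
        with pytest.raises(ValueError):
            profile_posterior(A, A, toy_store, w, {"a": 0})


class TestAlignProfiles:
    def test_identity_matrix_merges_column_to_column(self):
        A = Profile(ids=("a",), rows=("ACD",))
        B = Profile(ids=("b",), rows=("ACD",))
        merged = align_profiles(A, B, np.eye(3))
        assert merged.rows == ("ACD", "ACD")

    def test_offset_merge_inserts_gaps(self):
        A = Profile(ids=("a",), rows=("AC",))
        B = Profile(ids=("b",), rows=("C",))
        M = np.array([[0.0], [0.9]])
        merged = align_profiles(A, B, M)
        assert merged.rows == ("AC", "-C")

    def test_degapping_preserved(self, rng):
        A = Profile(ids=("a", "b"), rows=("AC-E", "-CDE"))
        B = Profile(ids=("c",), rows=("ACD",))
        merged = align_profiles(A, B, rng.random((4, 3)))
        assert merged.rows[0].replace(GAP, "") == "ACE"
        assert merged.rows[1].replace(GAP, "") == "CDE"
        assert merged.rows[2].replace(GAP, "") == "ACD"


class TestProgressive:
    def _pipeline_pieces(self, seqs, cfg, gonnet):
        store = compute_pair_posteriors(seqs, cfg, gonnet)
        D = distance_matrix(seqs, store, cfg)
        tree = upgma(D, [s.id for s in seqs])
        w = sequence_weights(tree)
        wvec = np.array([w.weights[s.id] for s in seqs])
        transformed = transform(store, wvec, rounds=cfg.transform_rounds,
                                sparsity_cutoff=0.0)
        return store, tree, w, transformed

    def test_identical_sequences_gapless(self, gonnet):
        cfg = default_weights()
        seqs, _, _ = make_family(3, 30, 0.0, 0.0, seed=5)
        _, tree, w, transformed = self._pipeline_pieces(seqs, cfg, gonnet)
        aln = progressive_align(tree, transformed, w, seqs)
        assert GAP not in "".join(aln.rows)
        assert len(set(aln.rows)) == 1

    def test_two_sequence_case_equals_pairwise_dp(self, gonnet):
        """With two sequences the progressive merge must reproduce the
        optimal pairwise alignment of the transformed posterior."""
        cfg = default_weights()
        seqs, _, _ = make_family(2, 40, 0.3, 0.05, seed=11)
        _, tree, w, transformed = self._pipeline_pieces(seqs, cfg, gonnet)
        aln = progressive_align(tree, transformed, w, seqs)
        pa, _ = optimal_alignment(transformed.get(0, 1))
        matched = []
        i = j = 0
        for a, b in zip(aln.rows[0], aln.rows[1]):
            if a != GAP and b != GAP:
                matched.append((i, j))
            i += a != GAP
            j += b != GAP
        assert tuple(matched) == pa.pairs

    def test_row_order_follows_input(self, gonnet):
        cfg = default_weights()
        seqs, _, _ = make_family(4, 25, 0.2, 0.05, seed=13)
        _, tree, w, transformed = self._pipeline_pieces(seqs, cfg, gonnet)
        aln = progressive_align(tree, transformed, w, seqs)
        assert list(aln.ids) == [s.id for s in seqs]


class TestRefinement:
    def test_zero_iterations_is_identity(self, gonnet):
        cfg = default_weights()
        seqs, _, _ = make_family(3, 25, 0.2, 0.05, seed=17)
        res = align(seqs, cfg)
        out = iterative_refine(res.alignment, res.transformed, res.weights,
                               0, seed=1, seqs=seqs)
        assert out is res.alignment

    def test_same_seed_reproducible(self, gonnet):
        cfg = default_weights()
        seqs, _, _ = make_family(4, 25, 0.25, 0.05, seed=19)
        res = align(seqs, cfg)
        a = iterative_refine(res.alignment, res.transformed, res.weights,
                             5, seed=42, seqs=seqs)
        b = iterative_refine(res.alignment, res.transformed, res.weights,
                             5, seed=42, seqs=seqs)
        assert a.rows == b.rows

    def test_degap_invariant_after_many_iterations(self, gonnet):
        cfg = default_weights()
        seqs, _, _ = make_family(5, 30, 0.3, 0.08, seed=23)
        res = align(seqs, cfg)
        out = iterative_refine(res.alignment, res.transformed, res.weights,
                               10, seed=3, seqs=seqs)
        for s, row in zip(seqs, out.rows):
            assert row.replace(GAP, "") == s.residues
        # no all-gap columns survive
        MultipleAlignment(out.ids, out.rows)
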