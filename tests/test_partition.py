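import math

import numpy as np
import pytest

from structmsa import similarity_scores
from structmsa.matrices import default_weights
from structmsa.partition import (AnnotationError, combine_posteriors,
                                 pair_score_matrix, partition_forward,
                                 partition_posterior)
from structmsa.seqio import AnnotatedSequence

from conftest import random_seq
from oracles import enumerate_partition


def oracle_scores(X, Y, cfg, S):
    """Score matrix built entry-by-entry from the public scoring triple —
    an independent route to the vectorized construction."""
    out = np.zeros((len(X), len(Y)))
    for i in range(len(X)):
        for j in range(len(Y)):
            s, ss, sa = similarity_scores(
                X.residues[i], Y.residues[j],
                X.ss[i] if X.ss else None, Y.ss[j] if Y.ss else None,
                X.sa[i] if X.sa else None, Y.sa[j] if Y.sa else None, S=S)
            out[i, j] = cfg.w1 * cfg.beta * s + cfg.w2 * ss + cfg.w3 * sa
    return out


class TestScoreMatrix:
    def test_matches_per_entry_construction(self, rng, gonnet, cfg):
        X = random_seq(rng, 4, name="x", with_ann=True)
        Y = random_seq(rng, 4, name="y", with_ann=True)
        np.testing.assert_allclose(pair_score_matrix(X, Y, cfg, gonnet),
                                   oracle_scores(X, Y, cfg, gonnet), atol=1e-12)

    def test_missing_annotation_with_structural_weight_errors(self, gonnet, cfg):
        X = AnnotatedSequence(id="x", residues="AC")
        Y = AnnotatedSequence(id="y", residues="AC")
        with pytest.raises(AnnotationError):
            pair_score_matrix(X, Y, cfg, gonnet)

    def test_ss_concordance_exponent_ratio(self, gonnet, cfg):
        """Identical vs different SS changes the match weight by e^{w2}."""
        same = AnnotatedSequence(id="a", residues="A", ss="H", sa="e")
        diff = AnnotatedSequence(id="b", residues="A", ss="E", sa="e")
        cfg2 = cfg.with_overrides(w1=0.5, w2=0.5, w3=0.0)
        lat_same = partition_forward(same, same, cfg2, gonnet)
        lat_diff = partition_forward(same, diff, cfg2, gonnet)
        ratio = math.exp(lat_same.FM[1, 1] - lat_diff.FM[1, 1])
        assert ratio == pytest.approx(math.exp(0.5 * (1 - 0)), rel=1e-12)


class TestForwardLattice:
    def test_single_pair_explicit_alignments(self, gonnet):
        """For 1-residue sequences the recursion grammar admits exactly one
        global alignment (the match): the double-gap renderings place a gap
        in one sequence directly against a gap in the other, which the
        gap-state transitions exclude."""
        cfg = default_weights().with_overrides(w1=1.0, w2=0.0, w3=0.0)
        X = AnnotatedSequence(id="x", residues="A")
        Y = AnnotatedSequence(id="y", residues="C")
        lat = partition_forward(X, Y, cfg, gonnet)
        s = cfg.w1 * cfg.beta * gonnet.score("A", "C")
        assert math.exp(lat.F[1, 1]) == pytest.approx(math.exp(s), rel=1e-12)

    def test_two_by_one_explicit_alignments(self, gonnet):
        """2x1: match-first and match-last paths each carry one gap-open."""
        cfg = default_weights().with_overrides(w1=1.0, w2=0.0, w3=0.0)
        X = AnnotatedSequence(id="x", residues="AC")
        Y = AnnotatedSequence(id="y", residues="D")
        lat = partition_forward(X, Y, cfg, gonnet)
        g = cfg.beta * cfg.gap_open
        b = cfg.w1 * cfg.beta
        expected = (math.exp(b * gonnet.score("A", "D") + g)
                    + math.exp(b * gonnet.score("C", "D") + g))
        assert math.exp(lat.F[2, 1]) == pytest.approx(expected, rel=1e-12)

    def test_cellwise_sum_invariant(self, rng, gonnet, cfg):
        X = random_seq(rng, 4, name="x", with_ann=True)
        Y = random_seq(rng, 4, name="y", with_ann=True)
        lat = partition_forward(X, Y, cfg, gonnet)
        stack = np.stack([lat.FM, lat.FX, lat.FY])
        from scipy.special import logsumexp

        np.testing.assert_allclose(logsumexp(stack, axis=0), lat.F, atol=1e-9)

    def test_partition_value_matches_enumeration(self, rng, gonnet, cfg):
        for _ in range(20):
            X = random_seq(rng, 4, name="x", with_ann=True)
            Y = random_seq(rng, 4, name="y", with_ann=True)
            score = pair_score_matrix(X, Y, cfg, gonnet)
            total, _ = enumerate_partition(score, cfg.beta * cfg.gap_open,
                                           cfg.beta * cfg.gap_ext)
            lat = partition_forward(X, Y, cfg, gonnet)
            assert math.exp(lat.F[len(X), len(Y)]) == pytest.approx(
                total, rel=1e-9)


class TestPosterior:
    def test_matches_enumeration(self, rng, gonnet, cfg):
        for _ in range(20):
            X = random_seq(rng, 4, name="x", with_ann=True)
            Y = random_seq(rng, 4, name="y", with_ann=True)
            score = pair_score_matrix(X, Y, cfg, gonnet)
            _, oracle = enumerate_partition(score, cfg.beta * cfg.gap_open,
                                            cfg.beta * cfg.gap_ext)
            post = partition_posterior(X, Y, cfg, gonnet)
            np.testing.assert_allclose(post, oracle, atol=1e-9)

    def test_structural_inputs_ignored_when_weights_zero(self, rng, gonnet):
        cfg0 = default_weights().with_overrides(w1=1.0, w2=0.0, w3=0.0)
        X = random_seq(rng, 4, name="x", with_ann=True)
        Y = random_seq(rng, 4, name="y", with_ann=True)
        X2 = AnnotatedSequence(id="x", residues=X.residues,
                               ss="C" * len(X), sa="b" * len(X))
        a = partition_posterior(X, Y, cfg0, gonnet)
        b = partition_posterior(X2, Y, cfg0, gonnet)
        np.testing.assert_array_equal(a, b)

    def test_self_pair_symmetric(self, gonnet, cfg):
        X = AnnotatedSequence(id="x", residues="ACDE", ss="HHEE", sa="ebeb")
        post = partition_posterior(X, X, cfg, gonnet)
        np.testing.assert_allclose(post, post.T, atol=1e-12)

    def test_ss_weight_promotes_concordant_pairs(self, gonnet):
        """Raising w2 must not let SS-discordant pairs overtake concordant
        ones: the concordant/discordant posterior ratio is monotone."""
        X = AnnotatedSequence(id="x", residues="AA", ss="HE", sa="ee")
        Y = AnnotatedSequence(id="y", residues="AA", ss="HE", sa="ee")
        ratios = []
        for w2 in (0.0, 0.25, 0.5):
            cfg = default_weights().with_overrides(w1=1.0 - w2, w2=w2, w3=0.0)
            p = partition_posterior(X, Y, cfg, gonnet)
            ratios.append(p[0, 0] / max(p[0, 1], 1e-300))
        assert ratios[0] <= ratios[1] <= ratios[2]


class TestCombine:
    def test_equal_inputs_fixed_point(self, rng):
        p = rng.random((3, 4))
        np.testing.assert_allclose(combine_posteriors(p, p), p, atol=1e-12)

    def test_endpoints(self):
        z = np.zeros((2, 2))
        o = np.ones((2, 2))
        assert np.all(combine_posteriors(z, z) == 0)
        np.testing.assert_allclose(combine_posteriors(o, o), 1.0)

    def test_rms_value(self):
        p1 = np.array([[0.6]])
        p2 = np.array([[0.8]])
        assert combine_posteriors(p1, p2)[0, 0] == pytest.approx(
            0.7071067811865476, abs=1e-12)

    def test_bounded_by_inputs(self, rng):
        p1 = rng.random((5, 5))
        p2 = rng.random((5, 5))
        c = combine_posteriors(p1, p2)
        assert np.all(c >= np.minimum(p1, p2) - 1e-12)
        assert np.all(c <= np.maximum(p1, p2) + 1e-12)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            combine_posteriors(np.zeros((2, 2)), np.zeros((2, 3)))
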