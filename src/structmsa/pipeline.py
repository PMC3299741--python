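"""End-to-end alignment pipeline.

Five stages: (1) all-pairs posterior matrices from the structure-aware
partition function fused with sequence-only pair-HMM posteriors; (2) a
pairwise distance matrix combining posterior alignment scores with
contact-map similarity; (3) a UPGMA guide tree and tree-derived sequence
weights; (4) the weighted consistency transformation of all posteriors;
(5) progressive profile-profile alignment along the tree followed by
randomized iterative refinement.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import pairhmm
from .consistency import PosteriorStore, transform
from .distance import distance_matrix
from .guidetree import GuideTree, SequenceWeights, sequence_weights, upgma
from .matrices import SubstitutionMatrix, WeightConfig, default_weights, \
    validate_weights
from .partition import combine_posteriors, partition_posterior
from .progressive import iterative_refine, progressive_align
from .seqio import MultipleAlignment

log = logging.getLogger("structmsa")


@dataclass(frozen=True)
class PipelineResult:
    """Final alignment plus the intermediates, for inspection and testing."""

    alignment: MultipleAlignment
    posteriors: PosteriorStore
    transformed: PosteriorStore
    distances: np.ndarray
    tree: GuideTree
    weights: SequenceWeights


def compute_pair_posteriors(seqs, cfg: WeightConfig,
                            S: SubstitutionMatrix,
                            hmm_params=None) -> PosteriorStore:
    """Fused posterior matrices for every unordered sequence pair."""
    if hmm_params is None:
        hmm_params = pairhmm.default_params()
    store = PosteriorStore(len(seqs))
    for k in range(len(seqs)):
        for l in range(k + 1, len(seqs)):
            p1 = partition_posterior(seqs[k], seqs[l], cfg, S)
            p2 = pairhmm.hmm_posterior(seqs[k], seqs[l], hmm_params)
            store.set(k, l, combine_posteriors(p1, p2))
    return store


def align(seqs, cfg: Optional[WeightConfig] = None,
          S: Optional[SubstitutionMatrix] = None,
          hmm_params=None) -> PipelineResult:
    """Run the full pipeline on a list of AnnotatedSequence."""
    if cfg is None:
        cfg = default_weights()
    validate_weights(cfg)
    if S is None:
        S = SubstitutionMatrix.gonnet()
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("sequence ids must be unique")
    if len(seqs) == 1:
        aln = MultipleAlignment(ids, [seqs[0].residues])
        empty = PosteriorStore(1)
        return PipelineResult(aln, empty, empty, np.zeros((1, 1)),
                              None, SequenceWeights(weights={ids[0]: 1.0}))

    t0 = time.perf_counter()
    store = compute_pair_posteriors(seqs, cfg, S, hmm_params)
    t1 = time.perf_counter()
    log.info("posterior matrices: %.2fs", t1 - t0)

    D = distance_matrix(seqs, store, cfg)
    tree = upgma(D, ids)
    w = sequence_weights(tree)
    t2 = time.perf_counter()
    log.info("distances + guide tree: %.2fs", t2 - t1)

    wvec = np.array([w.weights[i] for i in ids])
    transformed = transform(store, wvec, rounds=cfg.transform_rounds,
                            sparsity_cutoff=cfg.sparsity_cutoff)
    t3 = time.perf_counter()
    log.info("consistency transform: %.2fs", t3 - t2)

    aln = progressive_align(tree, transformed, w, seqs)
    aln = iterative_refine(aln, transformed, w, cfg.refine_iters, cfg.seed,
                           seqs=seqs)
    log.info("progressive + refinement: %.2fs", time.perf_counter() - t3)
    return PipelineResult(alignment=aln, posteriors=store,
                          transformed=transformed, distances=D, tree=tree,
                          weights=w)
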