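"""Sequence-vs-ecology similarity analyses and the monophyly test.

Three questions, matching the framework's motivating observations:

* do sequence-similar pairs share more ecological annotations (Jaccard
  index binned against pairwise sequence similarity, averaged over
  random subsamples)?
* is the internal sequence similarity of an ecologically coherent group
  higher than a background sample (one-sided Mann-Whitney-U)?
* are non-singleton OTUs monophyletic on a reference tree (unrooted
  bipartition test — an OTU passes iff its leaf set is exactly one side
  of some edge-induced bipartition)?
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.stats import mannwhitneyu

from .distance import _row_vs_block, encode
from .errors import DataError, UndefinedDistanceError
from .io_formats import AlignedSeqSet, Partition, PhyloTree
from .signals import FeatureAssignment

logger = logging.getLogger(__name__)


def jaccard(A: frozenset | set, B: frozenset | set) -> float:
    """|A∩B| / |A∪B|; undefined (error) when both sets are empty."""
    if not A and not B:
        raise UndefinedDistanceError("Jaccard undefined for two empty sets")
    A, B = set(A), set(B)
    return len(A & B) / len(A | B)


@dataclass
class SimilarityCurve:
    """Binned mean ecological similarity as a function of sequence similarity."""

    bin_edges: np.ndarray           # length B+1 over [0, 1]
    mean_ecological: np.ndarray     # length B, NaN where a bin is empty
    sd_ecological: np.ndarray       # between-subset sd, length B
    pair_counts: np.ndarray         # total pairs per bin, length B

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "mean_jaccard": self.mean_ecological,
                "sd_jaccard": self.sd_ecological,
                "pairs": self.pair_counts,
            }
        )


def _pairwise_jaccard(feature_sets: list[frozenset]) -> np.ndarray:
    """Condensed Jaccard similarities via sparse intersection counts."""
    feats = sorted({f for s in feature_sets for f in s})
    index = {f: j for j, f in enumerate(feats)}
    rows, cols = [], []
    for i, s in enumerate(feature_sets):
        for f in s:
            rows.append(i)
            cols.append(index[f])
    n = len(feature_sets)
    X = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, len(feats))
    )
    inter = (X @ X.T).toarray()
    sizes = np.asarray(X.sum(axis=1)).ravel()
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore"):
        J = np.where(union > 0, inter / union, np.nan)
    iu = np.triu_indices(n, k=1)
    return J[iu]


def _pairwise_similarity(enc: np.ndarray, mode: str) -> np.ndarray:
    """Condensed pairwise similarities (1 - distance) of encoded rows."""
    n = enc.shape[0]
    out = np.empty(n * (n - 1) // 2, dtype=np.float64)
    pos = 0
    for i in range(n - 1):
        d = _row_vs_block(enc[i], enc[i + 1:], mode)
        out[pos: pos + d.size] = 1.0 - d
        pos += d.size
    return out


def similarity_vs_ecology(
    seqs: AlignedSeqSet,
    fa: FeatureAssignment,
    n_subsets: int = 20,
    subset_size: int = 10_000,
    bins: int = 20,
    mode: str = "onegap",
    seed: int | None = None,
) -> SimilarityCurve:
    """Jaccard ecological similarity binned by pairwise sequence similarity.

    ``n_subsets`` random subsamples of ``subset_size`` annotated
    sequences each; all within-subset pairs contribute; per-bin means are
    averaged over subsets and the between-subset standard deviation is
    reported.  Sampling is over sorted ids, so input order is irrelevant.
    """
    annotated = sorted(set(seqs.ids) & fa.universe)
    if len(annotated) < 2:
        raise DataError("fewer than 2 annotated sequences")
    if subset_size > len(annotated):
        logger.warning(
            "subset_size %d exceeds %d annotated sequences; clamped",
            subset_size, len(annotated),
        )
        subset_size = len(annotated)

    edges = np.linspace(0.0, 1.0, bins + 1)
    rng = np.random.default_rng(seed)
    per_subset_means = np.full((n_subsets, bins), np.nan)
    counts = np.zeros(bins, dtype=np.int64)
    index = {sid: i for i, sid in enumerate(seqs.ids)}
    enc_all = encode(seqs)

    for s in range(n_subsets):
        chosen = rng.choice(len(annotated), size=subset_size, replace=False)
        ids = [annotated[i] for i in sorted(chosen)]
        enc = enc_all[[index[i] for i in ids]]
        sim = _pairwise_similarity(enc, mode)
        jac = _pairwise_jaccard([fa.features_of[i] for i in ids])
        ok = ~np.isnan(sim) & ~np.isnan(jac)
        sim, jac = sim[ok], jac[ok]
        which = np.clip(np.digitize(sim, edges[1:-1]), 0, bins - 1)
        for b in range(bins):
            mask = which == b
            if mask.any():
                per_subset_means[s, b] = jac[mask].mean()
                counts[b] += int(mask.sum())

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per_subset_means, axis=0)
        sd = np.nanstd(per_subset_means, axis=0, ddof=0)
    return SimilarityCurve(edges, mean, sd, counts)


@dataclass
class InternalSimilarity:
    """Summary of within-group pairwise sequence similarities."""

    mean: float
    median: float
    n_pairs_total: int
    similarities: np.ndarray    # raw or capped sample


def internal_similarity(
    seqs: AlignedSeqSet,
    group: set[str] | frozenset[str],
    mode: str = "onegap",
    cap: int = 150_000,
    seed: int | None = None,
) -> InternalSimilarity:
    """All within-group pairwise similarities, sampled down past ``cap``.

    The cap (uniform without replacement, seeded) keeps memory bounded
    for very large habitat groups; mean/median are computed on the
    retained sample.
    """
    members = sorted(set(group) & set(seqs.ids))
    if len(members) < 2:
        raise DataError(f"group has {len(members)} sequences; need >= 2")
    n = len(members)
    n_pairs = n * (n - 1) // 2
    index = {sid: i for i, sid in enumerate(seqs.ids)}
    enc = encode(seqs)[[index[m] for m in members]]

    if n_pairs <= cap:
        sims = _pairwise_similarity(enc, mode)
    else:
        rng = np.random.default_rng(seed)
        flat = rng.choice(n_pairs, size=cap, replace=False)
        # decode condensed index -> (i, j)
        i = (
            n - 2
            - np.floor(
                np.sqrt(-8.0 * flat + 4.0 * n * (n - 1) - 7.0) / 2.0 - 0.5
            )
        ).astype(np.int64)
        j = (flat + i + 1 + (i * (i + 1)) // 2 - n * i).astype(np.int64)
        sims = np.empty(cap, dtype=np.float64)
        for idx, (a, b) in enumerate(zip(i, j)):
            sims[idx] = 1.0 - _row_vs_block(enc[a], enc[b: b + 1], mode)[0]
    sims = sims[~np.isnan(sims)]
    if sims.size == 0:
        raise DataError("no comparable pairs in group")
    return InternalSimilarity(
        mean=float(sims.mean()),
        median=float(np.median(sims)),
        n_pairs_total=n_pairs,
        similarities=sims,
    )


def greater_than_background_test(
    group_pairs: np.ndarray, background_pairs: np.ndarray
) -> float:
    """One-sided Mann-Whitney-U p for 'group similarities exceed background'."""
    group_pairs = np.asarray(group_pairs, dtype=np.float64)
    background_pairs = np.asarray(background_pairs, dtype=np.float64)
    if group_pairs.size == 0 or background_pairs.size == 0:
        raise DataError("both similarity samples must be non-empty")
    pooled = np.concatenate([group_pairs, background_pairs])
    if np.all(pooled == pooled[0]):
        logger.warning("constant pooled similarity sample; p set to 1")
        return 1.0
    return float(
        mannwhitneyu(group_pairs, background_pairs, alternative="greater").pvalue
    )


# ---------------------------------------------------------------------------
# Monophyly
# ---------------------------------------------------------------------------


def _edge_sides(tree: PhyloTree) -> set[frozenset[str]]:
    """Leaf sets below each edge (one side of every bipartition)."""
    sides: set[frozenset[str]] = set()
    below: dict[int, frozenset[str]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset({node.taxon.label})
        else:
            s = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
            below[id(node)] = s
        if node.parent_node is not None:
            sides.add(below[id(node)])
    return sides


def monophyly_fraction(tree: PhyloTree, partition: Partition) -> float:
    """Fraction of non-singleton OTUs that are monophyletic on ``tree``.

    Unrooted convention: an OTU is monophyletic iff its (tree-restricted)
    leaf set equals one side of an edge-induced bipartition, or its
    complement does; the full leaf set passes trivially.  Sequences
    absent from the tree are dropped with a warning; singleton OTUs are
    excluded from numerator and denominator.
    """
    leaves = frozenset(tree.leaf_labels)
    overlap = set(partition.assignment) & leaves
    dropped = len(partition.assignment) - len(overlap)
    if dropped:
        logger.warning(
            "%d partitioned sequence(s) absent from the tree; dropped", dropped
        )
    if len(overlap) < 2:
        raise DataError("tree/partition leaf overlap smaller than 2")

    sides = _edge_sides(tree)
    n_tested = 0
    n_mono = 0
    for members in partition.restrict(overlap).members().values():
        fs = frozenset(members)
        if len(fs) < 2:
            continue
        n_tested += 1
        if fs == leaves or fs in sides or (leaves - fs) in sides:
            n_mono += 1
    if n_tested == 0:
        raise DataError("no non-singleton OTUs overlap the tree")
    return n_mono / n_tested
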