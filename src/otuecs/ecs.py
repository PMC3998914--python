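"""The Ecological Consistency Score (ECS).

For a partition of sequences into N OTUs of sizes n_1..n_N and an
ecological feature j with background frequency p_j, the probability of
observing feature j exactly k_ij times in OTU i under random assortment
is the binomial point probability

    L_ij = C(n_i, k_ij) * p_j**k_ij * (1 - p_j)**(n_i - k_ij).

The partition's summed log-likelihood is

    LL_set = sum_i sum_j ln L_ij

over EVERY feature in every OTU — absence of a frequent feature is
"negative enrichment" and contributes too; the k_ij = 0 cells are folded
in analytically as n_i * ln(1 - p_j).  A consistent partition
concentrates features in few OTUs, making LL_set far more negative than
expected by chance.

The null holds the OTU size distribution and total count fixed and
shuffles the sequence-to-OTU mapping uniformly (a sequence's whole
feature set travels with it, preserving inter-feature correlation).
With mu_rand and sigma_rand the mean and population standard deviation
of R such replicate LL values, the score is reported as

    ECS = (mu_rand - LL_set) / sigma_rand,

positive when ecologically similar sequences cluster together more than
chance predicts; the raw Z ``(LL_set - mu_rand)/sigma_rand`` is kept
alongside.  All likelihood math is in natural-log space via log-gamma.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import DataError, DegenerateNullError
from .io_formats import Partition
from .signals import FeatureAssignment, FeatureCountMatrix

logger = logging.getLogger(__name__)

DEFAULT_R = 1000


def binomial_likelihood(n: int, k: int, p: float) -> float:
    """Binomial point probability C(n,k) p^k (1-p)^(n-k).

    Computed via log-gamma and exponentiated only here, for display;
    internal sums stay in log space.  p = 0 and p = 1 short-circuit to
    their degenerate point masses.
    """
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    if p == 0.0:
        return 1.0 if k == 0 else 0.0
    if p == 1.0:
        return 1.0 if k == n else 0.0
    return float(math.exp(log_binomial_likelihood(n, k, p)))


def log_binomial_likelihood(n, k, p):
    """ln of the binomial point probability, vectorized over arrays."""
    n = np.asarray(n, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    return (
        gammaln(n + 1.0)
        - gammaln(k + 1.0)
        - gammaln(n - k + 1.0)
        + k * np.log(p)
        + (n - k) * np.log1p(-p)
    )


# ---------------------------------------------------------------------------
# Fast scoring context
# ---------------------------------------------------------------------------


class _ScoringContext:
    """Indexed arrays for repeated LL evaluation under permutations.

    Sequences are the intersection of the partition with the signal
    universe, in sorted-id order (so results do not depend on input
    ordering).  Features with p_j = 1 contribute ln(1) = 0 to every
    grouping and are checked for consistency, then dropped from the
    arrays.
    """

    def __init__(self, partition: Partition, fa: FeatureAssignment) -> None:
        seq_ids = sorted(set(partition.assignment) & fa.universe)
        if not seq_ids:
            raise DataError(
                f"no overlap between partition and the {fa.signal!r} universe"
            )
        self.seq_ids = seq_ids
        self.n_seq = len(seq_ids)

        otu_labels = sorted({partition.assignment[s] for s in seq_ids})
        otu_index = {o: i for i, o in enumerate(otu_labels)}
        self.groups = np.array(
            [otu_index[partition.assignment[s]] for s in seq_ids], dtype=np.int64
        )
        self.n_groups = len(otu_labels)
        self.group_sizes = np.bincount(self.groups, minlength=self.n_groups)

        feats = sorted(fa.p)
        sat = [f for f in feats if fa.p[f] >= 1.0]
        for f in sat:
            # p_j = 1 over fa.universe; on our subset every sequence must
            # carry f or the inputs are inconsistent
            if any(f not in fa.features_of[s] for s in seq_ids):
                raise DataError(
                    f"feature {f!r} has p=1 but is missing from a scored sequence"
                )
        feats = [f for f in feats if fa.p[f] < 1.0]
        self.features = feats
        self.n_feat = len(feats)
        feat_index = {f: j for j, f in enumerate(feats)}
        self.p = np.array([fa.p[f] for f in feats], dtype=np.float64)

        seq_nz: list[int] = []
        feat_nz: list[int] = []
        for i, sid in enumerate(seq_ids):
            for f in fa.features_of[sid]:
                j = feat_index.get(f)
                if j is not None:
                    seq_nz.append(i)
                    feat_nz.append(j)
        self.seq_nz = np.array(seq_nz, dtype=np.int64)
        self.feat_nz = np.array(feat_nz, dtype=np.int64)

        self.log1mp = np.log1p(-self.p)
        # baseline: every cell at k=0
        self.baseline = float(self.log1mp.sum() * self.group_sizes.sum())
        self._gammaln_n1 = gammaln(self.group_sizes + 1.0)
        self.logp = np.log(self.p)

    def ll_for_groups(self, groups: np.ndarray) -> float:
        """LL_set for an arbitrary sequence→group vector (sizes fixed)."""
        codes = groups[self.seq_nz] * self.n_feat + self.feat_nz
        uniq, k = np.unique(codes, return_counts=True)
        gi = uniq // self.n_feat
        fj = uniq % self.n_feat
        n = self.group_sizes[gi].astype(np.float64)
        kf = k.astype(np.float64)
        ll_nz = (
            self._gammaln_n1[gi]
            - gammaln(kf + 1.0)
            - gammaln(n - kf + 1.0)
            + kf * self.logp[fj]
            + (n - kf) * self.log1mp[fj]
        )
        # replace the k=0 baseline of those cells by their actual value
        return self.baseline + float((ll_nz - n * self.log1mp[fj]).sum())

    def ll_observed(self) -> float:
        return self.ll_for_groups(self.groups)


def partition_log_likelihood(
    counts: FeatureCountMatrix, fa: FeatureAssignment
) -> float:
    """LL_set from an explicit count matrix (all features, zero cells too)."""
    total = counts.total
    otus = sorted(counts.n)
    ll = 0.0
    for f, p in fa.p.items():
        if p >= 1.0:
            for otu in otus:
                k = counts.k.get((otu, f), 0)
                if k < counts.n[otu]:
                    raise DataError(
                        f"feature {f!r} has p=1 but k<n in OTU {otu!r}"
                    )
            continue
        ll += math.log1p(-p) * total
        for otu in otus:
            k = counts.k.get((otu, f), 0)
            if k:
                n = counts.n[otu]
                ll += float(
                    log_binomial_likelihood(n, k, p) - n * math.log1p(-p)
                )
    return ll


# ---------------------------------------------------------------------------
# Null model and score
# ---------------------------------------------------------------------------


def randomized_null(
    partition: Partition,
    fa: FeatureAssignment,
    R: int = DEFAULT_R,
    seed: int | None = None,
    _ctx: _ScoringContext | None = None,
) -> tuple[float, float, np.ndarray]:
    """Null LL distribution from R uniform shuffles of the OTU mapping.

    Returns (mean, population sd, samples).  Raises
    :class:`DegenerateNullError` when the null is constant (e.g. a single
    OTU, or features invariant under permutation).
    """
    if R < 2:
        raise ValueError("R must be >= 2")
    ctx = _ctx or _ScoringContext(partition, fa)
    rng = np.random.default_rng(seed)
    samples = np.empty(R, dtype=np.float64)
    for r in range(R):
        perm = rng.permutation(ctx.n_seq)
        samples[r] = ctx.ll_for_groups(ctx.groups[perm])
    mu = float(samples.mean())
    sigma = float(samples.std(ddof=0))
    if sigma == 0.0:
        raise DegenerateNullError(
            "null LL distribution is constant; ECS undefined "
            "(single OTU or permutation-invariant features)"
        )
    return mu, sigma, samples


@dataclass
class ECSResult:
    """Observed LL, null moments, and the consistency Z-score."""

    ll_obs: float
    mu_rand: float
    sigma_rand: float
    z: float                    # (ll_obs - mu_rand) / sigma_rand
    ecs: float                  # -z: positive = more consistent than chance
    abs_z: float
    R: int
    seed: int | None
    signal: str
    method: str = "unknown"
    threshold: float | None = None
    n_otus: int = 0
    n_sequences: int = 0
    jackknife_cv: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def ecs_score(
    partition: Partition,
    fa: FeatureAssignment,
    R: int = DEFAULT_R,
    seed: int | None = None,
) -> ECSResult:
    """Score one partition against one ecological signal."""
    ctx = _ScoringContext(partition, fa)
    ll_obs = ctx.ll_observed()
    mu, sigma, _ = randomized_null(partition, fa, R=R, seed=seed, _ctx=ctx)
    z = (ll_obs - mu) / sigma
    return ECSResult(
        ll_obs=ll_obs,
        mu_rand=mu,
        sigma_rand=sigma,
        z=z,
        ecs=-z,
        abs_z=abs(z),
        R=R,
        seed=seed,
        signal=fa.signal,
        method=partition.method,
        threshold=partition.threshold,
        n_otus=ctx.n_groups,
        n_sequences=ctx.n_seq,
    )


def jackknife_cv(
    partition: Partition,
    fa: FeatureAssignment,
    blocks: int = 20,
    R: int = DEFAULT_R,
    seed: int | None = None,
) -> float:
    """Delete-one-block jackknife coefficient of variation of the ECS.

    The universe is split into ``blocks`` equal random groups (seeded);
    each block is dropped in turn, background frequencies and counts are
    re-derived on the remainder, and the ECS recomputed.  Returns the
    jackknife standard error divided by the absolute mean of the block
    estimates.
    """
    if blocks < 2:
        raise ValueError("blocks must be >= 2")
    universe = sorted(set(partition.assignment) & fa.universe)
    if len(universe) < 2 * blocks:
        raise ValueError(
            f"universe of {len(universe)} too small for {blocks} blocks"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(universe))
    block_of = np.empty(len(universe), dtype=np.int64)
    block_of[order] = np.arange(len(universe)) % blocks

    estimates = []
    child_seeds = np.random.SeedSequence(seed).spawn(blocks)
    for b in range(blocks):
        keep = frozenset(
            sid for sid, blk in zip(universe, block_of) if blk != b
        )
        fa_b = fa.restrict(keep)
        part_b = partition.restrict(keep)
        sub_seed = int(child_seeds[b].generate_state(1)[0] % (2**31))
        try:
            res = ecs_score(part_b, fa_b, R=R, seed=sub_seed)
        except DegenerateNullError as exc:
            raise DegenerateNullError(
                f"jackknife block {b}: {exc}"
            ) from exc
        estimates.append(res.ecs)
    est = np.asarray(estimates)
    mean = est.mean()
    se = math.sqrt((blocks - 1) / blocks * float(((est - mean) ** 2).sum()))
    if mean == 0.0:
        raise DegenerateNullError("jackknife mean ECS is zero; cv undefined")
    return float(se / abs(mean))


def ecs_series(
    partitions: Sequence[Partition],
    fa: FeatureAssignment,
    R: int = DEFAULT_R,
    seed: int | None = None,
    jackknife_blocks: int | None = None,
) -> pd.DataFrame:
    """Score a family of partitions; rows sorted by total OTU count N.

    All partitions must cover the same sequence set.  N counts every
    OTU including singletons, which compares methods better than nominal
    thresholds.  ``jackknife_blocks`` adds a cv column (slower).
    """
    if not partitions:
        raise ValueError("no partitions given")
    ref = set(partitions[0].assignment)
    for p in partitions[1:]:
        if set(p.assignment) != ref:
            raise DataError("partitions cover different sequence sets")
    # one shared sub-seed: the same partition listed twice scores identically
    sub_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    rows = []
    for p in partitions:
        res = ecs_score(p, fa, R=R, seed=sub_seed)
        cv = None
        if jackknife_blocks:
            cv = jackknife_cv(
                p, fa, blocks=jackknife_blocks, R=R, seed=sub_seed
            )
        rows.append(
            {
                "method": p.method,
                "threshold": p.threshold,
                "n_otus": p.N,
                "ecs": res.ecs,
                "z": res.z,
                "ll_obs": res.ll_obs,
                "mu_rand": res.mu_rand,
                "sigma_rand": res.sigma_rand,
                "cv": cv,
            }
        )
    return (
        pd.DataFrame(rows).sort_values("n_otus", kind="stable").reset_index(drop=True)
    )
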