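"""Exact agglomerative clustering (single/complete/average linkage).

The full distance matrix is held in memory and every merge is exact —
no greedy seeding, no heuristic shortcut.  Linkage heights follow the
classic rules: single = minimum, complete = maximum, average = unweighted
arithmetic mean over all inter-cluster leaf pairs (UPGMA).

Determinism: among equal-distance candidate merges, the pair whose
smaller cluster index (creation order; leaves first, in input order) is
lowest wins, then the smaller second index.  This makes output
platform-independent and reproducible.

Cutting a dendrogram at nominal similarity ``t`` applies every merge with
height ≤ ``1 - t`` (inclusive, with a 1e-12 absolute tolerance so a pair
at exactly the threshold similarity clusters); the boundary convention
changes N and is therefore fixed here rather than left to float luck.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .distance import DistanceMatrix
from .io_formats import Partition

logger = logging.getLogger(__name__)

LINKAGES = ("single", "complete", "average")

CUT_EPS = 1e-12


@dataclass
class Dendrogram:
    """Ordered merge list over leaf ids.

    Cluster indices: leaves are 0..n-1 in ``ids`` order; the cluster
    created by merge ``m`` (0-based) has index ``n + m``.  Heights are
    distances in [0, 1].
    """

    ids: list[str]
    merges: list[tuple[int, int, float]]

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("cluster_a\tcluster_b\theight\n")
            for a, b, h in self.merges:
                fh.write(f"{a}\t{b}\t{h:.10g}\n")


def hclust(D: DistanceMatrix, linkage: str = "complete") -> Dendrogram:
    """Agglomerate ``D`` fully (n-1 merges) under the given linkage."""
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; use one of {LINKAGES}")
    n = D.n
    if n < 2:
        raise ValueError("need at least 2 sequences to cluster")

    M = D.square().astype(np.float64)
    np.fill_diagonal(M, np.inf)
    active = np.ones(n, dtype=bool)
    slot_cid = np.arange(n)        # cluster id living in each matrix slot
    sizes = np.ones(n, dtype=np.int64)
    merges: list[tuple[int, int, float]] = []

    for step in range(n - 1):
        # retired rows/cols are inf, so the global min is the active min
        h = float(M.min())
        # resolve ties by lowest (smaller cid, larger cid)
        cand = np.argwhere(M == h)
        best: tuple[int, int] | None = None
        best_slots: tuple[int, int] = (-1, -1)
        for pi, pj in cand:
            if pi >= pj or not (active[pi] and active[pj]):
                continue
            ca, cb = int(slot_cid[pi]), int(slot_cid[pj])
            key = (min(ca, cb), max(ca, cb))
            if best is None or key < best:
                best = key
                best_slots = (int(pi), int(pj))
        assert best is not None
        sa, sb = best_slots
        new_cid = n + step
        merges.append((best[0], best[1], h))

        # Lance-Williams row update into slot sa; retire slot sb
        ra, rb = M[sa], M[sb]
        if linkage == "single":
            new_row = np.minimum(ra, rb)
        elif linkage == "complete":
            new_row = np.maximum(ra, rb)
        else:  # average (UPGMA): mean over leaf pairs
            na, nb = sizes[sa], sizes[sb]
            new_row = (na * ra + nb * rb) / (na + nb)
        M[sa, :] = new_row
        M[:, sa] = new_row
        M[sa, sa] = np.inf
        M[sb, :] = np.inf
        M[:, sb] = np.inf
        active[sb] = False
        sizes[sa] += sizes[sb]
        slot_cid[sa] = new_cid

    return Dendrogram(list(D.ids), merges)


def _components(dend: Dendrogram, applied: Sequence[bool]) -> Partition:
    """Partition of leaves given a mask of applied merges (union-find)."""
    n = dend.n_leaves
    parent = list(range(n + len(dend.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m, ((a, b, _h), use) in enumerate(zip(dend.merges, applied)):
        if use:
            new = n + m
            parent[find(a)] = new
            parent[find(b)] = new

    roots: dict[int, str] = {}
    assignment: dict[str, str] = {}
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = f"otu{len(roots)}"
        assignment[dend.ids[leaf]] = roots[r]
    return Partition(assignment)


def cut(
    dend: Dendrogram,
    thresholds: Sequence[float],
    method: str = "hclust",
) -> list[Partition]:
    """Cut at nominal similarity thresholds, one :class:`Partition` each.

    Threshold ``t`` keeps every merge of height ≤ ``1 - t``; singletons
    are retained, so ``N`` counts them.
    """
    out = []
    for t in thresholds:
        if not (0.0 < t <= 1.0):
            raise ValueError(f"threshold {t} outside (0, 1]")
        if method == "average" and t < 0.92:
            logger.info(
                "average-linkage cut at %.3f: UPGMA heights below ~0.92 "
                "similarity are dominated by deep, size-weighted averages; "
                "interpret with care", t,
            )
        cutoff = 1.0 - t + CUT_EPS
        applied = [h <= cutoff for (_a, _b, h) in dend.merges]
        p = _components(dend, applied)
        p.method = method
        p.threshold = float(t)
        out.append(p)
    return out


def cut_n(dend: Dendrogram, n_otus: int, method: str = "hclust") -> Partition:
    """Partition with exactly ``n_otus`` clusters (first n - n_otus merges).

    Useful for comparing methods at matched total cluster counts rather
    than at matched nominal thresholds.
    """
    n = dend.n_leaves
    if not (1 <= n_otus <= n):
        raise ValueError(f"n_otus must be in [1, {n}]")
    k = n - n_otus
    applied = [i < k for i in range(len(dend.merges))]
    p = _components(dend, applied)
    p.method = method
    p.threshold = None
    return p
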