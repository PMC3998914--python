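"""Alignment-based pairwise distances with three gap-handling modes.

The distance between two aligned rows is

    d = (mismatches + gap_events) / (matches + mismatches + gap_events)

where columns gapped in BOTH sequences, and columns where either sequence
carries ``N``, are skipped outright.  The modes differ only in how columns
gapped in exactly one sequence are counted:

``gap``
    every such column is one mismatch (``gap_events`` = column count);
``onegap``
    each maximal run of consecutive such columns, gapped in the same
    sequence throughout, is one event (a multi-column indel counts once);
``nogap``
    such columns are skipped entirely (``gap_events`` = 0).

Similarity is ``1 - distance``.  A skipped column (both-gap or N) ends a
gap run; two abutting runs gapped in different sequences are two events.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import UndefinedDistanceError
from .io_formats import AlignedSeqSet

MODES = ("gap", "nogap", "onegap")

_GAP = ord("-")
_N = ord("N")


def encode(seqs: AlignedSeqSet) -> np.ndarray:
    """Aligned rows as a (n, L) uint8 matrix of ASCII codes."""
    return np.frombuffer(
        "".join(seqs.rows).encode("ascii"), dtype=np.uint8
    ).reshape(len(seqs), seqs.length)


def _row_vs_block(a: np.ndarray, block: np.ndarray, mode: str) -> np.ndarray:
    """Distances from one encoded row ``a`` (L,) to each row of ``block``.

    Vectorized over the block; returns (m,) float64 with NaN where a pair
    has zero comparable columns.
    """
    a = a[np.newaxis, :]
    skip = (a == _N) | (block == _N) | ((a == _GAP) & (block == _GAP))
    a_gap = (a == _GAP) & ~skip
    b_gap = (block == _GAP) & ~skip
    aligned = ~skip & ~a_gap & ~b_gap
    match = aligned & (a == block)

    n_match = match.sum(axis=1)
    n_mis = aligned.sum(axis=1) - n_match

    if mode == "nogap":
        gap_events = np.zeros(block.shape[0], dtype=np.int64)
    elif mode == "gap":
        gap_events = a_gap.sum(axis=1) + b_gap.sum(axis=1)
    elif mode == "onegap":
        # one event per maximal run: count run starts
        pad = np.zeros((block.shape[0], 1), dtype=bool)
        a_runs = (a_gap & ~np.concatenate([pad, a_gap[:, :-1]], axis=1)).sum(axis=1)
        b_runs = (b_gap & ~np.concatenate([pad, b_gap[:, :-1]], axis=1)).sum(axis=1)
        gap_events = a_runs + b_runs
    else:
        raise ValueError(f"unknown distance mode {mode!r}; use one of {MODES}")

    denom = n_match + n_mis + gap_events
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, (n_mis + gap_events) / denom, np.nan)
    return d


def seq_distance(a: str, b: str, mode: str = "onegap") -> float:
    """Distance in [0, 1] between two aligned rows (see module docstring)."""
    if len(a) != len(b):
        raise UndefinedDistanceError(
            f"aligned rows differ in length: {len(a)} vs {len(b)}"
        )
    if mode not in MODES:
        raise ValueError(f"unknown distance mode {mode!r}; use one of {MODES}")
    ea = np.frombuffer(a.upper().encode("ascii"), dtype=np.uint8)
    eb = np.frombuffer(b.upper().encode("ascii"), dtype=np.uint8).reshape(1, -1)
    d = _row_vs_block(ea, eb, mode)[0]
    if np.isnan(d):
        raise UndefinedDistanceError("no comparable columns between the pair")
    return float(d)


@dataclass
class DistanceMatrix:
    """Condensed (upper-triangle) pairwise distance matrix over ``ids``."""

    ids: list[str]
    condensed: np.ndarray  # length n*(n-1)//2, scipy ordering

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.condensed.shape != (n * (n - 1) // 2,):
            raise ValueError("condensed length inconsistent with id count")

    @property
    def n(self) -> int:
        return len(self.ids)

    def _pos(self, i: int, j: int) -> int:
        if i > j:
            i, j = j, i
        n = self.n
        return n * i - i * (i + 1) // 2 + (j - i - 1)

    def get(self, i: int, j: int) -> float:
        """Distance between sequences at positions i and j (0 on diagonal)."""
        if i == j:
            return 0.0
        return float(self.condensed[self._pos(i, j)])

    def square(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(self.condensed)

    def write_phylip(self, path: str | Path) -> None:
        sq = self.square()
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(f"{self.n}\n")
            for sid, row in zip(self.ids, sq):
                fh.write(sid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def pairwise_matrix(seqs: AlignedSeqSet, mode: str = "onegap") -> DistanceMatrix:
    """Full pairwise :class:`DistanceMatrix` (no heuristic shortcuts)."""
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least 2 sequences for a distance matrix")
    if mode not in MODES:
        raise ValueError(f"unknown distance mode {mode!r}; use one of {MODES}")
    enc = encode(seqs)
    out = np.empty(n * (n - 1) // 2, dtype=np.float64)
    pos = 0
    for i in range(n - 1):
        block = enc[i + 1:]
        d = _row_vs_block(enc[i], block, mode)
        if np.isnan(d).any():
            j = i + 1 + int(np.flatnonzero(np.isnan(d))[0])
            raise UndefinedDistanceError(
                f"no comparable columns between {seqs.ids[i]!r} and {seqs.ids[j]!r}"
            )
        out[pos: pos + d.size] = d
        pos += d.size
    return DistanceMatrix(list(seqs.ids), out)
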