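"""Seeded generator of clade-structured aligned datasets with tunable
niche conservatism.

The sequence model is a star-within-star topology: one random ancestral
sequence; each clade consensus mutates every ancestral site
independently with probability ``between_clade_sub_prob`` (to a
different residue, uniform over the other three); each sequence mutates
its clade consensus with ``within_clade_sub_prob``.  This deliberately
simple model keeps within- and between-clade expected identities in
closed form (:func:`expected_identity`), which is what tests that target
a clustering threshold need; it does not attempt realistic rRNA
evolution (no rate variation, no secondary-structure constraints, no
indel process beyond columnar gap injection).

Ecology: every clade has a home habitat; each sequence inherits it with
probability ``conservatism`` (rho) and otherwise draws uniformly from
all habitats.  Each habitat deterministically emits a fixed set of
``terms_per_habitat`` free-text terms, written into the annotation
table; one sampling event is assigned per (clade, habitat) pair.  Thus
rho = 1 means habitats (and their terms) are perfectly conserved within
clades and rho = 0 destroys the phylogenetic-ecological coupling.

All randomness flows from one seeded generator: the same seed gives a
bit-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import (
    AlignedSeqSet,
    AnnotationRecord,
    AnnotationTable,
    Partition,
)

_RESIDUES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GAP = ord("-")


@dataclass
class SimParams:
    """Knobs of the generator; probabilities are per site/sequence.

    ``gap_prob`` is the per-column probability that a column receives
    gaps; in such a column each sequence is gapped independently with
    probability ``gap_fraction``.
    """

    n_clades: int = 20
    seqs_per_clade: int = 50
    alignment_length: int = 300
    between_clade_sub_prob: float = 0.04
    within_clade_sub_prob: float = 0.015
    gap_prob: float = 0.0
    gap_fraction: float = 0.3
    n_habitats: int = 5
    conservatism: float = 0.9
    terms_per_habitat: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "between_clade_sub_prob",
            "within_clade_sub_prob",
            "gap_prob",
            "gap_fraction",
            "conservatism",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.within_clade_sub_prob > self.between_clade_sub_prob:
            raise ValueError(
                "within_clade_sub_prob must not exceed between_clade_sub_prob "
                "(clade structure must be real)"
            )
        for name in (
            "n_clades", "seqs_per_clade", "alignment_length",
            "n_habitats", "terms_per_habitat",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class SyntheticDataset:
    """Generated alignment, annotations and ground truth."""

    seqs: AlignedSeqSet
    annotations: AnnotationTable
    truth: dict[str, tuple[int, int]]   # seq id -> (clade, habitat)
    params: SimParams
    newick: str = ""

    def true_partition(self) -> Partition:
        """The generating clades as a partition (the recovery target)."""
        return Partition(
            {sid: f"clade{c}" for sid, (c, _h) in self.truth.items()},
            method="truth",
        )

    def habitat_names(self) -> list[str]:
        return [f"habitat_{h}" for h in range(self.params.n_habitats)]


def _mutate(rng: np.random.Generator, template: np.ndarray, prob: float) -> np.ndarray:
    """Mutate each site independently to a different residue with ``prob``."""
    out = template.copy()
    hit = rng.random(template.size) < prob
    idx = np.flatnonzero(hit)
    if idx.size:
        # pick uniformly among the 3 other residues
        cur = out[idx]
        offsets = rng.integers(1, 4, size=idx.size)
        pos = (np.searchsorted(_RESIDUES, cur) + offsets) % 4
        out[idx] = _RESIDUES[pos]
    return out


def simulate(params: SimParams) -> SyntheticDataset:
    """Generate a :class:`SyntheticDataset` (deterministic given the seed)."""
    rng = np.random.default_rng(params.seed)
    L = params.alignment_length
    C, S, H = params.n_clades, params.seqs_per_clade, params.n_habitats

    ancestor = rng.choice(_RESIDUES, size=L)
    # balanced home habitats (distinct while C <= H); random draws would
    # let clades collide on a home and muddy the conservatism dial
    home = np.arange(C) % H

    habitat_terms = {
        h: frozenset(
            f"habitat_{h}_term_{t}" for t in range(params.terms_per_habitat)
        )
        for h in range(H)
    }

    ids: list[str] = []
    rows_enc: list[np.ndarray] = []
    truth: dict[str, tuple[int, int]] = {}
    records: dict[str, AnnotationRecord] = {}
    clades_newick: list[str] = []

    for c in range(C):
        consensus = _mutate(rng, ancestor, params.between_clade_sub_prob)
        tip_names = []
        for s in range(S):
            sid = f"c{c}_s{s}"
            seq = _mutate(rng, consensus, params.within_clade_sub_prob)
            ids.append(sid)
            rows_enc.append(seq)
            if rng.random() < params.conservatism:
                hab = int(home[c])
            else:
                hab = int(rng.integers(0, H))
            truth[sid] = (c, hab)
            records[sid] = AnnotationRecord(
                seq_id=sid,
                authors=f"Consortium {c}",
                title=f"Survey of clade {c}",
                isolation_source=f"habitat_{hab} site",
                terms=habitat_terms[hab],
                habitat=f"habitat_{hab}",
                envo_ids=frozenset(),
                host_lineage=(),
            )
            tip_names.append(sid)
        clades_newick.append("(" + ",".join(tip_names) + ")")

    mat = np.vstack(rows_enc)
    if params.gap_prob > 0.0:
        gap_cols = np.flatnonzero(rng.random(L) < params.gap_prob)
        for col in gap_cols:
            gapped = rng.random(mat.shape[0]) < params.gap_fraction
            mat[gapped, col] = _GAP

    rows = [bytes(r).decode("ascii") for r in mat]
    newick = "(" + ",".join(clades_newick) + ");"
    return SyntheticDataset(
        seqs=AlignedSeqSet(ids, rows),
        annotations=AnnotationTable(records),
        truth=truth,
        params=params,
        newick=newick,
    )


def expected_identity(params: SimParams) -> tuple[float, float]:
    """Closed-form expected (within-clade, between-clade) pairwise similarity.

    Independent-sites model over 4 residues: a substitution event
    replaces the residue uniformly by one of the other three, i.e. the
    per-branch channel is ``M(s) = (1 - 4s/3) I + (s/3) J``.  Two tips
    hanging off a common source through channels with coefficients
    (a1, b1) and (a2, b2) agree per site with probability
    ``(a1+b1)(a2+b2) + 3 b1 b2`` (ancestral site uniform).  Requires
    ``gap_prob == 0``.
    """
    if params.gap_prob > 0.0:
        raise ValueError("closed form requires gap_prob == 0")

    def chan(s: float) -> tuple[float, float]:
        return 1.0 - 4.0 * s / 3.0, s / 3.0

    def compose(c1: tuple[float, float], c2: tuple[float, float]) -> tuple[float, float]:
        a1, b1 = c1
        a2, b2 = c2
        return a1 * a2, a1 * b2 + b1 * a2 + 4.0 * b1 * b2

    def agree(c1: tuple[float, float], c2: tuple[float, float]) -> float:
        a1, b1 = c1
        a2, b2 = c2
        return (a1 + b1) * (a2 + b2) + 3.0 * b1 * b2

    w = chan(params.within_clade_sub_prob)
    b = chan(params.between_clade_sub_prob)
    within = agree(w, w)
    path = compose(b, w)      # ancestor -> consensus -> tip
    between = agree(path, path)
    return float(within), float(between)
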