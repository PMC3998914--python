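"""Ecological feature signals derived from sequence annotations.

Four per-sequence binary feature constructions feed the consistency
score:

``terms``
    free-text ecological keywords, already normalized by the reader;
``envo``
    ontology term ids expanded with every ``is_a`` ancestor (roots
    excluded), so 'lake' and 'pond' both carry their shared 'water body'
    ancestor;
``sampling_site``
    one feature per sampling event, defined as the unique combination of
    submitting authors, publication title and isolation source;
``host_taxonomy``
    every taxon name along the host lineage; records without a host get
    the single feature ``NON_HOST``.

Sequences lacking a given signal are excluded from that signal's
universe and hence from background frequencies p_j, cluster sizes n_i
and counts k_ij: an unannotated sequence carries no evidence either way.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field

from .errors import DataError
from .io_formats import AnnotationTable, Ontology, Partition

logger = logging.getLogger(__name__)

SIGNALS = ("terms", "envo", "sampling_site", "host_taxonomy")

NON_HOST = "NON_HOST"

_WS = re.compile(r"\s+")


@dataclass
class FeatureAssignment:
    """Per-sequence binary feature sets for one ecological signal.

    ``p[j]`` is the background frequency of feature ``j``: the fraction
    of universe sequences whose set contains ``j`` (always in (0, 1]).
    """

    signal: str
    features_of: dict[str, frozenset[str]]
    p: dict[str, float] = field(init=False)
    universe: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        nonempty = {s for s, f in self.features_of.items() if f}
        self.universe = frozenset(nonempty)
        counts: dict[str, int] = {}
        for sid in nonempty:
            for f in self.features_of[sid]:
                counts[f] = counts.get(f, 0) + 1
        u = len(nonempty)
        self.p = {f: c / u for f, c in counts.items()} if u else {}

    @classmethod
    def with_background(
        cls,
        signal: str,
        features_of: dict[str, frozenset[str]],
        p: dict[str, float],
        universe: frozenset[str] | None = None,
    ) -> "FeatureAssignment":
        """Construct with externally stated background frequencies.

        Useful when p_j was estimated on a larger corpus than the
        sequences at hand; the usual constructor derives p from the data.
        """
        obj = cls.__new__(cls)
        obj.signal = signal
        obj.features_of = features_of
        obj.p = dict(p)
        obj.universe = (
            universe
            if universe is not None
            else frozenset(s for s, f in features_of.items() if f)
        )
        return obj

    def restrict(self, keep: frozenset[str]) -> "FeatureAssignment":
        """Re-derive the assignment (and p) on a subset of sequences."""
        sub = {s: f for s, f in self.features_of.items() if s in keep}
        return FeatureAssignment(self.signal, sub)


def _norm_field(text: str) -> str:
    return _WS.sub(" ", text.strip().lower())


def assign_sampling_events(annot: AnnotationTable) -> FeatureAssignment:
    """One feature per sampling event.

    A sampling event is the unique combination of submitting authors,
    publication title and isolation source (whitespace/case normalized).
    Records missing all three fields carry no event and drop out of the
    universe.
    """
    features: dict[str, frozenset[str]] = {}
    n_missing = 0
    for rec in annot:
        triple = (
            _norm_field(rec.authors),
            _norm_field(rec.title),
            _norm_field(rec.isolation_source),
        )
        if not any(triple):
            features[rec.seq_id] = frozenset()
            n_missing += 1
            continue
        digest = hashlib.sha1("\x1f".join(triple).encode("utf-8")).hexdigest()[:12]
        features[rec.seq_id] = frozenset({f"event:{digest}"})
    if n_missing:
        logger.warning(
            "%d record(s) missing authors, title and isolation source; "
            "excluded from the sampling-site universe", n_missing,
        )
    return FeatureAssignment("sampling_site", features)


def term_features(annot: AnnotationTable) -> FeatureAssignment:
    """Free-text ecological terms as features (empty sets excluded)."""
    return FeatureAssignment(
        "terms", {rec.seq_id: rec.terms for rec in annot}
    )


def envo_features(annot: AnnotationTable, onto: Ontology) -> FeatureAssignment:
    """Ontology ids plus all is_a ancestors, excluding ontology roots.

    Ids absent from the ontology are kept as leaf features (with a
    warning) but cannot be expanded.
    """
    roots = onto.roots
    features: dict[str, frozenset[str]] = {}
    unknown: set[str] = set()
    for rec in annot:
        expanded: set[str] = set()
        for tid in rec.envo_ids:
            if tid in onto:
                expanded.add(tid)
                expanded |= onto.ancestors(tid) - roots
            else:
                unknown.add(tid)
                expanded.add(tid)
        features[rec.seq_id] = frozenset(expanded)
    if unknown:
        logger.warning(
            "%d ontology id(s) absent from the ontology, kept unexpanded: %s",
            len(unknown), sorted(unknown)[:5],
        )
    return FeatureAssignment("envo", features)


def host_features(annot: AnnotationTable) -> FeatureAssignment:
    """Host lineage taxa as features; non-host records get ``NON_HOST``.

    Every record carries at least one feature, so the universe is the
    whole table.
    """
    features = {
        rec.seq_id: (
            frozenset(rec.host_lineage) if rec.host_lineage else frozenset({NON_HOST})
        )
        for rec in annot
    }
    return FeatureAssignment("host_taxonomy", features)


def build_signal(
    annot: AnnotationTable, signal: str, onto: Ontology | None = None
) -> FeatureAssignment:
    """Dispatch to the four signal constructors by name."""
    if signal == "terms":
        return term_features(annot)
    if signal == "envo":
        if onto is None:
            raise ValueError("the envo signal requires an ontology")
        return envo_features(annot, onto)
    if signal == "sampling_site":
        return assign_sampling_events(annot)
    if signal == "host_taxonomy":
        return host_features(annot)
    raise ValueError(f"unknown signal {signal!r}; use one of {SIGNALS}")


@dataclass
class FeatureCountMatrix:
    """Sparse per-(OTU, feature) counts restricted to the signal universe.

    ``n[i]`` is the number of universe sequences in OTU ``i``; OTUs with
    no universe member are dropped entirely.  ``k[(i, j)]`` stores only
    the non-zero counts.
    """

    n: dict[str, int]
    k: dict[tuple[str, str], int]

    def column_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (_otu, feat), c in self.k.items():
            out[feat] = out.get(feat, 0) + c
        return out

    @property
    def total(self) -> int:
        return sum(self.n.values())


def feature_counts(
    partition: Partition, fa: FeatureAssignment
) -> FeatureCountMatrix:
    """Exact integer counts k_ij of feature j in OTU i over the universe."""
    n: dict[str, int] = {}
    k: dict[tuple[str, str], int] = {}
    for sid, otu in partition.assignment.items():
        if sid not in fa.universe:
            continue
        n[otu] = n.get(otu, 0) + 1
        for feat in fa.features_of[sid]:
            k[(otu, feat)] = k.get((otu, feat), 0) + 1
    if not n:
        raise DataError(
            f"no overlap between partition and the {fa.signal!r} universe"
        )
    return FeatureCountMatrix(n, k)
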