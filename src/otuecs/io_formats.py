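"""Readers and writers for the external formats the tool touches.

Formats: aligned FASTA (equal-length rows over ``{A,C,G,T,N,-}``; ``U``
folded to ``T`` on read), delimited annotation tables with a configurable
column mapping, OTU partitions in a two-column TSV or the mothur list
dialect, OBO 1.2 ontologies (``is_a`` only) and Newick trees.

All validation is strict: invariant violations raise
:class:`~otuecs.errors.FormatError` (or subclasses) naming the offending
record rather than silently repairing input.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import networkx as nx
import obonet
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, FormatError, OntologyError

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN-")

# ---------------------------------------------------------------------------
# Aligned sequences
# ---------------------------------------------------------------------------


@dataclass
class AlignedSeqSet:
    """Equal-length aligned sequences keyed by id.

    ``rows[i]`` is the aligned residue string for ``ids[i]``; all rows have
    identical length ``length`` and use '-' as the gap character.
    """

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.ids:
            raise AlignmentError("alignment contains no sequences")
        if len(self.ids) != len(set(self.ids)):
            dupes = [i for i, c in Counter(self.ids).items() if c > 1]
            raise FormatError(f"duplicate sequence id(s): {dupes[:5]}")
        L = len(self.rows[0])
        if L < 1:
            raise AlignmentError(f"zero-length alignment row for id {self.ids[0]!r}")
        for sid, row in zip(self.ids, self.rows):
            if len(row) != L:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(row)}, expected {L}"
                )
            bad = set(row) - ALPHABET
            if bad:
                raise AlignmentError(
                    f"sequence {sid!r} contains characters outside the alphabet: "
                    f"{sorted(bad)}"
                )

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.ids)

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def subset(self, keep: Sequence[str]) -> "AlignedSeqSet":
        index = {sid: i for i, sid in enumerate(self.ids)}
        return AlignedSeqSet(list(keep), [self.rows[index[s]] for s in keep])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlignedSeqSet):
            return NotImplemented
        return self.ids == other.ids and self.rows == other.rows


def _normalize_residues(seq: str) -> str:
    return seq.upper().replace("U", "T").replace(".", "-")


def read_aligned_fasta(path: str | Path) -> AlignedSeqSet:
    """Read an aligned FASTA file into an :class:`AlignedSeqSet`.

    Residues are case-folded to upper case and ``U`` is mapped to ``T``
    (rRNA data arrives in both conventions); '.' gaps are folded to '-'.
    """
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(_normalize_residues(str(rec.seq)))
    if not ids:
        raise FormatError(f"no FASTA records found in {path}")
    return AlignedSeqSet(ids, rows)


def write_aligned_fasta(seqs: AlignedSeqSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(seqs.ids, seqs.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS: dict[str, str] = {
    "id": "seq_id",
    "authors": "authors",
    "title": "title",
    "isolation_source": "isolation_source",
    "terms": "terms",
    "habitat": "habitat",
    "envo": "envo_ids",
    "host": "host_lineage",
}

_PUNCT_EDGE = re.compile(r"^[\W_]+|[\W_]+$")
_WS = re.compile(r"\s+")


def default_stopwords() -> frozenset[str]:
    """Stop-list shipped with the package (editable text file)."""
    text = resources.files("otuecs").joinpath("data/stopwords.txt").read_text()
    words = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line.lower())
    return frozenset(words)


@dataclass
class AnnotationConfig:
    """Column mapping and vocabularies for annotation-table parsing.

    ``columns`` maps logical names (id, authors, title, isolation_source,
    terms, habitat, envo, host) to header names in the file.  A habitat
    vocabulary of ``None`` accepts any non-empty label.
    """

    columns: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_COLUMNS))
    habitat_vocabulary: frozenset[str] | None = None
    stopwords: frozenset[str] = field(default_factory=default_stopwords)
    list_separator: str = ";"


@dataclass(frozen=True)
class AnnotationRecord:
    seq_id: str
    authors: str = ""
    title: str = ""
    isolation_source: str = ""
    terms: frozenset[str] = frozenset()
    habitat: str | None = None
    envo_ids: frozenset[str] = frozenset()
    host_lineage: tuple[str, ...] = ()

    @property
    def non_host_associated(self) -> bool:
        return not self.host_lineage


@dataclass
class AnnotationTable:
    """Per-sequence ecological annotations keyed by sequence id."""

    records: dict[str, AnnotationRecord]

    def __post_init__(self) -> None:
        for sid, rec in self.records.items():
            if sid != rec.seq_id:
                raise FormatError(f"record key {sid!r} != record id {rec.seq_id!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, seq_id: str) -> AnnotationRecord:
        return self.records[seq_id]

    def __iter__(self):
        return iter(self.records.values())


def normalize_terms(
    raw: str, stopwords: frozenset[str] = frozenset(), sep: str = ";"
) -> frozenset[str]:
    """Lower-case, edge-punctuation-strip and de-duplicate a term list."""
    out = set()
    for token in re.split(rf"[{re.escape(sep)},]", raw):
        token = _WS.sub(" ", _PUNCT_EDGE.sub("", token.strip().lower()))
        if token and token not in stopwords:
            out.add(token)
    return frozenset(out)


def read_annotation_table(
    path: str | Path, config: AnnotationConfig | None = None
) -> AnnotationTable:
    """Read a delimited annotation table.

    Tab-separated with a header row; columns located via
    ``config.columns``.  Unknown habitat labels are warned about and
    treated as missing.  Empty host lineage marks a record
    non-host-associated.
    """
    config = config or AnnotationConfig()
    cols = config.columns
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise FormatError(f"{path}: empty file, expected a header row")
        header = header_line.split("\t")
        if cols["id"] not in header:
            raise FormatError(
                f"{path}: missing sequence-id column {cols['id']!r} in header"
            )
        idx = {logical: header.index(col) for logical, col in cols.items() if col in header}

        records: dict[str, AnnotationRecord] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields_ = line.split("\t")

            def get(logical: str) -> str:
                i = idx.get(logical)
                return fields_[i].strip() if i is not None and i < len(fields_) else ""

            sid = get("id")
            if not sid:
                raise FormatError(f"{path}:{lineno}: empty sequence id")
            if sid in records:
                raise FormatError(f"{path}: duplicate sequence id {sid!r}")

            habitat: str | None = get("habitat") or None
            if habitat is not None and config.habitat_vocabulary is not None:
                if habitat not in config.habitat_vocabulary:
                    logger.warning(
                        "%s:%d: habitat %r not in vocabulary; treated as missing",
                        path, lineno, habitat,
                    )
                    habitat = None

            host_raw = get("host")
            lineage = tuple(
                t.strip() for t in host_raw.split(config.list_separator) if t.strip()
            )
            envo_raw = get("envo")
            envo = frozenset(
                t.strip() for t in re.split(r"[;,\s]+", envo_raw) if t.strip()
            )
            records[sid] = AnnotationRecord(
                seq_id=sid,
                authors=get("authors"),
                title=get("title"),
                isolation_source=get("isolation_source"),
                terms=normalize_terms(
                    get("terms"), config.stopwords, config.list_separator
                ),
                habitat=habitat,
                envo_ids=envo,
                host_lineage=lineage,
            )
    return AnnotationTable(records)


def write_annotation_table(
    table: AnnotationTable, path: str | Path, config: AnnotationConfig | None = None
) -> None:
    config = config or AnnotationConfig()
    cols = config.columns
    sep = config.list_separator
    order = ["id", "authors", "title", "isolation_source", "terms", "habitat",
             "envo", "host"]
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(cols[k] for k in order) + "\n")
        for rec in table:
            fh.write(
                "\t".join(
                    [
                        rec.seq_id,
                        rec.authors,
                        rec.title,
                        rec.isolation_source,
                        sep.join(sorted(rec.terms)),
                        rec.habitat or "",
                        sep.join(sorted(rec.envo_ids)),
                        sep.join(rec.host_lineage),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------


@dataclass
class Partition:
    """A sequence→OTU assignment at a stated method/threshold.

    ``N`` counts every distinct OTU including singletons; equality is
    structural (same grouping of sequence ids, labels ignored) so that
    the same clustering read from different dialects compares equal.
    """

    assignment: dict[str, str]
    method: str = "unknown"
    threshold: float | None = None

    def __post_init__(self) -> None:
        if not self.assignment:
            raise FormatError("empty partition")

    @property
    def N(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def otu_sizes(self) -> Counter:
        return Counter(self.assignment.values())

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, otu in self.assignment.items():
            out.setdefault(otu, []).append(sid)
        return out

    def as_sets(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(m) for m in self.members().values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.as_sets() == other.as_sets()

    def restrict(self, keep: Iterable[str]) -> "Partition":
        keep = set(keep)
        sub = {s: o for s, o in self.assignment.items() if s in keep}
        return Partition(sub, method=self.method, threshold=self.threshold)


def read_partition(
    path: str | Path,
    dialect: str = "tsv",
    method: str = "unknown",
    threshold: float | None = None,
    label: str | None = None,
) -> Partition:
    """Read an OTU partition.

    ``dialect='tsv'``: two columns (sequence id, OTU id), no header.
    ``dialect='mothur-list'``: mothur list format — label, OTU count, then
    whitespace-separated OTUs of comma-joined member ids.  The label field
    is opaque (labels like ``unique`` exist in the wild); ``threshold``
    comes from the caller, not the file.  For multi-line list files,
    ``label`` selects the line.
    """
    path = Path(path)
    if dialect == "tsv":
        assignment: dict[str, str] = {}
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise FormatError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, "
                        f"got {len(parts)}"
                    )
                sid, otu = parts[0].strip(), parts[1].strip()
                if not sid or not otu:
                    raise FormatError(f"{path}:{lineno}: empty field")
                if sid in assignment:
                    raise FormatError(
                        f"{path}: sequence {sid!r} assigned to more than one OTU"
                    )
                assignment[sid] = otu
        return Partition(assignment, method=method, threshold=threshold)

    if dialect == "mothur-list":
        chosen: list[str] | None = None
        with path.open(encoding="utf-8") as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        if not lines:
            raise FormatError(f"{path}: empty mothur list file")
        if label is None:
            if len(lines) > 1:
                raise FormatError(
                    f"{path}: multiple list lines; pass label= to select one"
                )
            chosen = lines[0].split()
        else:
            for ln in lines:
                parts = ln.split()
                if parts and parts[0] == label:
                    chosen = parts
                    break
            if chosen is None:
                raise FormatError(f"{path}: no list line with label {label!r}")
        if len(chosen) < 3:
            raise FormatError(f"{path}: mothur list line has no OTUs")
        file_label, count_s, groups = chosen[0], chosen[1], chosen[2:]
        try:
            count = int(count_s)
        except ValueError as exc:
            raise FormatError(
                f"{path}: second field {count_s!r} is not an OTU count"
            ) from exc
        if count != len(groups):
            raise FormatError(
                f"{path}: list line declares {count} OTUs but contains {len(groups)}"
            )
        assignment = {}
        for k, group in enumerate(groups):
            members = [m for m in group.split(",") if m]
            if not members:
                raise FormatError(f"{path}: empty OTU at position {k}")
            for sid in members:
                if sid in assignment:
                    raise FormatError(
                        f"{path}: sequence {sid!r} assigned to more than one OTU"
                    )
                assignment[sid] = f"otu{k}"
        return Partition(assignment, method=method, threshold=threshold)

    raise ValueError(f"unknown partition dialect {dialect!r}")


def write_partition(
    partition: Partition, path: str | Path, dialect: str = "tsv",
    label: str | None = None,
) -> None:
    path = Path(path)
    if dialect == "tsv":
        with path.open("w", encoding="utf-8") as fh:
            for sid, otu in partition.assignment.items():
                fh.write(f"{sid}\t{otu}\n")
        return
    if dialect == "mothur-list":
        groups = partition.members()
        if label is None:
            label = (
                f"{1 - partition.threshold:.2f}"
                if partition.threshold is not None
                else "unique"
            )
        with path.open("w", encoding="utf-8") as fh:
            fh.write(label + "\t" + str(len(groups)))
            for otu in sorted(groups):
                fh.write("\t" + ",".join(groups[otu]))
            fh.write("\n")
        return
    raise ValueError(f"unknown partition dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Ontology (OBO) and trees (Newick)
# ---------------------------------------------------------------------------


@dataclass
class Ontology:
    """A DAG of terms linked by ``is_a`` edges (child → parent)."""

    names: dict[str, str]
    parents: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for child, ps in self.parents.items():
            if child not in self.names:
                raise OntologyError(f"edge from unknown term {child!r}")
            for p in ps:
                if p not in self.names:
                    raise OntologyError(f"is_a edge to unknown term {p!r}")
        g = nx.DiGraph(
            (c, p) for c, ps in self.parents.items() for p in ps
        )
        if g.number_of_nodes() and not nx.is_directed_acyclic_graph(g):
            raise OntologyError("cyclic is_a relation in ontology")

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(t for t in self.names if not self.parents.get(t))

    def __contains__(self, term: str) -> bool:
        return term in self.names

    def ancestors(self, term: str) -> frozenset[str]:
        """All is_a ancestors of ``term`` (term itself excluded)."""
        seen: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(self.parents.get(t, ()))
        return frozenset(seen)

    def id_of_name(self, name: str) -> str | None:
        for tid, tname in self.names.items():
            if tname.lower() == name.lower():
                return tid
        return None


def read_obo(path: str | Path) -> Ontology:
    """Read an OBO 1.2 file, retaining only id, name and is_a."""
    graph = obonet.read_obo(str(path))
    names = {
        node: (data.get("name") or node) for node, data in graph.nodes(data=True)
    }
    parents: dict[str, set[str]] = {}
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents.setdefault(child, set()).add(parent)
    return Ontology(names, {c: frozenset(p) for c, p in parents.items()})


@dataclass
class PhyloTree:
    """Unrooted tree with uniquely labelled leaves (dendropy-backed)."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.leaf_labels
        if len(labels) != len(set(labels)):
            raise FormatError("duplicate leaf labels in tree")

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]


def read_newick(path: str | Path) -> PhyloTree:
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise FormatError(f"{path}: Newick parse error: {exc}") from exc
    return PhyloTree(tree)


def tree_from_string(newick: str) -> PhyloTree:
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise FormatError(f"Newick parse error: {exc}") from exc
    return PhyloTree(tree)
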