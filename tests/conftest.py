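import pytest

from otuecs import (
    AlignedSeqSet,
    AnnotationRecord,
    AnnotationTable,
    Partition,
    SimParams,
    simulate,
)


@pytest.fixture
def tiny_alignment() -> AlignedSeqSet:
    return AlignedSeqSet(
        ["s1", "s2", "s3", "s4"],
        ["ACGTACGT", "ACGTACGA", "TGCATGCA", "TGCATGCC"],
    )


@pytest.fixture
def small_dataset():
    """4 clades x 10 sequences, perfectly conserved habitats."""
    return simulate(
        SimParams(
            n_clades=4,
            seqs_per_clade=10,
            alignment_length=200,
            conservatism=1.0,
            n_habitats=4,
            seed=11,
        )
    )


@pytest.fixture
def annot_table() -> AnnotationTable:
    recs = {
        "a": AnnotationRecord(
            "a", authors="Smith", title="T1", isolation_source="soil",
            terms=frozenset({"soil", "field"}), habitat="soil",
            host_lineage=(),
        ),
        "b": AnnotationRecord(
            "b", authors="Smith", title="T1", isolation_source="soil",
            terms=frozenset({"soil"}), habitat="soil", host_lineage=(),
        ),
        "c": AnnotationRecord(
            "c", authors="Jones", title="T2", isolation_source="skin",
            terms=frozenset({"skin"}), habitat="skin",
            host_lineage=("Animalia", "Chordata", "Homo sapiens"),
        ),
        "d": AnnotationRecord("d"),
    }
    return AnnotationTable(recs)


def random_partition(ids, n_otus, rng) -> Partition:
    labels = rng.integers(0, n_otus, size=len(ids))
    return Partition({s: f"o{g}" for s, g in zip(ids, labels)})
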