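import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from netfingerprint.ontology import (
    AnnotationTable,
    OntologyDAG,
    SemanticBackground,
    close_annotations,
    compute_ic,
)


@pytest.fixture
def chain_dag() -> OntologyDAG:
    """root <- a <- b <- c : a specialization chain of depth 3."""
    return OntologyDAG(
        namespace="biological_process",
        parents={
            "T:root": frozenset(),
            "T:a": frozenset({"T:root"}),
            "T:b": frozenset({"T:a"}),
            "T:c": frozenset({"T:b"}),
        },
        root="T:root",
    )


@pytest.fixture
def forked_dag() -> OntologyDAG:
    """Two sibling branches under the root, each with one leaf."""
    return OntologyDAG(
        namespace="biological_process",
        parents={
            "T:root": frozenset(),
            "T:x": frozenset({"T:root"}),
            "T:y": frozenset({"T:root"}),
            "T:x1": frozenset({"T:x"}),
            "T:y1": frozenset({"T:y"}),
        },
        root="T:root",
    )


@pytest.fixture
def forked_background(forked_dag) -> SemanticBackground:
    """Four genes over the forked DAG: a 1-in-4 corpus at each leaf."""
    ann = AnnotationTable(
        gene_terms={
            "gA": frozenset({"T:x1"}),
            "gB": frozenset({"T:x"}),
            "gC": frozenset({"T:y1"}),
            "gD": frozenset({"T:root"}),
        },
        closed=False,
    )
    closed = close_annotations(forked_dag, ann)
    return SemanticBackground(
        dag=forked_dag, annotations=closed, ic=compute_ic(forked_dag, closed)
    )
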