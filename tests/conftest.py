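"""Shared fixtures: tiny hand-built catalogs and ontologies."""

import pytest

from spatialgo.genome import Gene, GeneCatalog
from spatialgo.ontology import GOAnnotationSet, GODag


@pytest.fixture()
def small_catalog() -> GeneCatalog:
    """Five genes on two chromosomes, including an overlapping pair."""
    return GeneCatalog(
        [
            Gene("A", "a", "chr1", 100, 200),
            Gene("B", "b", "chr1", 1000, 2000),
            Gene("B2", "b2", "chr1", 1500, 2500),  # overlaps B
            Gene("C", "c", "chr2", 100, 300),
            Gene("D", "d", "chr2", 5000, 6000),
        ]
    )


@pytest.fixture()
def triangle_dag() -> GODag:
    """The minimal shared-parent ontology: A is_a R, B is_a R."""
    return GODag(
        {"A": "BP", "B": "BP", "R": "BP"},
        [("A", "R", "is_a"), ("B", "R", "is_a")],
    )


@pytest.fixture()
def triangle_annotations(triangle_dag) -> GOAnnotationSet:
    ann = GOAnnotationSet(triangle_dag)
    ann.add("gA", "A", "BP")
    ann.add("gB", "B", "BP")
    ann.add("gR", "R", "BP")
    return ann
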