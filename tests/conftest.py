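"""Shared fixtures: a dated primate tree and a small synthetic world."""

from __future__ import annotations

import dendropy
import pytest

from unipseudo.io_model import SpeciesTree, species_tree_from_dendropy
from unipseudo.synthetic_data import (
    GeneFate,
    build_ortholog_table,
    evolve_query_genome,
    simulate_reference_geneset,
)

PRIMATE_NEWICK = (
    "(((human:6.6,chimp:6.6):22.4,rhesus:29.0):13.9,marmoset:42.9);"
)


@pytest.fixture(scope="session")
def primate_tree() -> SpeciesTree:
    tree = dendropy.Tree.get(data=PRIMATE_NEWICK, schema="newick")
    return species_tree_from_dendropy(tree)


DEFAULT_FATES = {
    GeneFate.UNITARY_PSEUDO: 5,
    GeneFate.FAMILY_PSEUDO: 2,
    GeneFate.PROCESSED_COPY: 2,
    GeneFate.DELETED_IN_QUERY: 2,
    GeneFate.GAIN_IN_REF: 2,
}


@pytest.fixture(scope="session")
def small_world():
    """A 30-gene reference with an evolved query and planted fates."""
    ref = simulate_reference_geneset(30, n_tandem_families=2, seed=7)
    query, truth = evolve_query_genome(
        ref, neutral_sub_rate=0.0, fates=DEFAULT_FATES, seed=3
    )
    orthologs = build_ortholog_table(ref, truth)
    return ref, query, truth, orthologs
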