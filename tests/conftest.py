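"""Shared fixtures: a deterministic mini terminology and a synthetic corpus
with planted relevance, generated once per session."""

from __future__ import annotations

import pytest

from medlingua import (
    CorpusSpec,
    build_index,
    filter_language,
    generate_corpus,
    generate_mini_mesh,
    load_terminology,
    parse_citations,
)
from medlingua.fixtures import load_relevance_key

MESH_SEED = 20251
CORPUS_SEED = 4242


@pytest.fixture(scope="session")
def mesh_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("mesh")
    return generate_mini_mesh(MESH_SEED, out, n_descriptors=12, n_qualifiers=2,
                              n_metaterms=2, synonyms_per_descriptor=2)


@pytest.fixture(scope="session")
def store(mesh_dir):
    return load_terminology(mesh_dir)


@pytest.fixture(scope="session")
def planted_spec(store):
    # two planted queries on hierarchy-disjoint concepts
    chosen = []
    for ui in sorted(store.descriptors):
        if all(not (store.explode(ui) & store.explode(c)) for c in chosen):
            chosen.append(ui)
        if len(chosen) == 2:
            break
    return CorpusSpec(
        seed=CORPUS_SEED,
        n_citations=200,
        planted=dict(zip(chosen, (12, 8))),
    )


@pytest.fixture(scope="session")
def corpus_paths(planted_spec, store, tmp_path_factory):
    out = tmp_path_factory.mktemp("corpus")
    return generate_corpus(planted_spec, store, out)


@pytest.fixture(scope="session")
def corpus_records(corpus_paths):
    return parse_citations(str(corpus_paths[0]))


@pytest.fixture(scope="session")
def relevance_key(corpus_paths):
    return load_relevance_key(corpus_paths[1])


@pytest.fixture(scope="session")
def fre_index(corpus_records, store):
    return build_index(filter_language(corpus_records, "fre"), store, "fre")
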