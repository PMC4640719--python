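"""Shared fixtures: the toy two-channel network and a random-network builder."""

from __future__ import annotations

import numpy as np
import pytest

from herblink import EdgeCategory, EdgeRecord, EntityClass, NodeRef, PharmNetwork


def tkm(i) -> NodeRef:
    return NodeRef(EntityClass.TKM, f"t{i}")


def drug(i) -> NodeRef:
    return NodeRef(EntityClass.DRUG, str(i))


def disease(i) -> NodeRef:
    return NodeRef(EntityClass.DISEASE, f"D{int(i):06d}")


def protein(i) -> NodeRef:
    return NodeRef(EntityClass.PROTEIN, str(i))


def side_effect(i) -> NodeRef:
    return NodeRef(EntityClass.SIDE_EFFECT, f"D{900000 + int(i):06d}")


_POOLS = {
    EntityClass.TKM: tkm,
    EntityClass.DRUG: drug,
    EntityClass.DISEASE: disease,
    EntityClass.PROTEIN: protein,
    EntityClass.SIDE_EFFECT: side_effect,
}


@pytest.fixture
def toy_network() -> PharmNetwork:
    """One TKM sharing two diseases and one drug with protein 1, one drug with protein 2."""
    net = PharmNetwork()
    for a, b, cat in [
        (tkm(1), disease(1), EdgeCategory.TKM_DISEASE),
        (tkm(1), disease(2), EdgeCategory.TKM_DISEASE),
        (disease(1), protein(1), EdgeCategory.DISEASE_PROTEIN),
        (disease(2), protein(1), EdgeCategory.DISEASE_PROTEIN),
        (tkm(1), drug(1), EdgeCategory.TKM_DRUG),
        (drug(1), protein(1), EdgeCategory.DRUG_PROTEIN),
        (drug(1), protein(2), EdgeCategory.DRUG_PROTEIN),
    ]:
        net.add_edge(EdgeRecord(a, b, cat))
    return net


def build_random_network(rng: np.random.Generator, max_nodes: int = 60) -> PharmNetwork:
    """A random schema-valid network with all five classes and random edges.

    Pool sizes are drawn so the total node budget stays below ``max_nodes``;
    every edge joins a legal class pairing, so the result always satisfies
    the five-partite schema by construction.
    """
    per_class = max(2, max_nodes // 5)
    pools = {
        cls: [mk(i) for i in range(1, int(rng.integers(2, per_class + 1)) + 1)]
        for cls, mk in _POOLS.items()
    }
    net = PharmNetwork()
    for pool in pools.values():
        for node in pool:
            net.add_node(node)
    n_edges = int(rng.integers(5, 80))
    categories = list(EdgeCategory)
    for _ in range(n_edges):
        cat = categories[int(rng.integers(len(categories)))]
        classes = sorted(cat.endpoint_classes, key=lambda c: c.value)
        if len(classes) == 1:
            classes = classes * 2
        a_pool, b_pool = pools[classes[0]], pools[classes[1]]
        a = a_pool[int(rng.integers(len(a_pool)))]
        b = b_pool[int(rng.integers(len(b_pool)))]
        if a == b:
            continue
        prov = ["SrcA", "SrcB", "Literature"][int(rng.integers(3))]
        net.add_edge(EdgeRecord(a, b, cat, frozenset({prov})))
    return net


@pytest.fixture
def make_random_network():
    return build_random_network
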