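"""Network model: namespaces, schema closure, provenance merge, path queries."""

import numpy as np
import pytest

from herblink import (
    EdgeCategory,
    EdgeRecord,
    EntityClass,
    NamespaceError,
    NodeNotFoundError,
    NodeRef,
    PharmNetwork,
    SchemaError,
    set_tkm_id_pattern,
)
from conftest import build_random_network, disease, drug, protein, tkm


class TestNodeRef:
    @pytest.mark.parametrize(
        "cls,ident",
        [
            (EntityClass.DRUG, "444795"),
            (EntityClass.DRUG, "1"),
            (EntityClass.PROTEIN, "5743"),
            (EntityClass.DISEASE, "D012871"),
            (EntityClass.DISEASE, "D000086382"),  # post-2014 nine-digit descriptor
            (EntityClass.SIDE_EFFECT, "D006261"),
            (EntityClass.TKM, "MedCD001"),
        ],
    )
    def test_valid_identifiers(self, cls, ident):
        assert NodeRef(cls, ident).identifier == ident

    @pytest.mark.parametrize(
        "cls,ident",
        [
            (EntityClass.DRUG, "0"),        # CIDs start at 1
            (EntityClass.DRUG, "007"),      # no leading zeros
            (EntityClass.DRUG, "-5"),
            (EntityClass.DRUG, "aspirin"),
            (EntityClass.PROTEIN, "TP53"),  # symbols are not Entrez IDs
            (EntityClass.DISEASE, "012871"),
            (EntityClass.DISEASE, "D12871"),    # five digits
            (EntityClass.DISEASE, "D0128711"),  # seven digits
            (EntityClass.SIDE_EFFECT, "C537890"),
            (EntityClass.TKM, ""),
            (EntityClass.TKM, "bad|token"),
        ],
    )
    def test_invalid_identifiers_raise(self, cls, ident):
        with pytest.raises(NamespaceError):
            NodeRef(cls, ident)

    def test_equality_requires_both_fields(self):
        assert drug(7) == drug(7)
        assert drug(7) != protein(7)  # same identifier, different class
        assert drug(7) != drug(8)

    def test_parse_roundtrip_and_errors(self):
        assert NodeRef.parse("PROTEIN:7124") == protein(7124)
        with pytest.raises(ValueError, match="CLASS:identifier"):
            NodeRef.parse("7124")
        with pytest.raises(ValueError, match="unknown entity class"):
            NodeRef.parse("GENE:7124")

    def test_configurable_tkm_pattern(self):
        set_tkm_id_pattern(r"MedCD\d+$")
        try:
            NodeRef(EntityClass.TKM, "MedCD042")
            with pytest.raises(NamespaceError):
                NodeRef(EntityClass.TKM, "herb-42")
        finally:
            set_tkm_id_pattern(None)
        NodeRef(EntityClass.TKM, "herb-42")  # default: any token


class TestEdgeCategory:
    def test_exactly_eight_categories(self):
        assert len(EdgeCategory) == 8
        expected = {
            "TKM_DISEASE": {EntityClass.TKM, EntityClass.DISEASE},
            "TKM_DRUG": {EntityClass.TKM, EntityClass.DRUG},
            "DRUG_DISEASE": {EntityClass.DRUG, EntityClass.DISEASE},
            "DRUG_DRUG": {EntityClass.DRUG},
            "DRUG_PROTEIN": {EntityClass.DRUG, EntityClass.PROTEIN},
            "DRUG_SIDE_EFFECT": {EntityClass.DRUG, EntityClass.SIDE_EFFECT},
            "DISEASE_PROTEIN": {EntityClass.DISEASE, EntityClass.PROTEIN},
            "PROTEIN_PROTEIN": {EntityClass.PROTEIN},
        }
        assert {c.name: set(c.endpoint_classes) for c in EdgeCategory} == expected

    def test_no_tkm_protein_category(self):
        # known TKM-protein pairs are evaluation input, never network edges
        assert "TKM_PROTEIN" not in EdgeCategory.__members__
        with pytest.raises(SchemaError, match="TKM"):
            EdgeRecord(tkm(1), protein(1), EdgeCategory.DRUG_PROTEIN)


class TestEdgeRecord:
    def test_endpoint_order_is_canonical(self):
        e1 = EdgeRecord(tkm(1), disease(1), EdgeCategory.TKM_DISEASE)
        e2 = EdgeRecord(disease(1), tkm(1), EdgeCategory.TKM_DISEASE)
        assert e1 == e2 and e1.key == e2.key

    def test_class_mismatch_names_offenders(self):
        with pytest.raises(SchemaError, match="DISEASE-TKM"):
            EdgeRecord(tkm(1), disease(1), EdgeCategory.DRUG_DISEASE)

    def test_self_loop_rejected_even_in_same_class_category(self):
        with pytest.raises(SchemaError, match="self-loop"):
            EdgeRecord(drug(3), drug(3), EdgeCategory.DRUG_DRUG)
        # distinct same-class endpoints are fine
        EdgeRecord(drug(3), drug(4), EdgeCategory.DRUG_DRUG)


class TestPharmNetwork:
    def test_duplicate_insertion_merges_provenance(self):
        net = PharmNetwork()
        t, d = NodeRef(EntityClass.TKM, "MedCD001"), disease(12871)
        net.add_edge(EdgeRecord(t, d, EdgeCategory.TKM_DISEASE, frozenset({"KTKP"})))
        net.add_edge(EdgeRecord(d, t, EdgeCategory.TKM_DISEASE, frozenset({"Literature"})))
        assert net.edge_count == 1
        (rec,) = list(net.edges())
        assert rec.provenance == {"KTKP", "Literature"}

    def test_insertion_into_empty_network(self):
        net = PharmNetwork()
        net.add_edge(EdgeRecord(drug(444795), protein(5743), EdgeCategory.DRUG_PROTEIN))
        assert net.edge_count == 1 and len(net) == 2

    def test_edge_count_equals_distinct_keys(self, make_random_network):
        rng = np.random.default_rng(11)
        for _ in range(20):
            net = make_random_network(rng)
            records = list(net.edges())
            rebuilt = PharmNetwork.from_edges(records * 2)  # every record twice
            assert rebuilt.edge_count == len({r.key for r in records})

    def test_neighbors_empty_for_absent_node(self):
        assert PharmNetwork().neighbors(tkm(1), EdgeCategory.TKM_DRUG) == set()

    def test_neighbors_reflect_insertions(self, toy_network):
        assert toy_network.neighbors(tkm(1), EdgeCategory.TKM_DISEASE) == {
            disease(1),
            disease(2),
        }

    def test_neighbor_symmetry_on_random_networks(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            net = build_random_network(rng, max_nodes=30)
            for v in net.nodes:
                for c in EdgeCategory:
                    for u in net.neighbors(v, c):
                        assert v in net.neighbors(u, c)

    def test_schema_closure_after_random_operations(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            build_random_network(rng).validate()


class TestShortestPath:
    def test_trivial_and_chain(self, toy_network):
        assert toy_network.shortest_path(tkm(1), tkm(1)) == [tkm(1)]
        net = PharmNetwork()
        net.add_edge(EdgeRecord(tkm(1), drug(1), EdgeCategory.TKM_DRUG))
        net.add_edge(EdgeRecord(drug(1), protein(1), EdgeCategory.DRUG_PROTEIN))
        assert net.shortest_path(tkm(1), protein(1)) == [tkm(1), drug(1), protein(1)]

    def test_unknown_node_raises_naming_it(self, toy_network):
        with pytest.raises(NodeNotFoundError, match="t99"):
            toy_network.shortest_path(tkm(1), tkm(99))

    def test_disconnected_returns_none(self):
        net = PharmNetwork()
        net.add_node(tkm(1))
        net.add_node(protein(1))
        assert net.shortest_path(tkm(1), protein(1)) is None

    def test_hop_counts_match_bfs_oracle_and_symmetry(self):
        import networkx as nx

        rng = np.random.default_rng(23)
        for _ in range(10):
            net = build_random_network(rng, max_nodes=50)
            g = nx.Graph()
            g.add_nodes_from(net.nodes)
            for rec in net.edges():
                g.add_edge(rec.a, rec.b)
            oracle = dict(nx.all_pairs_shortest_path_length(g))
            nodes = sorted(net.nodes)
            for s in nodes[:10]:
                for t in nodes:
                    path = net.shortest_path(s, t)
                    back = net.shortest_path(t, s)
                    if t in oracle[s]:
                        assert path is not None
                        assert len(path) - 1 == oracle[s][t] == len(back) - 1
                    else:
                        assert path is None and back is None

    def test_deterministic_tie_break(self):
        # two equal-length routes; expansion must prefer the smaller intermediate
        net = PharmNetwork()
        for d in (drug(2), drug(9)):
            net.add_edge(EdgeRecord(tkm(1), d, EdgeCategory.TKM_DRUG))
            net.add_edge(EdgeRecord(d, protein(1), EdgeCategory.DRUG_PROTEIN))
        assert net.shortest_path(tkm(1), protein(1)) == [tkm(1), drug(2), protein(1)]
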