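"""Typed five-partite bio-pharmacological network model.

Nodes fall into five entity classes — herbal medicines (TKM), drugs,
diseases, proteins, and side effects — each with its own identifier
namespace (Med CD tokens, PubChem CIDs, MeSH descriptors, Entrez Gene
IDs, MeSH descriptors respectively).  Edges are undirected and restricted
to the eight legal class pairings; every other pairing is a schema
violation.  The model is purely in-memory; serialization lives in
:mod:`herblink.io`.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional

__all__ = [
    "EntityClass",
    "EdgeCategory",
    "NodeRef",
    "EdgeRecord",
    "PharmNetwork",
    "SchemaError",
    "NamespaceError",
    "NodeNotFoundError",
    "set_tkm_id_pattern",
    "get_tkm_id_pattern",
]


class SchemaError(ValueError):
    """An edge violates the five-partite schema (illegal class pairing)."""


class NamespaceError(ValueError):
    """An identifier fails the namespace convention of its entity class."""


class NodeNotFoundError(KeyError):
    """A queried node is not present in the network."""

    def __str__(self) -> str:  # KeyError quotes its payload; keep the message readable
        return self.args[0] if self.args else ""


class EntityClass(str, Enum):
    """The five node classes of the network."""

    TKM = "TKM"
    DRUG = "DRUG"
    DISEASE = "DISEASE"
    PROTEIN = "PROTEIN"
    SIDE_EFFECT = "SIDE_EFFECT"

    def __str__(self) -> str:
        return self.value


# Namespace conventions.  Drugs carry PubChem CIDs and proteins Entrez Gene
# IDs (decimal integers >= 1, no leading zeros or sign).  Diseases and side
# effects carry MeSH descriptors: 'D' followed by six digits (pre-2014
# vocabulary) or nine digits (post-2014).
_INT_ID = re.compile(r"^[1-9][0-9]*$")
_MESH_ID = re.compile(r"^D(?:[0-9]{6}|[0-9]{9})$")

# Med CD identifiers (Korean Traditional Knowledge Portal) have no published
# format; by default any non-empty token without whitespace/reserved
# delimiters is accepted.  A stricter pattern can be installed globally.
_TKM_RESERVED = re.compile(r"[\t\n\r|:]")
_tkm_id_pattern: Optional[re.Pattern[str]] = None


def set_tkm_id_pattern(pattern: Optional[str]) -> None:
    """Install (or clear, with ``None``) a validation regex for TKM identifiers."""
    global _tkm_id_pattern
    _tkm_id_pattern = re.compile(pattern) if pattern is not None else None


def get_tkm_id_pattern() -> Optional[re.Pattern[str]]:
    return _tkm_id_pattern


_NAMESPACE_HINT = {
    EntityClass.DRUG: "a PubChem CID (decimal integer >= 1)",
    EntityClass.PROTEIN: "an Entrez Gene ID (decimal integer >= 1)",
    EntityClass.DISEASE: "a MeSH descriptor (D + 6 or 9 digits)",
    EntityClass.SIDE_EFFECT: "a MeSH descriptor (D + 6 or 9 digits)",
    EntityClass.TKM: "a non-empty Med CD token",
}


def _validate_identifier(entity_class: EntityClass, identifier: str) -> None:
    if not identifier:
        raise NamespaceError(
            f"empty identifier for {entity_class}; expected {_NAMESPACE_HINT[entity_class]}"
        )
    if entity_class in (EntityClass.DRUG, EntityClass.PROTEIN):
        ok = bool(_INT_ID.match(identifier))
    elif entity_class in (EntityClass.DISEASE, EntityClass.SIDE_EFFECT):
        ok = bool(_MESH_ID.match(identifier))
    else:  # TKM
        ok = not _TKM_RESERVED.search(identifier)
        if ok and _tkm_id_pattern is not None:
            ok = bool(_tkm_id_pattern.match(identifier))
    if not ok:
        raise NamespaceError(
            f"identifier {identifier!r} is not valid for {entity_class}; "
            f"expected {_NAMESPACE_HINT[entity_class]}"
        )


@dataclass(frozen=True, order=True)
class NodeRef:
    """A typed node identity: entity class plus namespace-validated identifier.

    Ordering is lexicographic on ``(entity_class, identifier)``, which gives
    every deterministic tie-break in the package a single definition.
    """

    entity_class: EntityClass
    identifier: str

    def __post_init__(self) -> None:
        if not isinstance(self.entity_class, EntityClass):
            object.__setattr__(self, "entity_class", EntityClass(self.entity_class))
        _validate_identifier(self.entity_class, self.identifier)

    def __str__(self) -> str:
        return f"{self.entity_class.value}:{self.identifier}"

    @classmethod
    def parse(cls, token: str) -> "NodeRef":
        """Parse a ``CLASS:identifier`` token (e.g. ``PROTEIN:7124``)."""
        cls_name, sep, ident = token.partition(":")
        if not sep:
            raise ValueError(
                f"node token {token!r} must be CLASS:identifier, e.g. PROTEIN:7124"
            )
        try:
            entity = EntityClass(cls_name)
        except ValueError:
            valid = ", ".join(e.value for e in EntityClass)
            raise ValueError(
                f"unknown entity class {cls_name!r}; expected one of {valid}"
            ) from None
        return cls(entity, ident)


class EdgeCategory(Enum):
    """The eight legal relationship categories, each an unordered class pairing."""

    TKM_DISEASE = (EntityClass.TKM, EntityClass.DISEASE)
    TKM_DRUG = (EntityClass.TKM, EntityClass.DRUG)
    DRUG_DISEASE = (EntityClass.DRUG, EntityClass.DISEASE)
    DRUG_DRUG = (EntityClass.DRUG, EntityClass.DRUG)
    DRUG_PROTEIN = (EntityClass.DRUG, EntityClass.PROTEIN)
    DRUG_SIDE_EFFECT = (EntityClass.DRUG, EntityClass.SIDE_EFFECT)
    DISEASE_PROTEIN = (EntityClass.DISEASE, EntityClass.PROTEIN)
    PROTEIN_PROTEIN = (EntityClass.PROTEIN, EntityClass.PROTEIN)

    @property
    def endpoint_classes(self) -> frozenset[EntityClass]:
        return frozenset(self.value)

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class EdgeRecord:
    """One undirected relationship instance with category and provenance.

    Endpoints are stored in canonical order (smaller ``NodeRef`` first), so
    ``EdgeRecord(a, b, c)`` and ``EdgeRecord(b, a, c)`` compare equal.
    """

    a: NodeRef
    b: NodeRef
    category: EdgeCategory
    provenance: frozenset[str] = field(default_factory=frozenset, compare=False)

    def __post_init__(self) -> None:
        if not isinstance(self.provenance, frozenset):
            object.__setattr__(self, "provenance", frozenset(self.provenance))
        if self.b < self.a:
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)
        classes = frozenset({self.a.entity_class, self.b.entity_class})
        if classes != self.category.endpoint_classes:
            want = "-".join(sorted(c.value for c in self.category.endpoint_classes))
            got = "-".join(sorted(c.value for c in classes))
            raise SchemaError(
                f"category {self.category} joins {want}, "
                f"but endpoints are {got} ({self.a}, {self.b})"
            )
        if self.a == self.b:
            raise SchemaError(f"self-loop on {self.a} is not allowed")

    @property
    def key(self) -> tuple[NodeRef, NodeRef, EdgeCategory]:
        """The identity of the edge: canonical endpoint pair plus category."""
        return (self.a, self.b, self.category)


class PharmNetwork:
    """The five-partite graph: typed nodes, category-keyed undirected edges.

    Duplicate insertions of the same ``(pair, category)`` merge provenance
    sets rather than creating parallel edges, so neighbor counts always
    count distinct nodes, never source multiplicity.
    """

    def __init__(self) -> None:
        self._nodes: set[NodeRef] = set()
        # (a, b, category) -> provenance; a < b canonical
        self._edges: dict[tuple[NodeRef, NodeRef, EdgeCategory], frozenset[str]] = {}
        self._adj: dict[NodeRef, dict[EdgeCategory, set[NodeRef]]] = {}

    # -- construction ------------------------------------------------------

    def add_node(self, node: NodeRef) -> None:
        if node not in self._nodes:
            self._nodes.add(node)
            self._adj[node] = {}

    def add_edge(self, rec: EdgeRecord) -> "PharmNetwork":
        """Insert an edge record; repeated insertion unions provenance."""
        self.add_node(rec.a)
        self.add_node(rec.b)
        key = rec.key
        if key in self._edges:
            self._edges[key] = self._edges[key] | rec.provenance
        else:
            self._edges[key] = rec.provenance
            self._adj[rec.a].setdefault(rec.category, set()).add(rec.b)
            self._adj[rec.b].setdefault(rec.category, set()).add(rec.a)
        return self

    # -- queries -----------------------------------------------------------

    @property
    def nodes(self) -> frozenset[NodeRef]:
        return frozenset(self._nodes)

    def nodes_of_class(self, entity_class: EntityClass) -> list[NodeRef]:
        return sorted(n for n in self._nodes if n.entity_class == entity_class)

    def __contains__(self, node: NodeRef) -> bool:
        return node in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    @property
    def edge_count(self) -> int:
        return len(self._edges)

    def edges(self) -> Iterator[EdgeRecord]:
        """Iterate edge records in canonical sort order."""
        for (a, b, cat) in sorted(
            self._edges, key=lambda k: (k[2].name, k[0], k[1])
        ):
            yield EdgeRecord(a, b, cat, self._edges[(a, b, cat)])

    def category_counts(self) -> dict[EdgeCategory, int]:
        counts = {c: 0 for c in EdgeCategory}
        for (_, _, cat) in self._edges:
            counts[cat] += 1
        return counts

    def neighbors(self, v: NodeRef, c: EdgeCategory) -> set[NodeRef]:
        """Nodes sharing an edge of category ``c`` with ``v``; empty if absent."""
        if v not in self._adj:
            return set()
        return set(self._adj[v].get(c, ()))

    def all_neighbors(self, v: NodeRef) -> set[NodeRef]:
        if v not in self._adj:
            return set()
        out: set[NodeRef] = set()
        for nbrs in self._adj[v].values():
            out |= nbrs
        return out

    def edge_categories(self, a: NodeRef, b: NodeRef) -> list[EdgeCategory]:
        """Categories of the stored edges joining ``a`` and ``b``."""
        if b < a:
            a, b = b, a
        return sorted(
            (cat for (x, y, cat) in self._edges if x == a and y == b),
            key=lambda c: c.name,
        )

    def shortest_path(self, s: NodeRef, t: NodeRef) -> Optional[list[NodeRef]]:
        """Minimum-hop path from ``s`` to ``t`` across all edge categories.

        All categories are traversable at unit cost.  Ties among equal-length
        paths are broken by expanding neighbors in lexicographic
        ``(entity_class, identifier)`` order, so the returned path is
        deterministic.  Returns ``None`` when the endpoints are disconnected.
        """
        for node in (s, t):
            if node not in self._nodes:
                raise NodeNotFoundError(f"node {node} is not in the network")
        if s == t:
            return [s]
        parent: dict[NodeRef, NodeRef] = {s: s}
        queue: deque[NodeRef] = deque([s])
        while queue:
            u = queue.popleft()
            for v in sorted(self.all_neighbors(u)):
                if v in parent:
                    continue
                parent[v] = u
                if v == t:
                    path = [t]
                    while path[-1] != s:
                        path.append(parent[path[-1]])
                    path.reverse()
                    return path
                queue.append(v)
        return None

    # -- equality (value semantics over nodes, edge keys, provenance) ------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PharmNetwork):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __repr__(self) -> str:
        return f"PharmNetwork(nodes={len(self._nodes)}, edges={len(self._edges)})"

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Re-check every schema invariant over the stored node and edge sets."""
        for (a, b, cat), _prov in self._edges.items():
            if a not in self._nodes or b not in self._nodes:
                raise SchemaError(f"edge ({a}, {b}) has an endpoint outside the node set")
            # EdgeRecord re-validates classes and self-loops
            EdgeRecord(a, b, cat)
            if b not in self._adj[a].get(cat, ()) or a not in self._adj[b].get(cat, ()):
                raise SchemaError(f"adjacency index out of sync for ({a}, {b}, {cat})")
        for v, by_cat in self._adj.items():
            for cat, nbrs in by_cat.items():
                for u in nbrs:
                    key = (v, u, cat) if v < u else (u, v, cat)
                    if key not in self._edges:
                        raise SchemaError(f"dangling adjacency entry ({v}, {u}, {cat})")

    @classmethod
    def from_edges(cls, records: Iterable[EdgeRecord]) -> "PharmNetwork":
        net = cls()
        for rec in records:
            net.add_edge(rec)
        return net
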