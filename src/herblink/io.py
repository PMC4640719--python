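"""Edge-list, known-positives and GraphML input/output.

The native dialect is UTF-8 TSV with a header row; provenance labels are
pipe-delimited within their column.  Writing is canonical (stable sort,
smaller endpoint first), so two networks that are equal as values produce
byte-identical files regardless of insertion history.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Union

import networkx as nx

from .netmodel import (
    EdgeCategory,
    EdgeRecord,
    EntityClass,
    NamespaceError,
    NodeRef,
    PharmNetwork,
    SchemaError,
)

__all__ = [
    "EdgeFileError",
    "read_edges",
    "write_edges",
    "read_known_links",
    "write_known_links",
    "export_graphml",
]

logger = logging.getLogger("herblink.io")

PathLike = Union[str, Path]

EDGE_COLUMNS = (
    "source_class",
    "source_id",
    "target_class",
    "target_id",
    "category",
    "provenance",
)
KNOWN_COLUMNS = ("tkm_id", "protein_id", "provenance")


class EdgeFileError(ValueError):
    """A malformed row or header, reported with file name and line number."""


def _split_provenance(cell: str) -> frozenset[str]:
    return frozenset(p for p in cell.split("|") if p)


def _parse_row(row: dict[str, str], path: Path, lineno: int) -> EdgeRecord:
    try:
        a = NodeRef(EntityClass(row["source_class"]), row["source_id"])
        b = NodeRef(EntityClass(row["target_class"]), row["target_id"])
        category = EdgeCategory[row["category"]]
    except KeyError as exc:
        raise EdgeFileError(
            f"{path}:{lineno}: unknown category {row.get('category')!r} "
            f"(valid: {', '.join(c.name for c in EdgeCategory)})"
        ) from exc
    except (ValueError, NamespaceError) as exc:
        raise EdgeFileError(f"{path}:{lineno}: {exc}") from exc
    try:
        return EdgeRecord(a, b, category, _split_provenance(row.get("provenance", "")))
    except SchemaError as exc:
        raise EdgeFileError(f"{path}:{lineno}: {exc}") from exc


def _open_reader(path: Path, required: tuple[str, ...]):
    handle = path.open("r", encoding="utf-8", newline="")
    reader = csv.reader(handle, delimiter="\t")
    header: list[str] | None = None
    for lineno, cells in enumerate(reader, start=1):
        if not cells or (cells[0].startswith("#")):
            continue
        header = [c.strip() for c in cells]
        break
    if header is None:
        handle.close()
        raise EdgeFileError(f"{path}: empty file, expected a header row")
    missing = [c for c in required if c not in header]
    if missing:
        handle.close()
        raise EdgeFileError(
            f"{path}: header is missing column(s) {', '.join(missing)}; found {header}"
        )
    return handle, reader, header, lineno


def read_edges(path: PathLike, lenient: bool = False) -> PharmNetwork:
    """Read a native edge TSV into a :class:`PharmNetwork`.

    Columns are resolved by header name (order-insensitive); lines starting
    with ``#`` are ignored.  Malformed rows raise :class:`EdgeFileError`
    unless ``lenient`` is set, in which case they are logged and skipped.
    """
    path = Path(path)
    handle, reader, header, header_line = _open_reader(path, EDGE_COLUMNS)
    net = PharmNetwork()
    n_rows = 0
    n_skipped = 0
    with handle:
        for lineno, cells in enumerate(reader, start=header_line + 1):
            if not cells or cells[0].startswith("#"):
                continue
            if len(cells) != len(header):
                msg = f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
                if lenient:
                    logger.warning("skipping row: %s", msg)
                    n_skipped += 1
                    continue
                raise EdgeFileError(msg)
            row = dict(zip(header, cells))
            try:
                rec = _parse_row(row, path, lineno)
            except EdgeFileError as exc:
                if lenient:
                    logger.warning("skipping row: %s", exc)
                    n_skipped += 1
                    continue
                raise
            net.add_edge(rec)
            n_rows += 1
    logger.info(
        "read %s: %d rows -> %d edges (%d merged duplicates), %d skipped",
        path, n_rows, net.edge_count, n_rows - net.edge_count, n_skipped,
    )
    return net


def write_edges(net: PharmNetwork, path: PathLike) -> None:
    """Write the canonical edge TSV: deterministic for equal network values.

    Rows are sorted by (category, endpoints); within a row the
    lexicographically smaller (class, id) endpoint comes first and
    provenance labels are sorted.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(EDGE_COLUMNS)
        for rec in net.edges():  # already canonically ordered
            writer.writerow(
                [
                    rec.a.entity_class.value,
                    rec.a.identifier,
                    rec.b.entity_class.value,
                    rec.b.identifier,
                    rec.category.name,
                    "|".join(sorted(rec.provenance)),
                ]
            )


def read_known_links(path: PathLike) -> set[tuple[NodeRef, NodeRef]]:
    """Read a known TKM-protein positives TSV (columns tkm_id, protein_id, provenance).

    These literature-curated pairs are evaluation input, never network edges:
    no TKM-protein category exists in the schema.
    """
    path = Path(path)
    handle, reader, header, header_line = _open_reader(path, KNOWN_COLUMNS[:2])
    known: set[tuple[NodeRef, NodeRef]] = set()
    with handle:
        for lineno, cells in enumerate(reader, start=header_line + 1):
            if not cells or cells[0].startswith("#"):
                continue
            row = dict(zip(header, cells))
            try:
                tkm = NodeRef(EntityClass.TKM, row["tkm_id"])
                protein = NodeRef(EntityClass.PROTEIN, row["protein_id"])
            except NamespaceError as exc:
                raise EdgeFileError(f"{path}:{lineno}: {exc}") from exc
            known.add((tkm, protein))
    logger.info("read %s: %d known TKM-protein pairs", path, len(known))
    return known


def write_known_links(
    pairs: Iterable[tuple[NodeRef, NodeRef]],
    path: PathLike,
    provenance: str = "synthetic",
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(KNOWN_COLUMNS)
        for tkm, protein in sorted(pairs):
            writer.writerow([tkm.identifier, protein.identifier, provenance])


def export_graphml(net: PharmNetwork, path: PathLike) -> None:
    """Export to GraphML for external graph viewers.

    Nodes carry ``entity_class`` and ``identifier`` attributes; edges carry
    ``category`` and pipe-joined ``provenance``.  Parallel categories between
    the same endpoints become parallel edges of a multigraph.
    """
    g = nx.MultiGraph()
    for node in sorted(net.nodes):
        g.add_node(str(node), entity_class=node.entity_class.value, identifier=node.identifier)
    for rec in net.edges():
        g.add_edge(
            str(rec.a),
            str(rec.b),
            key=rec.category.name,
            category=rec.category.name,
            provenance="|".join(sorted(rec.provenance)),
        )
    nx.write_graphml(g, str(path))
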