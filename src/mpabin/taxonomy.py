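"""NCBI-style taxonomy trees: loading, navigation, LCA and path distances.

The taxonomy is a rooted tree in which every node carries a rank label
(``superkingdom`` … ``species``, plus ``no rank`` and assorted sub-ranks) and a
*level*: the number of edges separating it from the root.  Levels are raw edge
counts and deliberately include non-canonical nodes such as ``cellular
organisms`` — the distance arithmetic used by the binning algorithm is purely
edge-based, while rank *projection* (``ancestor_at_rank``) considers canonical
ranks only.

Two on-disk dialects are supported:

* the NCBI taxdump pair ``nodes.dmp``/``names.dmp`` (fields separated by
  ``\\t|\\t``, rows terminated by ``\\t|``), and
* a single-file toy TSV dialect (header ``tax_id  parent_id  rank  name``)
  used by the synthetic fixtures so that no download is ever required.
"""

from __future__ import annotations

import io
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

from .errors import TaxonomyStructureError, UnknownTaxidError, UsageError

#: Canonical ranks ordered from shallow (closest to the root) to deep.
CANONICAL_RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Specificity tiers reused by the evaluation module.
RANK_INDEX = {rank: i for i, rank in enumerate(CANONICAL_RANKS)}


@dataclass(frozen=True)
class TaxonNode:
    """One taxonomy node.

    ``level`` is the number of edges from the root (root itself has level 0);
    it is computed during loading, never read from the input.
    """

    tax_id: int
    parent_id: int
    rank: str
    name: str
    level: int


class TaxonomyTree:
    """A validated, rooted taxonomy supporting LCA and edge-distance queries.

    LCA is computed by level-equalising parent walks, O(depth) per query; NCBI
    lineages are shallow (< 40 edges) so no preprocessing is required.
    """

    def __init__(self, nodes: dict[int, TaxonNode], root_id: int,
                 rank_order: Sequence[str] = CANONICAL_RANKS) -> None:
        self.nodes = nodes
        self.root_id = root_id
        self.rank_order = tuple(rank_order)

    # -- basic access -----------------------------------------------------

    def __contains__(self, tax_id: int) -> bool:
        return tax_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, tax_id: int) -> TaxonNode:
        try:
            return self.nodes[tax_id]
        except KeyError:
            raise UnknownTaxidError(f"unknown tax_id {tax_id!r}") from None

    def parent(self, tax_id: int) -> int:
        return self.node(tax_id).parent_id

    def level(self, tax_id: int) -> int:
        return self.node(tax_id).level

    def rank(self, tax_id: int) -> str:
        return self.node(tax_id).rank

    def name(self, tax_id: int) -> str:
        return self.node(tax_id).name

    def path_to_root(self, tax_id: int) -> list[int]:
        """Return ``[tax_id, parent, …, root]`` (inclusive at both ends)."""
        node = self.node(tax_id)
        path = [tax_id]
        while node.tax_id != self.root_id:
            node = self.node(node.parent_id)
            path.append(node.tax_id)
        return path

    def children_map(self) -> dict[int, list[int]]:
        """parent → children adjacency (excludes the root's self-edge)."""
        out: dict[int, list[int]] = {t: [] for t in self.nodes}
        for node in self.nodes.values():
            if node.tax_id != self.root_id:
                out[node.parent_id].append(node.tax_id)
        return out

    def leaves(self) -> list[int]:
        has_child = set()
        for node in self.nodes.values():
            if node.tax_id != self.root_id:
                has_child.add(node.parent_id)
        return sorted(t for t in self.nodes if t not in has_child)

    # -- queries ----------------------------------------------------------

    def lca(self, a: int, b: int) -> int:
        """Lowest common ancestor of ``a`` and ``b`` (deepest shared node)."""
        na, nb = self.node(a), self.node(b)
        while na.level > nb.level:
            na = self.node(na.parent_id)
        while nb.level > na.level:
            nb = self.node(nb.parent_id)
        while na.tax_id != nb.tax_id:
            na = self.node(na.parent_id)
            nb = self.node(nb.parent_id)
        return na.tax_id

    def lca_set(self, taxa: Sequence[int]) -> int:
        """LCA of a non-empty collection, the left fold of pairwise LCA."""
        if not taxa:
            raise UsageError("lca_set requires at least one tax_id")
        acc = taxa[0]
        self.node(acc)
        for t in taxa[1:]:
            acc = self.lca(acc, t)
        return acc

    def is_ancestor(self, ancestor: int, descendant: int) -> bool:
        """True when ``ancestor`` lies on the root path of ``descendant`` (self counts)."""
        na, nd = self.node(ancestor), self.node(descendant)
        while nd.level > na.level:
            nd = self.node(nd.parent_id)
        return nd.tax_id == na.tax_id

    def ancestor_at_rank(self, tax_id: int, rank: str) -> int | None:
        """First node of ``rank`` on the inclusive walk from ``tax_id`` to the root.

        Returns ``None`` when the lineage lacks that rank.
        """
        node = self.node(tax_id)
        while True:
            if node.rank == rank:
                return node.tax_id
            if node.tax_id == self.root_id:
                return None
            node = self.node(node.parent_id)

    def pairwise_distance(self, candidate: int, taxon: int) -> int:
        """Edge distance between two nodes through their LCA.

        ``[level(candidate) − level(lca)] + [level(taxon) − level(lca)]``;
        this reduces to a plain level difference when one node is an
        ancestor of the other, and to 0 when they coincide.
        """
        anc = self.lca(candidate, taxon)
        la = self.node(anc).level
        return (self.node(candidate).level - la) + (self.node(taxon).level - la)


# -- construction and validation ------------------------------------------


def build_tree(records: Iterable[tuple[int, int, str, str]]) -> TaxonomyTree:
    """Validate raw ``(tax_id, parent_id, rank, name)`` records into a tree.

    Levels are assigned by breadth-first descent from the root.  Raises
    :class:`TaxonomyStructureError` on duplicate ids, dangling parents,
    missing/multiple roots, or nodes unreachable from the root (cycles).
    """
    raw: dict[int, tuple[int, str, str]] = {}
    root_id: int | None = None
    for tax_id, parent_id, rank, name in records:
        if tax_id in raw:
            raise TaxonomyStructureError(f"duplicate tax_id {tax_id}")
        raw[tax_id] = (parent_id, rank, name)
        if tax_id == parent_id:
            if root_id is not None:
                raise TaxonomyStructureError(
                    f"multiple roots: {root_id} and {tax_id}")
            root_id = tax_id
    if root_id is None:
        raise TaxonomyStructureError("no root row (tax_id == parent_id) found")
    for tax_id, (parent_id, _, _) in raw.items():
        if parent_id not in raw:
            raise TaxonomyStructureError(
                f"node {tax_id} has dangling parent {parent_id}")

    children: dict[int, list[int]] = {t: [] for t in raw}
    for tax_id, (parent_id, _, _) in raw.items():
        if tax_id != root_id:
            children[parent_id].append(tax_id)

    nodes: dict[int, TaxonNode] = {}
    queue: deque[tuple[int, int]] = deque([(root_id, 0)])
    while queue:
        tax_id, level = queue.popleft()
        parent_id, rank, name = raw[tax_id]
        nodes[tax_id] = TaxonNode(tax_id, parent_id, rank, name, level)
        for child in children[tax_id]:
            queue.append((child, level + 1))
    if len(nodes) != len(raw):
        orphans = sorted(set(raw) - set(nodes))[:5]
        raise TaxonomyStructureError(
            f"cycle detected: nodes unreachable from root, e.g. {orphans}")
    return TaxonomyTree(nodes, root_id)


def _dmp_fields(line: str) -> list[str]:
    # taxdump rows: fields separated by "\t|\t", terminated by "\t|"
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[:-2]
    return [f.strip() for f in line.split("\t|\t")]


def _as_lines(source: str | Path | TextIO) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as fh:
            yield from fh
    else:
        yield from source


def load_taxonomy(nodes_source: str | Path | TextIO,
                  names_source: str | Path | TextIO) -> TaxonomyTree:
    """Load an NCBI taxdump pair (``nodes.dmp``, ``names.dmp``).

    Scientific names are preferred; any other name class is used as a
    fallback, and nodes without a name row get ``taxid:<id>``.
    """
    names: dict[int, str] = {}
    scientific: set[int] = set()
    for line in _as_lines(names_source):
        if not line.strip():
            continue
        fields = _dmp_fields(line)
        tax_id = int(fields[0])
        name, name_class = fields[1], fields[3] if len(fields) > 3 else ""
        if name_class == "scientific name":
            names[tax_id] = name
            scientific.add(tax_id)
        elif tax_id not in scientific and tax_id not in names:
            names[tax_id] = name

    def records() -> Iterator[tuple[int, int, str, str]]:
        for line in _as_lines(nodes_source):
            if not line.strip():
                continue
            fields = _dmp_fields(line)
            tax_id, parent_id, rank = int(fields[0]), int(fields[1]), fields[2]
            yield tax_id, parent_id, rank, names.get(tax_id, f"taxid:{tax_id}")

    return build_tree(records())


TOY_TSV_HEADER = ("tax_id", "parent_id", "rank", "name")


def load_taxonomy_tsv(source: str | Path | TextIO) -> TaxonomyTree:
    """Load the single-file toy dialect: header + one TSV row per node."""
    lines = _as_lines(source)
    try:
        header = next(lines).rstrip("\n").split("\t")
    except StopIteration:
        raise TaxonomyStructureError("empty taxonomy file") from None
    if tuple(header) != TOY_TSV_HEADER:
        raise TaxonomyStructureError(
            f"expected header {TOY_TSV_HEADER}, got {tuple(header)}")

    def records() -> Iterator[tuple[int, int, str, str]]:
        for line in lines:
            if not line.strip():
                continue
            tax_id, parent_id, rank, name = line.rstrip("\n").split("\t")
            yield int(tax_id), int(parent_id), rank, name

    return build_tree(records())


def write_taxonomy_tsv(tree: TaxonomyTree, dest: str | Path | TextIO) -> None:
    """Write a tree in the toy TSV dialect (row order: ascending tax_id)."""
    own = isinstance(dest, (str, Path))
    fh: TextIO = open(dest, "wt", encoding="utf-8") if own else dest  # type: ignore[arg-type]
    try:
        fh.write("\t".join(TOY_TSV_HEADER) + "\n")
        for tax_id in sorted(tree.nodes):
            n = tree.nodes[tax_id]
            fh.write(f"{n.tax_id}\t{n.parent_id}\t{n.rank}\t{n.name}\n")
    finally:
        if own:
            fh.close()


def taxonomy_tsv_text(tree: TaxonomyTree) -> str:
    buf = io.StringIO()
    write_taxonomy_tsv(tree, buf)
    return buf.getvalue()
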