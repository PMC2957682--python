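"""Isolated-taxon reclassification.

Stray but significant hits against sparsely represented ("isolated") taxa are
a dominant source of misclassification in similarity-based binning: the
offending assignments show up as taxa holding only a handful of reads.
Rather than discarding such bins — which inflates the unassigned fraction —
each read in an isolated bin is promoted along its lineage to the first
ancestor that already holds enough reads, and is marked ``Unassigned`` only
when no ancestor up to the superkingdom qualifies.

The population threshold (*Isolated Taxon Size*) defaults to
``min(300, ⌈1% of total reads⌉)``: the absolute cap of 300 keeps rare
organisms — e.g. a 0.6 Mb genome sequenced at very low coverage — from being
treated as noise.

Semantics (closest literal reading of the procedure, both exposed as options):

* a taxon is isolated when its **direct** read count is *less than* the
  threshold;
* an ancestor accepts the reads when its **cumulative** (subtree) count is
  *greater than* the threshold;
* cumulative counts are computed on the pre-reclassification table and frozen
  during a pass, which makes the pass deterministic and independent of
  processing order; ``iterate=True`` repeats passes to a fixed point
  (bounded by the tree depth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .core import ASSIGNED, ROUTE_RECLASSIFIED, UNASSIGNED, Assignment
from .errors import TaxonomyStructureError
from .taxonomy import TaxonomyTree

DEFAULT_ISOLATED_CAP = 300
DEFAULT_ISOLATED_FRACTION = 0.01


@dataclass(frozen=True)
class BinTable:
    """Per-taxon read counts: direct (assigned exactly there) and cumulative
    (direct summed over the whole subtree, self included)."""

    direct_count: dict[int, int]
    cumulative_count: dict[int, int]


@dataclass(frozen=True)
class IsolationPolicy:
    isolated_taxon_size: int
    ceiling_rank: str = "superkingdom"

    def __post_init__(self) -> None:
        if self.isolated_taxon_size < 1:
            raise ValueError("isolated_taxon_size must be >= 1")


def isolated_taxon_size(
    total_reads: int,
    cap: int = DEFAULT_ISOLATED_CAP,
    fraction: float = DEFAULT_ISOLATED_FRACTION,
) -> int:
    """``min(cap, ⌈fraction × total_reads⌉)``, floored at 1."""
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    return max(1, min(cap, math.ceil(fraction * total_reads)))


def build_bin_table(tree: TaxonomyTree, assignments: Sequence[Assignment]) -> BinTable:
    """Direct counts by assigned taxid; cumulative counts by root-path sweeps.

    Only ``Assigned`` reads contribute; the cumulative count at the root
    therefore equals the number of assigned reads.
    """
    direct: dict[int, int] = {}
    for a in assignments:
        if a.status != ASSIGNED:
            continue
        if a.taxid not in tree:
            raise TaxonomyStructureError(
                f"assigned taxid {a.taxid} not present in the taxonomy")
        direct[a.taxid] = direct.get(a.taxid, 0) + 1
    cumulative: dict[int, int] = {}
    for taxid, n in direct.items():
        for anc in tree.path_to_root(taxid):
            cumulative[anc] = cumulative.get(anc, 0) + n
    return BinTable(direct, cumulative)


def _eligible_ancestors(tree: TaxonomyTree, taxid: int, ceiling_rank: str) -> list[int]:
    """Strict ancestors of ``taxid`` from the parent up to (and including) the
    ceiling-ranked node; empty when ``taxid`` sits at or above the ceiling."""
    ceiling = tree.ancestor_at_rank(taxid, ceiling_rank)
    if ceiling is None or ceiling == taxid:
        return []
    out = []
    for anc in tree.path_to_root(taxid)[1:]:
        out.append(anc)
        if anc == ceiling:
            break
    return out


def _one_pass(
    tree: TaxonomyTree,
    assignments: Sequence[Assignment],
    policy: IsolationPolicy,
) -> tuple[list[Assignment], bool]:
    bins = build_bin_table(tree, assignments)
    size = policy.isolated_taxon_size
    isolated = {t for t, n in bins.direct_count.items() if n < size}
    if not isolated:
        return list(assignments), False
    # resolve each isolated taxon once; frozen pre-pass cumulative counts
    target: dict[int, int | None] = {}
    for taxid in isolated:
        target[taxid] = None
        for anc in _eligible_ancestors(tree, taxid, policy.ceiling_rank):
            if bins.cumulative_count.get(anc, 0) > size:
                target[taxid] = anc
                break
    changed = False
    out: list[Assignment] = []
    for a in assignments:
        if a.status != ASSIGNED or a.taxid not in isolated:
            out.append(a)
            continue
        changed = True
        dest = target[a.taxid]
        if dest is None:
            out.append(replace(a, status=UNASSIGNED, taxid=None,
                               route=ROUTE_RECLASSIFIED, old_taxid=a.taxid))
        else:
            out.append(replace(a, taxid=dest, route=ROUTE_RECLASSIFIED,
                               old_taxid=a.taxid))
    return out, changed


def reclassify(
    tree: TaxonomyTree,
    assignments: Sequence[Assignment],
    policy: IsolationPolicy,
    iterate: bool = False,
) -> list[Assignment]:
    """Promote reads in isolated bins up the lineage (one pass by default).

    Guarantees: read identity is preserved (no read created or destroyed);
    every promoted read moves to a strict ancestor of its previous taxon; no
    read is ever placed above the ceiling rank; reads whose whole eligible
    lineage fails the cumulative test become ``Unassigned``.
    """
    out, changed = _one_pass(tree, assignments, policy)
    if iterate:
        # cascades are bounded by the tree depth
        max_depth = max(n.level for n in tree.nodes.values()) + 1
        for _ in range(max_depth):
            if not changed:
                break
            out, changed = _one_pass(tree, out, policy)
    return out


# -- bin summary -----------------------------------------------------------

BIN_SUMMARY_COLUMNS = ("taxid", "name", "rank", "direct_before", "direct_after")


def write_bin_summary(
    tree: TaxonomyTree,
    before: Sequence[Assignment],
    after: Sequence[Assignment],
    dest,
) -> None:
    """Per-taxon direct counts before/after reclassification, as TSV."""
    from pathlib import Path

    tb = build_bin_table(tree, before)
    ta = build_bin_table(tree, after)
    taxa = sorted(set(tb.direct_count) | set(ta.direct_count))
    own = isinstance(dest, (str, Path))
    fh = open(dest, "wt", encoding="utf-8") if own else dest
    try:
        fh.write("\t".join(BIN_SUMMARY_COLUMNS) + "\n")
        for t in taxa:
            node = tree.node(t)
            fh.write(f"{t}\t{node.name}\t{node.rank}\t"
                     f"{tb.direct_count.get(t, 0)}\t{ta.direct_count.get(t, 0)}\n")
    finally:
        if own:
            fh.close()
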