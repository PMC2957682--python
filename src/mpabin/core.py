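"""Read assignment by bit-score/tree-distance ratio scoring.

For a read with three or more valid hits the assignment proceeds in three
steps:

1. **Candidate ancestors** — running LCA over growing, score-ordered prefixes
   of the (TL-substituted) hit taxa.  Each time the running LCA changes it is
   appended, so the candidates form a root-ward chain starting at the LCA of
   the top two hits and ending at the LCA of all hits.
2. **Distances** — the edge distance between every candidate and every hit
   taxon, through their LCA (see :meth:`TaxonomyTree.pairwise_distance`).
3. **Most Probable Ancestor (MPA)** — each candidate is scored by
   ``Σ_hits bit_score / (distance + 1)`` and the read is assigned to the
   candidate with the highest sum; ties go to the deeper candidate.

The ``+ 1`` offset in the denominator is a deliberate regularisation: the
ratio is otherwise undefined at distance 0, which necessarily occurs whenever
a candidate coincides with a hit taxon (common for the first candidate).  A
uniform offset preserves the ordering intent — closer taxa contribute larger
ratios — without special-casing exact matches.

Reads with one valid hit go straight to that hit's substituted taxon; reads
with two valid hits go to the LCA of the two substituted taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from .errors import DataError, UsageError
from .hits import (
    DEFAULT_MIN_ALIGNMENT_LENGTH,
    DEFAULT_MIN_BIT_SCORE,
    AlignmentHit,
    ReadHitSet,
    filter_valid_hits,
)
from .taxonomy import TaxonomyTree
from .tl import DEFAULT_TL_CONFIG, TLConfig, determine_tl, substitute_at_tl

logger = logging.getLogger(__name__)

# assignment statuses
ASSIGNED = "Assigned"
UNASSIGNED = "Unassigned"
NO_HITS = "NoHits"

# provenance routes
ROUTE_SINGLE_HIT = "single-hit"
ROUTE_TWO_HIT_LCA = "two-hit-LCA"
ROUTE_MPA = "MPA"
ROUTE_RECLASSIFIED = "reclassified"
ROUTE_PLAIN_LCA = "plain-LCA"


@dataclass
class CandidateAncestor:
    """One node of the candidate chain.

    ``introduced_at`` is the 0-based index of the hit whose inclusion in the
    running prefix produced this LCA (the first candidate carries index 1,
    the LCA of hits 0 and 1).
    """

    taxid: int
    introduced_at: int
    ratio_sum: float = 0.0


@dataclass(frozen=True)
class Assignment:
    """Final per-read result with provenance."""

    read_id: str
    status: str
    taxid: int | None = None
    route: str | None = None
    tl: str | None = None
    old_taxid: int | None = None

    def __post_init__(self) -> None:
        if (self.status == ASSIGNED) != (self.taxid is not None):
            raise UsageError("taxid must be present exactly when status is Assigned")


def enumerate_candidate_ancestors(
    tree: TaxonomyTree,
    substituted: Sequence[tuple[AlignmentHit, int]],
) -> list[CandidateAncestor]:
    """Running-LCA chain over score-ordered prefixes (top-2, top-3, … all).

    Requires at least three entries — callers route the one- and two-hit
    shortcuts.  The chain is strictly root-ward: each appended candidate is a
    proper ancestor of its predecessor, so duplicates cannot occur.
    """
    if len(substituted) < 3:
        raise UsageError("candidate enumeration requires >= 3 hits")
    running = tree.lca(substituted[0][1], substituted[1][1])
    chain = [CandidateAncestor(running, introduced_at=1)]
    for i in range(2, len(substituted)):
        running = tree.lca(running, substituted[i][1])
        if running != chain[-1].taxid:
            chain.append(CandidateAncestor(running, introduced_at=i))
    return chain


def score_candidates(
    tree: TaxonomyTree,
    substituted: Sequence[tuple[AlignmentHit, int]],
    candidates: list[CandidateAncestor],
) -> list[CandidateAncestor]:
    """Fill ``ratio_sum = Σ_h bit_score(h) / (distance(candidate, taxon(h)) + 1)``.

    Every hit contributes to every candidate; multiple hits to the same
    subject taxon are not collapsed.
    """
    for cand in candidates:
        total = 0.0
        for hit, taxid in substituted:
            total += hit.bit_score / (tree.pairwise_distance(cand.taxid, taxid) + 1)
        cand.ratio_sum = total
    return candidates


def select_mpa(scored: Sequence[CandidateAncestor]) -> int:
    """Argmax of ``ratio_sum`` over the chain; ties resolve to the deeper node.

    The chain is ordered deepest-first, so keeping the first strict maximum
    implements the tie rule without consulting the tree.
    """
    if not scored:
        raise UsageError("select_mpa requires a non-empty candidate list")
    best = scored[0]
    for cand in scored[1:]:
        if cand.ratio_sum > best.ratio_sum:
            best = cand
    return best.taxid


def assign_read(
    tree: TaxonomyTree,
    rhs: ReadHitSet,
    config: TLConfig = DEFAULT_TL_CONFIG,
    min_bit_score: float = DEFAULT_MIN_BIT_SCORE,
    min_alignment_length: int = DEFAULT_MIN_ALIGNMENT_LENGTH,
) -> Assignment:
    """Full per-read pipeline: validity filter → TL → candidate scoring.

    Total over all hit counts: no rows ⇒ NoHits, no valid rows ⇒ Unassigned,
    one valid hit ⇒ its substituted taxon, two ⇒ their LCA, three or more ⇒
    the MPA.  The assigned node is always at the TL or shallower.
    """
    if not rhs.hits:
        return Assignment(rhs.query_id, NO_HITS)
    valid = filter_valid_hits(rhs, min_bit_score, min_alignment_length)
    if not valid.hits:
        return Assignment(rhs.query_id, UNASSIGNED)
    tl = determine_tl(valid.best_hit, config)
    substituted = substitute_at_tl(tree, valid, tl)
    taxa = [t for _, t in substituted]
    if len(taxa) == 1:
        return Assignment(rhs.query_id, ASSIGNED, taxa[0], ROUTE_SINGLE_HIT, tl)
    if len(taxa) == 2:
        return Assignment(rhs.query_id, ASSIGNED, tree.lca(taxa[0], taxa[1]),
                          ROUTE_TWO_HIT_LCA, tl)
    if len(set(taxa)) == 1:
        # degenerate chain of length one; enumeration would add nothing
        return Assignment(rhs.query_id, ASSIGNED, taxa[0], ROUTE_MPA, tl)
    chain = enumerate_candidate_ancestors(tree, substituted)
    score_candidates(tree, substituted, chain)
    return Assignment(rhs.query_id, ASSIGNED, select_mpa(chain), ROUTE_MPA, tl)


def assign_all(
    tree: TaxonomyTree,
    read_hit_sets: Iterable[ReadHitSet],
    config: TLConfig = DEFAULT_TL_CONFIG,
    min_bit_score: float = DEFAULT_MIN_BIT_SCORE,
    min_alignment_length: int = DEFAULT_MIN_ALIGNMENT_LENGTH,
) -> list[Assignment]:
    """Assign every read; output sorted by read_id for reproducibility."""
    out = [
        assign_read(tree, rhs, config, min_bit_score, min_alignment_length)
        for rhs in read_hit_sets
    ]
    out.sort(key=lambda a: a.read_id)
    return out


def plain_lca_assign(
    tree: TaxonomyTree,
    rhs: ReadHitSet,
    min_bit_score: float = DEFAULT_MIN_BIT_SCORE,
    min_alignment_length: int = DEFAULT_MIN_ALIGNMENT_LENGTH,
) -> Assignment:
    """Baseline: LCA of the raw taxa of all valid hits (no TL, no scoring).

    Provided only for qualitative comparison against the ratio-based
    assignment; this is the classical conservative LCA strategy.
    """
    if not rhs.hits:
        return Assignment(rhs.query_id, NO_HITS)
    valid = filter_valid_hits(rhs, min_bit_score, min_alignment_length)
    if not valid.hits:
        return Assignment(rhs.query_id, UNASSIGNED)
    taxid = tree.lca_set([h.subject_taxid for h in valid.hits])
    return Assignment(rhs.query_id, ASSIGNED, taxid, ROUTE_PLAIN_LCA)


# -- assignment table I/O --------------------------------------------------

ASSIGNMENT_COLUMNS = (
    "read_id", "status", "taxid", "name", "rank", "route", "tl", "old_taxid",
)


def write_assignments(
    tree: TaxonomyTree,
    assignments: Iterable[Assignment],
    dest: str | Path | TextIO,
) -> None:
    """Stable-schema TSV, one row per read (columns: ASSIGNMENT_COLUMNS)."""
    own = isinstance(dest, (str, Path))
    fh = open(dest, "wt", encoding="utf-8") if own else dest  # type: ignore[arg-type]
    try:
        fh.write("\t".join(ASSIGNMENT_COLUMNS) + "\n")
        for a in assignments:
            if a.taxid is not None:
                node = tree.node(a.taxid)
                name, rank, taxid = node.name, node.rank, str(a.taxid)
            else:
                name = rank = taxid = ""
            fh.write("\t".join([
                a.read_id, a.status, taxid, name, rank,
                a.route or "", a.tl or "",
                "" if a.old_taxid is None else str(a.old_taxid),
            ]) + "\n")
    finally:
        if own:
            fh.close()


def read_assignments(source: str | Path | TextIO) -> list[Assignment]:
    own = isinstance(source, (str, Path))
    fh = open(source, "rt", encoding="utf-8") if own else source  # type: ignore[arg-type]
    try:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ASSIGNMENT_COLUMNS:
            raise DataError(f"unexpected assignment header {header}")
        out = []
        for line in fh:
            if not line.strip():
                continue
            (read_id, status, taxid, _name, _rank, route, tl, old) = \
                line.rstrip("\n").split("\t")
            out.append(Assignment(
                read_id=read_id,
                status=status,
                taxid=int(taxid) if taxid else None,
                route=route or None,
                tl=tl or None,
                old_taxid=int(old) if old else None,
            ))
        return out
    finally:
        if own:
            fh.close()


def route_counts(assignments: Iterable[Assignment]) -> dict[str, int]:
    """Run-log summary: reads per status/route."""
    counts: dict[str, int] = {}
    for a in assignments:
        key = a.status if a.status != ASSIGNED else (a.route or ASSIGNED)
        counts[key] = counts.get(key, 0) + 1
    return counts
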