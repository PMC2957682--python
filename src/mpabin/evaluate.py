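"""Accuracy and specificity evaluation against known source taxa.

An assignment is **Correct** when the assigned node lies on the path from the
root to the read's true source taxon (ancestor-or-self of the truth), and
**Wrong** otherwise; ``Unassigned``/``NoHits`` pass through as their own
categories, so the four categories partition the reads.

Correct assignments are further tiered by depth:

* **Higher** (non-specific) — root, ``cellular organisms``, superkingdom;
* **Intermediate** — phylum, class or order;
* **Specific** — family or anything deeper.

Nodes of non-canonical rank (species groups, strains, ``no rank`` clades)
take the tier of their nearest canonical ancestor, which places e.g. a
species-complex node in the Specific tier.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

from .core import ASSIGNED, NO_HITS, UNASSIGNED, Assignment
from .errors import ParseError, UsageError
from .taxonomy import RANK_INDEX, TaxonomyTree

CATEGORY_CORRECT = "Correct"
CATEGORY_WRONG = "Wrong"
CATEGORIES = (CATEGORY_CORRECT, CATEGORY_WRONG, UNASSIGNED, NO_HITS)

SPEC_HIGHER = "Higher"
SPEC_INTERMEDIATE = "Intermediate"
SPEC_SPECIFIC = "Specific"
SPEC_NA = "not-applicable"
SPECIFICITY_CLASSES = (SPEC_SPECIFIC, SPEC_INTERMEDIATE, SPEC_HIGHER)

_RANK_TIER = {
    "superkingdom": SPEC_HIGHER,
    "phylum": SPEC_INTERMEDIATE,
    "class": SPEC_INTERMEDIATE,
    "order": SPEC_INTERMEDIATE,
    # family and deeper
    "family": SPEC_SPECIFIC,
    "genus": SPEC_SPECIFIC,
    "species": SPEC_SPECIFIC,
}


@dataclass(frozen=True)
class EvaluationRecord:
    read_id: str
    true_taxid: int
    category: str
    specificity: str = SPEC_NA


def specificity_class(tree: TaxonomyTree, assigned_taxid: int) -> str:
    """Depth tier of a node; non-canonical ranks defer to the nearest
    canonical ancestor, and lineages with no canonical rank at all (root,
    ``cellular organisms``) are Higher."""
    node = tree.node(assigned_taxid)
    while True:
        if node.rank in _RANK_TIER:
            return _RANK_TIER[node.rank]
        if node.tax_id == tree.root_id:
            return SPEC_HIGHER
        node = tree.node(node.parent_id)


def categorize(tree: TaxonomyTree, a: Assignment, true_taxid: int) -> EvaluationRecord:
    """Classify one assignment against the read's true source taxon."""
    tree.node(true_taxid)
    if a.status in (UNASSIGNED, NO_HITS):
        return EvaluationRecord(a.read_id, true_taxid, a.status)
    assert a.taxid is not None
    if tree.is_ancestor(a.taxid, true_taxid):
        return EvaluationRecord(a.read_id, true_taxid, CATEGORY_CORRECT,
                                specificity_class(tree, a.taxid))
    return EvaluationRecord(a.read_id, true_taxid, CATEGORY_WRONG)


def categorize_all(
    tree: TaxonomyTree,
    assignments: Sequence[Assignment],
    truth: Mapping[str, int],
) -> list[EvaluationRecord]:
    return [categorize(tree, a, truth[a.read_id]) for a in assignments]


def summarize(records: Sequence[EvaluationRecord]) -> pd.DataFrame:
    """Category and specificity percentages over all reads.

    Returns a tidy frame with columns ``group`` (``category`` or
    ``specificity``), ``label``, ``count`` and ``percent``.  Category
    percentages sum to 100; specificity rows break the Correct share down
    further (they sum to the Correct percentage).
    """
    if not records:
        raise UsageError("summarize requires a non-empty record list")
    n = len(records)
    rows = []
    for label in CATEGORIES:
        count = sum(1 for r in records if r.category == label)
        rows.append(("category", label, count, 100.0 * count / n))
    for label in SPECIFICITY_CLASSES:
        count = sum(1 for r in records if r.specificity == label)
        rows.append(("specificity", label, count, 100.0 * count / n))
    return pd.DataFrame(rows, columns=["group", "label", "count", "percent"])


def category_percentages(records: Sequence[EvaluationRecord]) -> dict[str, float]:
    """Convenience view of :func:`summarize` for the four categories."""
    df = summarize(records)
    sub = df[df["group"] == "category"]
    return dict(zip(sub["label"], sub["percent"]))


def coverage(n_reads: int, read_length: float, genome_length: float) -> float:
    """Fold coverage ``n_reads × read_length / genome_length``, to 2 decimals.

    E.g. 300 reads of 1000 bp over a 0.6 Mb genome give 0.5X; the same read
    count at 250 bp gives 0.13X (0.125 rounded).
    """
    if read_length <= 0 or genome_length <= 0:
        raise ValueError("read_length and genome_length must be positive")
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    fold = n_reads * read_length / genome_length
    # report with conventional half-up rounding (0.125X prints as 0.13X)
    return float(Decimal(str(fold)).quantize(Decimal("0.01"), ROUND_HALF_UP))


# -- truth-table I/O -------------------------------------------------------


def read_truth(source: str | Path | TextIO) -> dict[str, int]:
    """Two-column TSV ``read_id → true taxid`` (optional header)."""
    own = isinstance(source, (str, Path))
    fh = open(source, "rt", encoding="utf-8") if own else source  # type: ignore[arg-type]
    out: dict[str, int] = {}
    try:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ParseError(f"truth table line {lineno}: expected 2 columns")
            if lineno == 1 and parts[0] == "read_id":
                continue
            out[parts[0]] = int(parts[1])
    finally:
        if own:
            fh.close()
    return out


def write_truth(truth: Mapping[str, int], dest: str | Path | TextIO) -> None:
    own = isinstance(dest, (str, Path))
    fh = open(dest, "wt", encoding="utf-8") if own else dest  # type: ignore[arg-type]
    try:
        fh.write("read_id\ttrue_taxid\n")
        for read_id in sorted(truth):
            fh.write(f"{read_id}\t{truth[read_id]}\n")
    finally:
        if own:
            fh.close()
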