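"""BLAST tabular (outfmt 6) ingestion, ordering and hit-validity filtering.

A *valid* hit is one whose bit-score is at least ``min_bit_score`` (default 35
bits) and whose alignment length strictly exceeds ``min_alignment_length``
(default 25 columns).  A read none of whose hits survive this filter is
*Unassigned*, which is distinct from *NoHits* (no BLAST rows at all).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

from .errors import ParseError

logger = logging.getLogger(__name__)

DEFAULT_MIN_BIT_SCORE = 35.0
DEFAULT_MIN_ALIGNMENT_LENGTH = 25

#: the 12 canonical outfmt-6 columns
OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass(frozen=True)
class AlignmentHit:
    """One BLAST hit.

    ``identities`` is a residue *count*; plain 12-column outfmt 6 reports only
    a percentage, which is converted with ``round(pident × length / 100)``.
    ``positives`` is absent (``None``) in the plain format.
    """

    query_id: str
    subject_id: str
    subject_taxid: int
    bit_score: float
    alignment_length: int
    identities: int
    positives: int | None = None
    gaps: int = 0
    evalue: float | None = None

    @property
    def identity_fraction(self) -> float:
        return self.identities / self.alignment_length

    @property
    def positive_fraction(self) -> float | None:
        if self.positives is None:
            return None
        return self.positives / self.alignment_length


@dataclass(frozen=True)
class ReadHitSet:
    """All hits of one read, in descending bit-score order.

    Ties are broken by ascending subject taxid, then by input order, so the
    ordering is total and reproducible across platforms and row shuffles.
    """

    query_id: str
    hits: tuple[AlignmentHit, ...] = field(default_factory=tuple)

    @property
    def best_hit(self) -> AlignmentHit:
        return self.hits[0]

    def __len__(self) -> int:
        return len(self.hits)


def order_hits(hits: Sequence[tuple[int, AlignmentHit]]) -> tuple[AlignmentHit, ...]:
    """Sort ``(input_index, hit)`` pairs by the canonical ordering."""
    return tuple(
        h for _, h in sorted(
            hits, key=lambda p: (-p[1].bit_score, p[1].subject_taxid, p[0]))
    )


def make_read_hit_set(query_id: str, hits: Iterable[AlignmentHit]) -> ReadHitSet:
    return ReadHitSet(query_id, order_hits(list(enumerate(hits))))


def _parse_row(line: str, lineno: int) -> dict:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise ParseError(
            f"line {lineno}: expected >= 12 tab-separated columns, got {len(fields)}")
    try:
        return {
            "qseqid": fields[0],
            "sseqid": fields[1],
            "pident": float(fields[2]),
            "length": int(fields[3]),
            "gapopen": int(fields[5]),
            "evalue": float(fields[10]),
            "bitscore": float(fields[11]),
            "extra": fields[12:],
        }
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from None


def parse_blast_tabular(
    source: str | Path | TextIO | Iterable[str],
    taxid_map: Mapping[str, int] | None = None,
    taxid_col: int | None = None,
    positives_col: int | None = None,
) -> list[ReadHitSet]:
    """Parse outfmt-6 rows into one :class:`ReadHitSet` per query.

    Taxids come either from ``taxid_map`` (subject_id → taxid) or from a
    0-based extra ``taxid_col`` (≥ 12, e.g. a ``staxids`` column appended to
    the canonical 12).  Subjects with no resolvable taxid are skipped with a
    logged warning — stale subject→taxid mappings must not abort a run.
    Rows for one query need not be contiguous; output order follows first
    appearance of each query in the input.
    """
    if taxid_map is None and taxid_col is None:
        raise ParseError("either taxid_map or taxid_col is required")
    own = isinstance(source, (str, Path))
    fh = open(source, "rt", encoding="utf-8") if own else source  # type: ignore[arg-type]
    per_query: dict[str, list[tuple[int, AlignmentHit]]] = {}
    skipped = 0
    try:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            row = _parse_row(line, lineno)
            taxid: int | None = None
            if taxid_col is not None:
                idx = taxid_col - 12
                if idx < 0 or idx >= len(row["extra"]):
                    raise ParseError(
                        f"line {lineno}: taxid column {taxid_col} out of range")
                # staxids may be ';'-separated; take the first
                taxid = int(str(row["extra"][idx]).split(";")[0])
            elif taxid_map is not None and row["sseqid"] in taxid_map:
                taxid = taxid_map[row["sseqid"]]
            if taxid is None:
                skipped += 1
                continue
            positives: int | None = None
            if positives_col is not None:
                idx = positives_col - 12
                if idx < 0 or idx >= len(row["extra"]):
                    raise ParseError(
                        f"line {lineno}: positives column {positives_col} out of range")
                positives = int(round(float(row["extra"][idx])))
            hit = AlignmentHit(
                query_id=row["qseqid"],
                subject_id=row["sseqid"],
                subject_taxid=taxid,
                bit_score=row["bitscore"],
                alignment_length=row["length"],
                identities=int(round(row["pident"] * row["length"] / 100.0)),
                positives=positives,
                gaps=row["gapopen"],
                evalue=row["evalue"],
            )
            per_query.setdefault(row["qseqid"], []).append((lineno, hit))
    finally:
        if own:
            fh.close()
    if skipped:
        logger.warning("skipped %d hit rows with no subject→taxid mapping", skipped)
    return [ReadHitSet(q, order_hits(pairs)) for q, pairs in per_query.items()]


def filter_valid_hits(
    rhs: ReadHitSet,
    min_bit_score: float = DEFAULT_MIN_BIT_SCORE,
    min_alignment_length: int = DEFAULT_MIN_ALIGNMENT_LENGTH,
) -> ReadHitSet:
    """Keep hits with bit-score ≥ ``min_bit_score`` and length > ``min_alignment_length``.

    Order-preserving and idempotent.  An empty result marks the read as
    Unassigned downstream.
    """
    kept = tuple(
        h for h in rhs.hits
        if h.bit_score >= min_bit_score and h.alignment_length > min_alignment_length
    )
    return replace(rhs, hits=kept)


def write_blast_tabular(
    read_hit_sets: Iterable[ReadHitSet],
    dest: str | Path | TextIO,
    positives_col: bool = False,
) -> None:
    """Write hits back out as outfmt-6 rows (plus an optional positives column).

    Coordinates are synthesised as 1..length — only the columns the binning
    algorithm consumes round-trip exactly.
    """
    own = isinstance(dest, (str, Path))
    fh = open(dest, "wt", encoding="utf-8") if own else dest  # type: ignore[arg-type]
    try:
        for rhs in read_hit_sets:
            for h in rhs.hits:
                pident = 100.0 * h.identities / h.alignment_length
                row = [
                    h.query_id, h.subject_id, f"{pident:.2f}",
                    str(h.alignment_length),
                    str(h.alignment_length - h.identities), str(h.gaps),
                    "1", str(h.alignment_length), "1", str(h.alignment_length),
                    f"{(h.evalue if h.evalue is not None else 0.0):.2g}",
                    f"{h.bit_score:.1f}",
                ]
                if positives_col:
                    row.append("" if h.positives is None else str(h.positives))
                fh.write("\t".join(row) + "\n")
    finally:
        if own:
            fh.close()


def write_taxid_map(taxid_map: Mapping[str, int], dest: str | Path | TextIO) -> None:
    own = isinstance(dest, (str, Path))
    fh = open(dest, "wt", encoding="utf-8") if own else dest  # type: ignore[arg-type]
    try:
        for subject in sorted(taxid_map):
            fh.write(f"{subject}\t{taxid_map[subject]}\n")
    finally:
        if own:
            fh.close()


def read_taxid_map(source: str | Path | TextIO) -> dict[str, int]:
    """Two-column TSV ``subject_id → taxid``."""
    own = isinstance(source, (str, Path))
    fh = open(source, "rt", encoding="utf-8") if own else source  # type: ignore[arg-type]
    out: dict[str, int] = {}
    try:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ParseError(f"taxid map line {lineno}: expected 2 columns")
            out[parts[0]] = int(parts[1])
    finally:
        if own:
            fh.close()
    return out
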