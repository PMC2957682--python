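"""Taxonomic-level (TL) restriction.

The quality of the best alignment of a read decides how deep in the taxonomy
its assignment may land: near-perfect alignments may be assigned at species
level, poorer ones are restricted to progressively shallower ranks.  Once the
TL is fixed, *every* hit taxon of the read is substituted by its ancestor at
that rank, so the final assignment can only fall at the TL or above it.

The rank thresholds are calibration constants, not published values: this
module ships a documented default rule table mapping identity/positive
fractions of the best hit to restriction ranks, overridable from a YAML file.
Parity with any external tool's thresholds is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, TextIO

import yaml

from .errors import ConfigError
from .hits import AlignmentHit, ReadHitSet
from .taxonomy import CANONICAL_RANKS, RANK_INDEX, TaxonomyTree


@dataclass(frozen=True)
class TLRule:
    """One threshold row: ``fractions ≥ thresholds ⇒ restrict at this rank``."""

    restriction_rank: str
    min_identity_fraction: float
    min_positive_fraction: float | None = None

    def matches(self, identity_fraction: float,
                positive_fraction: float | None) -> bool:
        if identity_fraction < self.min_identity_fraction:
            return False
        # plain outfmt 6 lacks a positives column; fall back to identity-only
        if self.min_positive_fraction is not None and positive_fraction is not None:
            return positive_fraction >= self.min_positive_fraction
        return True


@dataclass(frozen=True)
class TLConfig:
    """Ordered rule table; the first matching rule wins.

    Rules must be sorted from most to least stringent (deepest rank first)
    and ``fallback_rank`` applies when nothing matches.
    """

    rules: tuple[TLRule, ...]
    fallback_rank: str = "superkingdom"

    def __post_init__(self) -> None:
        for rule in self.rules:
            if rule.restriction_rank not in RANK_INDEX:
                raise ConfigError(f"unknown rank {rule.restriction_rank!r}")
            if not 0.0 <= rule.min_identity_fraction <= 1.0:
                raise ConfigError("identity fractions must lie in [0, 1]")
            if (rule.min_positive_fraction is not None
                    and not 0.0 <= rule.min_positive_fraction <= 1.0):
                raise ConfigError("positive fractions must lie in [0, 1]")
            if RANK_INDEX[self.fallback_rank] > RANK_INDEX[rule.restriction_rank]:
                raise ConfigError(
                    "fallback_rank must be at or above every rule's rank")


#: Default calibration table.  Fractions are computed against the full
#: alignment length (gap columns included), matching BLAST's percentages.
DEFAULT_TL_CONFIG = TLConfig(
    rules=(
        TLRule("species", 0.95, 0.97),
        TLRule("genus", 0.85, 0.87),
        TLRule("family", 0.70, 0.72),
        TLRule("order", 0.55, 0.57),
        TLRule("class", 0.45, 0.47),
        TLRule("phylum", 0.35, 0.37),
    ),
    fallback_rank="superkingdom",
)


def determine_tl(best: AlignmentHit, config: TLConfig = DEFAULT_TL_CONFIG) -> str:
    """Restriction rank for a read, from its top-scoring valid hit.

    Monotone by construction of the rule table: improving both fractions can
    only keep the rank or deepen it.
    """
    if not config.rules:
        raise ConfigError("TL configuration has no rules")
    idf = best.identity_fraction
    pof = best.positive_fraction
    for rule in config.rules:
        if rule.matches(idf, pof):
            return rule.restriction_rank
    return config.fallback_rank


def substitute_at_tl(
    tree: TaxonomyTree,
    rhs: ReadHitSet,
    tl: str,
) -> list[tuple[AlignmentHit, int]]:
    """Replace every hit taxon by its ancestor at rank ``tl``.

    A lineage lacking the TL rank is projected onto its nearest canonical
    ancestor *shallower* than the TL (ultimately the root), so every hit
    yields a node at or above the restriction level.  Hit order is preserved;
    re-applying at the same TL is a no-op.
    """
    if tl not in RANK_INDEX:
        raise ConfigError(f"unknown rank {tl!r}")
    out: list[tuple[AlignmentHit, int]] = []
    for hit in rhs.hits:
        out.append((hit, project_to_rank(tree, hit.subject_taxid, tl)))
    return out


def project_to_rank(tree: TaxonomyTree, taxid: int, tl: str) -> int:
    """Ancestor of ``taxid`` at rank ``tl``, or the nearest shallower canonical
    ancestor when the lineage lacks that rank (root as last resort)."""
    for rank in CANONICAL_RANKS[RANK_INDEX[tl]::-1]:
        anc = tree.ancestor_at_rank(taxid, rank)
        if anc is not None:
            return anc
    return tree.root_id


# -- YAML configuration ----------------------------------------------------


def load_tl_config(source: str | Path | TextIO) -> TLConfig:
    """Read a rule table from YAML.

    Layout::

        fallback_rank: superkingdom
        rules:
          - rank: species
            min_identity_fraction: 0.95
            min_positive_fraction: 0.97
          - rank: genus
            ...

    Rules are kept in file order (most stringent first).
    """
    own = isinstance(source, (str, Path))
    fh = open(source, "rt", encoding="utf-8") if own else source  # type: ignore[arg-type]
    try:
        data = yaml.safe_load(fh)
    finally:
        if own:
            fh.close()
    if not isinstance(data, dict) or "rules" not in data:
        raise ConfigError("TL config must be a mapping with a 'rules' list")
    rules = []
    for entry in data["rules"]:
        try:
            rules.append(TLRule(
                restriction_rank=entry["rank"],
                min_identity_fraction=float(entry["min_identity_fraction"]),
                min_positive_fraction=(
                    float(entry["min_positive_fraction"])
                    if entry.get("min_positive_fraction") is not None else None),
            ))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"bad TL rule {entry!r}: {exc}") from None
    return TLConfig(tuple(rules), data.get("fallback_rank", "superkingdom"))


def dump_tl_config(config: TLConfig, dest: str | Path | TextIO) -> None:
    data = {
        "fallback_rank": config.fallback_rank,
        "rules": [
            {
                "rank": r.restriction_rank,
                "min_identity_fraction": r.min_identity_fraction,
                **({"min_positive_fraction": r.min_positive_fraction}
                   if r.min_positive_fraction is not None else {}),
            }
            for r in config.rules
        ],
    }
    own = isinstance(dest, (str, Path))
    fh = open(dest, "wt", encoding="utf-8") if own else dest  # type: ignore[arg-type]
    try:
        yaml.safe_dump(data, fh, sort_keys=False)
    finally:
        if own:
            fh.close()
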