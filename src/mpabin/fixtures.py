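"""Deterministic synthetic taxonomies and hit tables.

Everything downstream is testable without any database download: this module
builds balanced toy taxonomies with the seven canonical ranks and simulates
per-read BLAST hit tables in which the expected bit-score of a hit decays
linearly with the tree distance between the read's source species and the
hit's subject species.  That linear-decay-plus-Gaussian-noise model is the
simplest one honouring the premise that higher similarity indicates a
taxonomically closer organism; it is synthetic, not biological (no sequences
are ever simulated, and no alignment error model is involved).

Clade-deletion scenarios emulate reads from unknown organisms: under
``species-unknown``/``genus-unknown``/``family-unknown`` every hit falling
inside the source read's species/genus/family clade is omitted, mirroring
reference databases from which the query clade is absent.

Generation is a pure function of the :class:`ScenarioSpec` — the same seed
produces byte-identical output files.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from .hits import AlignmentHit, ReadHitSet, make_read_hit_set
from .taxonomy import CANONICAL_RANKS, TaxonomyTree, build_tree

UNKNOWN_MODES = ("known", "species-unknown", "genus-unknown", "family-unknown")

#: clade rank deleted from the reference under each mode
_DELETED_RANK = {
    "known": None,
    "species-unknown": "species",
    "genus-unknown": "genus",
    "family-unknown": "family",
}


@dataclass(frozen=True)
class BitscoreModel:
    """Linear bit-score decay in tree distance.

    ``mean_bits_at_zero`` is the expected bit-score of a hit against the
    source species itself; every edge of species-to-subject tree distance
    subtracts ``decay_per_edge`` bits; Gaussian noise of s.d. ``noise_sd`` is
    added per hit.  Hits whose sampled bit-score falls below
    ``min_emitted_bits`` are not emitted at all (they would be invisible to
    a thresholded similarity search).
    """

    mean_bits_at_zero: float = 180.0
    decay_per_edge: float = 20.0
    noise_sd: float = 5.0
    min_emitted_bits: float = 35.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete description of one synthetic study condition."""

    seed: int = 0
    n_genera: int = 6
    species_per_genus: int = 3
    reads_per_species: int = 50
    unknown_mode: str = "known"
    bitscore_model: BitscoreModel = field(default_factory=BitscoreModel)
    subjects_per_species: int = 2     # reference proteins per species
    alignment_length: int = 100       # columns, constant across hits

    def __post_init__(self) -> None:
        if self.unknown_mode not in UNKNOWN_MODES:
            raise ValueError(f"unknown_mode must be one of {UNKNOWN_MODES}")
        for name in ("n_genera", "species_per_genus", "reads_per_species",
                     "subjects_per_species", "alignment_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


# identity model: fraction lost per edge of effective distance, floored.
# identities are derived from the *noisy* bit-score so that alignment
# quality and score stay mutually consistent within a hit row.
_IDENTITY_DROP_PER_EDGE = 0.07
_IDENTITY_FLOOR = 0.25
_POSITIVES_BONUS = 0.03


def _identity_fraction(bit: float, model: BitscoreModel) -> float:
    effective_distance = (model.mean_bits_at_zero - bit) / model.decay_per_edge
    return min(1.0, max(_IDENTITY_FLOOR,
                        1.0 - _IDENTITY_DROP_PER_EDGE * effective_distance))


def make_taxonomy(spec: ScenarioSpec) -> TaxonomyTree:
    """Balanced toy taxonomy: root → superkingdom → … → genus → species.

    Genera are grouped pairwise into families, families into orders, orders
    into classes and classes into phyla under a single superkingdom, so every
    species leaf sits at level 7 and sibling clades exist at every rank
    whenever the genus count allows it.
    """
    records: list[tuple[int, int, str, str]] = [(1, 1, "no rank", "root")]
    next_id = 2

    def add(parent: int, rank: str, name: str) -> int:
        nonlocal next_id
        records.append((next_id, parent, rank, name))
        next_id += 1
        return next_id - 1

    n_genera = spec.n_genera
    counts = {"genus": n_genera}
    for child, parent in (("genus", "family"), ("family", "order"),
                          ("order", "class"), ("class", "phylum")):
        counts[parent] = math.ceil(counts[child] / 2)

    sk = add(1, "superkingdom", "superkingdom_1")
    phyla = [add(sk, "phylum", f"phylum_{i + 1}") for i in range(counts["phylum"])]
    classes = [add(phyla[i // 2], "class", f"class_{i + 1}")
               for i in range(counts["class"])]
    orders = [add(classes[i // 2], "order", f"order_{i + 1}")
              for i in range(counts["order"])]
    families = [add(orders[i // 2], "family", f"family_{i + 1}")
                for i in range(counts["family"])]
    genera = [add(families[i // 2], "genus", f"genus_{i + 1}")
              for i in range(n_genera)]
    for gi, genus in enumerate(genera):
        for si in range(spec.species_per_genus):
            add(genus, "species", f"species_{gi + 1}_{si + 1}")
    return build_tree(records)


def species_leaves(tree: TaxonomyTree) -> list[int]:
    return [t for t in sorted(tree.nodes)
            if tree.nodes[t].rank == "species"]


def _deleted_clade(tree: TaxonomyTree, source: int, mode: str) -> int | None:
    rank = _DELETED_RANK[mode]
    if rank is None:
        return None
    return tree.ancestor_at_rank(source, rank)


@dataclass(frozen=True)
class HitTableBundle:
    """In-memory result of one simulated scenario."""

    read_hit_sets: list[ReadHitSet]
    taxid_map: dict[str, int]        # subject_id → taxid
    truth: dict[str, int]            # read_id → source taxid


def make_hit_tables(tree: TaxonomyTree, spec: ScenarioSpec) -> HitTableBundle:
    """Simulate hit tables for every read of every source species.

    Each source species contributes ``reads_per_species`` reads; each read
    gets one hit per reference subject (``subjects_per_species`` per species
    leaf) whose sampled bit-score clears ``min_emitted_bits``.  Under a
    clade-deletion mode, subjects inside the source read's deleted clade are
    skipped entirely.
    """
    rng = random.Random(spec.seed)
    model = spec.bitscore_model
    leaves = species_leaves(tree)
    subjects = {leaf: [f"p{leaf}_{j + 1}" for j in range(spec.subjects_per_species)]
                for leaf in leaves}
    taxid_map = {sid: leaf for leaf, sids in subjects.items() for sid in sids}
    distance = {(a, b): tree.pairwise_distance(a, b)
                for a in leaves for b in leaves}

    read_hit_sets: list[ReadHitSet] = []
    truth: dict[str, int] = {}
    for source in leaves:
        deleted = _deleted_clade(tree, source, spec.unknown_mode)
        refs = [leaf for leaf in leaves
                if deleted is None or not tree.is_ancestor(deleted, leaf)]
        for r in range(spec.reads_per_species):
            read_id = f"r{source:04d}_{r:04d}"
            truth[read_id] = source
            hits: list[AlignmentHit] = []
            for ref in refs:
                d = distance[source, ref]
                for sid in subjects[ref]:
                    bit = round(model.mean_bits_at_zero - model.decay_per_edge * d
                                + rng.gauss(0.0, model.noise_sd), 1)
                    if bit < model.min_emitted_bits:
                        continue
                    frac = _identity_fraction(bit, model)
                    identities = int(round(frac * spec.alignment_length))
                    positives = min(spec.alignment_length,
                                    identities + int(round(
                                        _POSITIVES_BONUS * spec.alignment_length)))
                    # store the e-value exactly as it prints so hit tables
                    # round-trip through the outfmt-6 writer/parser
                    evalue = float(f"{2.0 ** (-bit) * 1e9:.2g}")
                    hits.append(AlignmentHit(
                        query_id=read_id,
                        subject_id=sid,
                        subject_taxid=ref,
                        bit_score=bit,
                        alignment_length=spec.alignment_length,
                        identities=identities,
                        positives=positives,
                        gaps=0,
                        evalue=evalue,
                    ))
            read_hit_sets.append(make_read_hit_set(read_id, hits))
    return HitTableBundle(read_hit_sets, taxid_map, truth)


def make_scenario(spec: ScenarioSpec) -> tuple[TaxonomyTree, HitTableBundle]:
    tree = make_taxonomy(spec)
    return tree, make_hit_tables(tree, spec)


def write_scenario(outdir: str | Path, spec: ScenarioSpec) -> dict[str, Path]:
    """Emit taxonomy.tsv, hits.tsv, taxid_map.tsv and truth.tsv into ``outdir``."""
    from .evaluate import write_truth
    from .hits import write_blast_tabular, write_taxid_map
    from .taxonomy import write_taxonomy_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree, bundle = make_scenario(spec)
    paths = {
        "taxonomy": outdir / "taxonomy.tsv",
        "hits": outdir / "hits.tsv",
        "taxid_map": outdir / "taxid_map.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_taxonomy_tsv(tree, paths["taxonomy"])
    write_blast_tabular(bundle.read_hit_sets, paths["hits"], positives_col=True)
    write_taxid_map(bundle.taxid_map, paths["taxid_map"])
    write_truth(bundle.truth, paths["truth"])
    return paths


# -- engineered single-read showcase ---------------------------------------


def make_stray_hit_scenario() -> tuple[TaxonomyTree, ReadHitSet, int]:
    """One read whose hit list contains strong within-genus hits plus two
    high-scoring *stray* hits from a distant class.

    The plain LCA of all hits collapses to the phylum, while the
    bit-score/distance scoring keeps the assignment at the source genus —
    the situation in which ratio scoring improves specificity over the
    conservative LCA.  Returns ``(tree, read, true_taxid)``.
    """
    spec = ScenarioSpec(n_genera=12, species_per_genus=3, reads_per_species=1)
    tree = make_taxonomy(spec)
    leaves = species_leaves(tree)
    source = leaves[0]                       # species_1_1, under genus_1/class_1
    genus = tree.ancestor_at_rank(source, "genus")
    siblings = [t for t in leaves
                if tree.ancestor_at_rank(t, "genus") == genus and t != source]
    stray_class = [t for t in leaves
                   if tree.ancestor_at_rank(t, "class")
                   != tree.ancestor_at_rank(source, "class")]
    model = BitscoreModel()

    def hit(sid: str, taxid: int, bit: float) -> AlignmentHit:
        frac = _identity_fraction(bit, model)
        identities = int(round(frac * 100))
        return AlignmentHit(
            query_id="stray_read", subject_id=sid, subject_taxid=taxid,
            bit_score=bit, alignment_length=100, identities=identities,
            positives=min(100, identities + 3), evalue=1e-40,
        )

    hit_list = [hit(f"p{source}_1", source, 180.0)]
    hit_list += [hit(f"p{t}_{i + 1}", t, 150.0)
                 for i, t in enumerate(siblings * 2)]
    hit_list += [hit(f"p{t}_9", t, 120.0) for t in stray_class[:2]]
    return tree, make_read_hit_set("stray_read", hit_list), source


def make_random_tree(seed: int, n_nodes: int) -> TaxonomyTree:
    """Random rooted tree for oracle tests (distances, LCA).

    Each new node attaches to a uniformly chosen existing node; ranks cycle
    through the canonical list with occasional ``no rank`` insertions, so the
    tree exercises non-canonical nodes without promising rank consistency.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    rng = random.Random(seed)
    records: list[tuple[int, int, str, str]] = [(1, 1, "no rank", "root")]
    for i in range(2, n_nodes + 1):
        parent = rng.randint(1, i - 1)
        rank = ("no rank" if rng.random() < 0.25
                else rng.choice(CANONICAL_RANKS))
        records.append((i, parent, rank, f"node_{i}"))
    return build_tree(records)
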