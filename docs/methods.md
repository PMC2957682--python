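# Methods

## Problem and model

`mpabin` performs similarity-based taxonomic binning: each metagenomic read,
represented by its BLAST tabular hits against a protein reference, is
assigned to a node of an NCBI-style taxonomy. The central difficulty is that
most reads in an environmental sample originate from organisms absent from
the reference, so the best hit is frequently in the wrong clade and the naive
lowest-common-ancestor (LCA) of all hits is either over-specific (when hits
are clustered in one wrong clade) or uselessly shallow (when one stray hit
drags the LCA toward the root).

The pipeline has four stages:

1. **Hit validity.** A hit counts only if its bit-score is ≥ 35 bits *and*
   its alignment spans more than 25 columns. A read with rows but no valid
   hit is *Unassigned*; a read with no rows at all is *NoHits*. The
   thresholds are configurable (`--min-bit-score`, `--min-alignment-length`);
   the conjunctive reading of the two conditions is deliberate — it is the
   stricter interpretation and minimises false assignment.

2. **Taxonomic-level (TL) restriction.** The identity and positive fractions
   of the best valid hit select the deepest rank the assignment may reach,
   through an ordered rule table (first match wins, most stringent rule
   first). Every hit taxon is then substituted by its ancestor at the TL, so
   whatever happens later, the final node lies at the TL or above it. The
   shipped thresholds (species 0.95/0.97 → phylum 0.35/0.37, fallback
   superkingdom; fractions are relative to the full alignment length, gap
   columns included) are **calibration defaults**, not published constants:
   they are chosen so that rank depth degrades smoothly with alignment
   quality, they are overridable from YAML (`--tl-config`), and no parity
   with any external tool's internal thresholds is claimed. When the input
   lacks a positives column the identity thresholds alone decide. A lineage
   that lacks the TL rank is projected onto its nearest shallower canonical
   ancestor, which preserves the at-or-above-TL guarantee.

3. **Most Probable Ancestor (MPA).** For reads with ≥ 3 valid hits,
   candidate ancestors are the successive values of the running LCA over
   score-ordered prefixes of the substituted taxa (top-2, top-3, … all) —
   a strictly root-ward chain from the LCA of the top two hits down to the
   LCA of everything. Each candidate *c* is scored

       S(c) = Σ_h  bit(h) / (d(c, taxon(h)) + 1)

   where *d* is the edge distance through the taxonomy (levels are raw edge
   counts from the root, non-canonical nodes included). The read is assigned
   to the argmax; ties go to the deeper candidate, since specificity is the
   point of the scoring step. Reads with one valid hit take that hit's
   substituted taxon; with two, the LCA of the two substituted taxa.

   *The +1 offset.* The bit/distance ratio is undefined at distance zero,
   which necessarily occurs whenever a candidate coincides with a hit taxon
   (typical for the first candidate). All denominators are offset by one
   uniformly: the ordering intent — nearer taxa contribute more — is
   preserved with no special case. Multiple hits into the same taxon all
   contribute; collapsing them would discard evidence of local hit density.

4. **Isolated-taxon reclassification.** After all reads are assigned, taxa
   whose *direct* read count is below the Isolated Taxon Size —
   `min(300, ⌈1% of total reads⌉)`, floored at 1 — are dissolved: their reads
   move to the first ancestor (parent upward, stopping at the superkingdom)
   whose *cumulative* subtree count exceeds the threshold, and become
   Unassigned only if no ancestor qualifies. The absolute cap of 300 exists
   so that genuinely rare organisms are not dissolved: 300 reads of
   100–1000 bp correspond to 0.05X–0.5X coverage of a 0.6 Mb genome
   (`evaluate.coverage` reproduces this arithmetic). The direct/cumulative
   split follows the most literal reading of the procedure ("number of reads
   assigned" for isolation, "cumulative number" for acceptance), and both
   comparisons are strict (`< size` isolated, `> size` acceptable).

   Cumulative counts are computed on the pre-pass table and **frozen** for
   the pass, making the result independent of processing order. Whether
   promoted reads should feed later acceptance tests is genuinely open; the
   frozen single pass is the default because it is deterministic, and
   `--iterate` repeats passes to a fixed point (bounded by the tree depth)
   for the cascading interpretation. "Immediate ancestor" means the parent
   edge including non-canonical nodes, consistent with the edge-count level
   definition. Assignment *at* the superkingdom is permitted; promotion
   above it is not.

## Evaluation semantics

Against a truth table, an assignment is **Correct** when the assigned node
lies on the root-to-source path (ancestor-or-self of the true taxon), else
**Wrong**; Unassigned and NoHits are their own categories, so the four
percentages always total 100. Correct assignments are tiered **Higher**
(root / `cellular organisms` / superkingdom), **Intermediate**
(phylum–order) or **Specific** (family and deeper). Nodes with non-canonical
ranks (species complexes, strains) inherit the tier of their nearest
canonical ancestor — the tiers are defined over canonical ranks, yet real
correct paths contain such nodes.

A plain-LCA baseline (`plain_lca_assign`: LCA of the raw taxa of all valid
hits, no TL, no scoring) is included strictly for qualitative comparison.

## The synthetic-data generator

No real reference database is practical in tests, so `fixtures` generates
complete toy studies:

* **Taxonomy** — a balanced tree with exactly the seven canonical ranks,
  genera paired into families, families into orders, and so on under one
  superkingdom; every species leaf sits at level 7.
* **Hit tables** — each source species emits reads; each read receives one
  hit per reference protein (2 per species by default) with bit-score
  `180 − 20·d + N(0, 5²)` bits, where `d` is the species-to-subject tree
  distance, truncated below 35 bits (invisible to a thresholded search).
  Identity fractions are derived from the sampled bit-score
  (`1 − 0.07·(180 − bit)/20`, floored at 0.25) and positives sit 3 points
  above identities, so alignment quality and score stay mutually consistent
  within a row. Alignments are a constant 100 columns.
* **Clade deletion** — `species-unknown` / `genus-unknown` /
  `family-unknown` omit every hit inside the source read's species / genus /
  family, emulating reads from organisms missing from the reference at the
  corresponding depth.
* Default study size: 6 genera × 3 species × 50 reads (900 reads, 18
  reference species). Generation is a pure function of the `ScenarioSpec`;
  a seed reproduces files byte-for-byte.

The linear-decay score model is the simplest one honouring the premise that
higher similarity implies a taxonomically closer source. What it does *not*
emulate: sequence content and alignment error models, horizontal gene
transfer, contaminated references, uneven taxon sampling, variable alignment
lengths, and the long-tailed score distributions of real searches. Passing
tests therefore demonstrate the *algorithmic* contracts (chain structure,
distance arithmetic, conservation, recovery under the stated noise model),
not field accuracy on real data.

## Numerical and design choices

* Distances and levels are integers; no floating-point issues arise in the
  tree arithmetic. Ratio sums are floats; the argmax scan keeps the first
  (deepest) maximum, so exact ties resolve deterministically.
* Hit ordering is total: descending bit-score, then ascending subject taxid,
  then input order — parsing is insensitive to row shuffles.
* Unknown subject taxids in hit files are skipped with a logged count rather
  than failing the run (stale mappings are routine); structural taxonomy
  errors (cycles, dangling parents, duplicate ids) are fatal.
* Fold coverage is reported with half-up rounding to two decimals (0.125X
  prints as 0.13X, the printed convention).
* The coarse-grained problem sizes used by the test-suite and the acceptance
  script (up to ~10⁴ simulated reads, random oracle trees up to 200 nodes,
  five seeds per statistical comparison) are the package's own choice of a
  desk-scale study; all of them are parameters of the public API and scale
  up unchanged.
* The noisy condition used to demonstrate the reclassification effect raises
  the score noise to 15 bits s.d. (species-unknown deletion): under the
  default 5-bit noise the pipeline makes essentially no wrong assignments on
  the toy geometry, leaving the reclassification step nothing to show.

## Known limitations

* Merged/deleted taxid handling (`merged.dmp`) is not implemented; inputs
  are expected to reference live taxids, and unknown ones are skipped.
* The TL rule table is a calibration surface: on real data it should be
  re-fit against alignments of known provenance before any accuracy claim.
* The reclassification threshold treats all taxa equally; genome length or
  marker density are not modelled beyond the rationale for the 300-read cap.
* Single-machine, in-memory processing: roughly a million reads in a few GB;
  no streaming/cluster mode.
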