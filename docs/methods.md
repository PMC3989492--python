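# Methods

This note documents the models and procedures implemented in `primerforge`, the
parameters that matter, the numerical and design choices made where the problem
was genuinely open, what the synthetic-data generator does and does not emulate,
and known limitations.

## Window scan and consensus

The scan slides a `width`-nt window (default 15 nt — the lower bound of typical
16S primer lengths — step 1 nt) across a multiple sequence alignment of
full-length prokaryotic 16S rRNA genes. Within a window, the **frequency** of an
observed slice *s* is the number of member slices at Hamming distance ≤
`max_mm` (default 1) from *s*; the **consensus** is the observed slice with the
highest frequency. Only observed slices compete — candidates are never drawn
from the 5^15 possible strings. The alignment gap `-` is a fifth symbol, so
gap-containing slices participate in counting; a window whose consensus
contains a gap (or an ambiguity code) can never become a primer and is dropped
at selection.

Numerical conventions:

* **Tie-break.** Equal-frequency consensi resolve lexicographically with `-`
  ordered before `A` (plain ASCII). Determinism matters more than the
  particular choice; the choice is visible in output tables.
* **Ambiguity codes** mismatch every symbol, including themselves, for all
  distance computations, and are excluded (with renormalization) from entropy
  distributions. This is deliberately conservative: no expansion semantics are
  invented for counting.
* **Variability** is the per-column entropy of the empirical 5-symbol
  distribution, summed over the window, in bits. The default is Shannon
  entropy (0 = fully conserved, upper bound `width·log2 5`); relative entropy
  against the uniform 5-symbol background is available via
  `method="kl_uniform"` for users who prefer a divergence-style score. The two
  are affinely related per column, so rankings of fully-populated columns
  agree.
* **Coordinates** are 1-based, inclusive, in the ungapped numbering of a
  designated reference row (conventionally *E. coli*, the community-standard
  16S coordinate system). Columns where the reference has a gap inherit the
  nearest preceding base position; columns before the first reference base map
  to 0 and are flagged, and flagged windows never become candidates.

**Candidate selection** keeps windows whose consensus is a synthesizable oligo
(pure ACGT) and whose coverage is at least `min_coverage` (default 90%) in at
least `min_phylum_fraction` (default 0.9) of the phyla present. The defaults
operationalize "conserved in almost all phyla"; both knobs are exposed and
recorded in outputs because no sharp rule exists for "almost all". A
position-based keep interval on the reference coordinate (default [30, 1200])
drops terminal candidates: the 16S termini are missing from many database
records, and 3'-distal sites exceed amplicon read reach.

## Probe matching and coverage

A primer matches a template "within *k* mismatches" when some same-length
substring of the template has Hamming distance ≤ *k* (no indels — the
probe-match convention; PCR mismatch tolerance is usually discussed in
substitutions). Forward primers are matched on the sense strand; reverse
primers via their reverse complement, the standard PCR geometry. Reference
sequences are assumed sense-stranded; this convention is fixed and documented
rather than searching both strands.

Two metrics:

* **Per-sequence coverage** — fraction of a group's sequences with a site
  within the allowance. Used for chloroplast/mitochondrion/eukaryote sets at
  ≤ 2 mismatches, because ≥ 3 primer–template mismatches are assumed to
  prevent amplification.
* **Genus-majority coverage** — fraction of genera in a phylum in which a
  *strict* majority of member sequences match (exactly half does not count).
  Used for prokaryotic sets at ≤ 1 mismatch. The genus granularity buffers the
  extremely uneven per-genus sampling of public rRNA databases; species labels
  are too unreliable in environmental entries to use.

The **eukaryote-exclusion rule** removes a candidate when its per-sequence
coverage within 2 mismatches exceeds 50% in the mitochondrial *or* the
eukaryotic set; exactly 50% is kept ("more than half" is strict). Chloroplast
coverage is reported but not used for exclusion — in practice no 16S-universal
candidate avoids chloroplast rRNA, and excluding on it would empty the
candidate list.

## Candidate merging and pairing

Runs of selected windows at consecutive reference positions whose consensi
agree on every overlap merge into one longer candidate (a run of *k* windows of
width *w* gives a *w+k−1*-mer). Longer oligos reduce random non-specific
priming, but merging must not silently sacrifice taxa, so a merge is accepted
only when, for every phylum, the merged candidate's coverage is at least the
*minimum* over its constituent windows minus `tolerance` (default 0). The
min-based floor is the weakest reading of "maintain coverage" that still
forbids degradation. When a run fails, it splits greedily left-to-right into
the longest acceptable prefixes; overlap disagreements split runs without
error.

Published degenerate primers are made comparable by expanding all IUPAC
variants (capped at 1024 by default; the cap is a safety valve, not a limit of
the method) and keeping the variant with the highest mean per-phylum
genus-majority coverage, ties resolving to the lexicographically smallest
variant. The full per-variant report is returned so any other objective can be
audited.

Candidates are stored in **sense-strand orientation**; the synthesizable
reverse oligo is a derived reverse complement. This single-representation rule
prevents silent double-complementing as candidates move between roles.
Pairing enumerates forward × reverse combinations whose amplicon span
(reverse end − forward start + 1) lies in `[min_span, max_span]` (defaults
350–550 nt: long enough for accurate taxonomic assignment, short enough for a
single long-amplicon read) and contains a non-empty insert, ranked by mean
prokaryotic coverage, then span, then coordinates — stable under input
permutation.

## Read processing

Long amplicon reads are removed when they contain any non-ACGT base, fall
outside the experiment's length window, or have arithmetic mean Phred quality
strictly below 20 (a mean of exactly 20 is kept; reads without qualities are
"unscorable" and removed separately). The removal report counts each read once
under the first rule it trips, in fixed order (ambiguity, length, quality), so
counts always partition the input. Filtering precedes trimming.

Primer trimming is a bounded-mismatch terminal search: the forward oligo is
sought within the first 30 nt (≤ 2 mismatches) of the read or of its reverse
complement — reads found on the antisense strand are flipped first, so all
surviving reads start on the sense strand — then the reverse oligo's reverse
complement is excised from the tail when present. Reads with no forward site
are dropped. This replaces alignment-based trimmers (cross-match-style): for
full-length primer remnants at read termini the bounded search is functionally
equivalent, parameter-transparent, and dependency-free.

Short read pairs are removed when either mate failed purity filtering or
carries more than one base at Phred value 2 within its first 60 cycles —
quality 2 being the read-segment quality indicator ("B" flag) of that pipeline
generation; the numeric value is configurable.

## Taxonomic assignment

Hits arrive as standard 12-column blast tabular rows plus a subject-metadata
table (lineage, gene class); the similarity search itself is external — it is
infrastructure, not the method. Filtering is exact to the printed conventions:
e-value strictly `<` threshold, alignment length `≥` threshold. Assignment runs
at two *independent* identity tiers — genus ≥ 94%, phylum ≥ 85% — so a read can
be phylum-assigned yet genus-unassigned; a genus-unassigned read never inherits
a genus from phylum-tier hits. Within a tier, the read's unit weight splits as
1/n over the n hits tied at the best bit score; tied hits in the same taxon
accumulate. Every assigned read therefore contributes exactly 1 across taxa,
and profiles are additive over read batches.

A read pair contributes one unit (not two) when both mates resolve to the same
single taxon among SSU-rRNA best hits and their best-hit strands are
*opposite* — paired ends face each other on the template. "Consistent alignment
direction" admits a same-strand reading for other chemistries, so the strand
rule is a flag (`require_opposite_strands`). Inter-mate distance is ignored:
16S genes in some taxa carry long insertions.

Profiles compare by Spearman rank correlation over the union of taxa (absent
taxa as 0, average ranks for ties, via `scipy.stats.spearmanr`); fewer than
three taxa is an error because the statistic is meaningless there. Rank
abundance uses competition ranking (ties share the smaller rank; the next rank
is skipped).

## Synthetic data: what it emulates, and what passing tests show

The generator emulates every pipeline input at desk scale. The default
community — the study condition for the end-to-end test — has 20 prokaryote
taxa (5 phyla × 4 genera, one record each, geometric abundances with ratio
0.85), 5 eukaryote and 5 mitochondrion reference taxa, 900-nt templates
(enough to span the forward/reverse motif coordinates at realistic scan cost),
i.i.d. backgrounds at GC 0.5, 10% prokaryote and 25% eukaryote per-site
background divergence from a common template. Three motifs are planted: the
16-nt forward motif at *E. coli* position 342, the 17-nt reverse motif at 790
(sense strand), and a 15-nt broad-range decoy at 600.

Construction guarantees, enforced rather than sampled:

* prokaryote members carry each motif within `prok_max_mm` (default 0)
  mismatches;
* eukaryote-like members are at least `euk_min_mm` (default 3) mismatches from
  the exclusion-safe motifs at *every* offset of their final sequence — a
  post-construction probe-match scan mutates any chance background site,
  which matters for low-complexity motifs that can resurface by chance;
* the decoy is planted into eukaryote-like members within `euk_max_mm`
  (default 2) mismatches, so the exclusion filter has a true positive;
* each motif is flanked by insertion columns carrying bases only in
  eukaryote-like rows (gaps in all prokaryote rows, the reference included).
  Conserved rRNA stems abutting variable-length regions is the natural
  alignment geometry, and it pins candidate boundaries: with one mismatch
  allowed, a window overhanging a conserved region by a single position would
  otherwise always pass selection, making exact coordinate recovery
  ill-defined.

Reads are sense-strand amplicons (forward oligo + template insert + reverse
complement of the reverse oligo) with i.i.d. substitution errors, random
orientation flips, and Phred+33 qualities; configurable disjoint read fractions
violate each QC rule so filter reports have exact expectations. Hit tables
encode each read's true taxon, with optional forced bit-score ties (partner
genera chosen by deterministic rotation) and reduced-identity tops that land
between the genus and phylum thresholds. All generators are pure functions of
(spec, seed).

Not emulated: rRNA secondary structure, covariation, indel and homopolymer
sequencing errors, chimeras (an exclusion list of read ids is accepted
instead), barcodes, and flowgram artefacts. Passing tests therefore
demonstrate the correctness of the algorithms and their boundary semantics on
data satisfying the stated guarantees — not primer performance on real
communities, where alignment quality, taxon sampling and amplification
chemistry dominate.

## Degenerate inputs and edge cases

Empty slice lists, empty profiles, alignments shorter than the window, missing
reference rows and mismatched quality lengths raise immediately with specific
messages. Empty reference groups are omitted from coverage tables (a warning,
not an error); an empty admissible pair list returns empty with a diagnostic.
Malformed hit rows are skipped and counted, never silently dropped.

## Known limitations

* No thermodynamic screening (melting temperature, hairpins, dimers): the
  selection criterion is sequence conservation only.
* Mismatch counting is ungapped; a primer site interrupted by an indel is
  scored as mismatches, which can understate coverage for taxa with insertions
  inside the primer region.
* Genus-majority coverage inherits the taxonomy attached to the references;
  misannotated lineages propagate directly.
* The homopolymer curation cutoff (single-base runs longer than 14 nt) is a
  conservative default for flagging pathological database records, exposed as
  a parameter rather than asserted as a standard.
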