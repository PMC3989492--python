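# primerforge

Design and evaluation of **non-degenerate universal primers for prokaryotic 16S
rRNA genes**, plus the downstream read processing and taxonomic profiling needed
to validate such primers on amplicon and shotgun sequencing data.

Universal 16S primers are the workhorse of culture-independent microbial
community profiling, but many published primers also anneal to eukaryotic 18S
and organelle small-subunit rRNA genes. In host-associated or plant-rich
samples this wastes sequencing throughput and distorts the inferred community.
`primerforge` implements the complete desk workflow for finding primers that
cover bacterial *and* archaeal 16S genes while excluding eukaryotic and
mitochondrial rRNA, for users who design or audit amplicon assays:
microbial-ecology and microbiome researchers working in Python.

## What it computes

* **Window scan** (`primerforge.window_scan`) — a 15-nt window slides (step 1)
  across a taxonomically labelled multiple sequence alignment of full-length
  16S genes. For each window the *consensus* is the observed 15-mer that the
  most member slices fall within one mismatch of (gaps count as a fifth
  symbol), per-phylum coverage is the percentage of members within the
  allowance, and sequence variability is the summed per-site entropy over
  {A,C,G,T,−}. Coordinates are reported in standard *E. coli* 16S numbering
  via a designated reference row.
* **Probe matching** (`primerforge.probe_match`) — ungapped sliding comparison
  of a primer (forward, or reverse via reverse complement) against every
  same-length substring of each reference sequence. Two coverage metrics:
  per-sequence coverage (fraction of sequences with a site within *k*
  mismatches) and genus-majority coverage (fraction of genera in a phylum in
  which a strict majority of members match within *k*). Candidates covering
  more than 50% of mitochondrial or eukaryotic references within two
  mismatches are excluded — three or more mismatches are assumed to prevent
  amplification.
* **Primer assembly** (`primerforge.primer_design`) — neighbouring candidate
  windows that agree on their overlap merge into longer concrete primers while
  maintaining per-phylum coverage; IUPAC-degenerate published primers resolve
  to their best-covering concrete variant; forward/reverse candidates pair
  under amplicon-span constraints and rank by prokaryotic coverage.
* **Read QC** (`primerforge.read_qc`) — amplicon-read filters (ambiguity,
  length window, mean Phred < 20), bounded-mismatch primer trimming with
  sense-strand orientation normalization, and paired short-read filters
  (purity flag, early-cycle quality-2 "B" bases).
* **Taxonomic assignment** (`primerforge.taxo_assign`) — 12-column tabular
  similarity hits are filtered (e-value strictly below threshold, alignment
  length at least threshold) and each read's unit weight is split equally
  across hits tied at the best bit score, independently at a genus tier
  (identity ≥ 94%) and a phylum tier (≥ 85%). Read pairs count once, and only
  when both mates agree on the taxon with consistent alignment directions.
  Profiles compare by Spearman rank correlation and competition-rank
  abundance curves.
* **Synthetic data** (`primerforge.synthetic_data`) — labelled alignments with
  conserved motifs planted at known coordinates, diverged eukaryote/organelle
  reference sets, mock amplicon reads and read pairs with qualities, and mock
  hit tables with exact ground truth, so the entire pipeline runs with no
  external databases.

## Worked example

Generate a synthetic community (20 prokaryote taxa across 5 phyla plus 10
eukaryote-like reference sequences, with conserved regions planted at *E. coli*
positions 342 and 790 and a broad-range decoy at 600) and run the full
discovery pipeline:

```console
$ primerforge synth --seed 7 --out community
community with 31 records -> community/
$ primerforge design community/alignment.fasta community/taxonomy.tsv \
      --reference-id REF --origins community/origins.tsv
top pair 342F-790R: CTACGGGGGGCAGCAG / AGATACCCCGGTAGTCC (amplicon 465 nt)
```

The scan finds the conserved windows, merges the neighbouring windows at
342/343 into the 16-nt forward primer `CTACGGGGGGCAGCAG` (*E. coli* 342–357)
and the windows at 790–792 into the 17-nt reverse candidate spanning 790–806
(emitted as its reverse-complement oligo `AGATACCCCGGTAGTCC`); the decoy at
600, which matches the eukaryote-like references within two mismatches, is
removed by the exclusion filter. The amplicon spans 465 nt — inside the usable
read length of long-amplicon platforms. `design.candidates.tsv` and
`design.pairs.tsv` hold the full tables; the pair table reports 100.0
genus-majority coverage for both primers in this community.

The same operations are available as a library:

```python
from primerforge.synthetic_data import default_community_spec, generate_alignment
from primerforge.pipeline import design_primer_pairs

community = generate_alignment(default_community_spec(seed=7))
refs = community.references_by_origin()
result = design_primer_pairs(
    community.prokaryote_alignment(), reference_id="REF",
    prok_records=community.prokaryote_records(),
    mito_records=refs["mitochondrion"], euk_records=refs["eukaryote"],
)
print(result.top_pair.forward.oligo, result.top_pair.reverse.oligo)
```

## Layout

```
src/primerforge/      library modules (seqio, window_scan, probe_match,
                      primer_design, read_qc, taxo_assign, synthetic_data,
                      pipeline, cli)
tests/                pytest suite (unit, property and end-to-end tests)
docs/methods.md       models, parameters, numerical choices and limitations
scripts/acceptance.py worked-example reproduction script
```
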