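"""Synthetic communities, reference sets, reads and hit tables for the pipeline.

Every input the primer-discovery and profiling pipeline consumes can be generated
here with no download: a taxonomically labelled rRNA-like alignment with conserved
motifs planted at known reference coordinates (exact in prokaryote taxa, forced to
diverge in eukaryote-like taxa so the exclusion machinery has something to act on),
mock amplicon reads and short read pairs with Phred qualities, and mock similarity
hit tables whose identities/bit scores encode each read's true source taxon.

All generators are pure functions of (spec, seed): the same spec and seed give
byte-identical output.  Backgrounds are i.i.d. nucleotides with configurable GC;
there is no secondary-structure or indel-error realism - none of the operations
under test depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from primerforge.primer_design import PrimerPair
from primerforge.probe_match import best_site
from primerforge.read_qc import Read, ReadPair
from primerforge.seqio import GAP, AlignedRecord, Alignment, Lineage, SeqRecord, reverse_complement
from primerforge.taxo_assign import AlignmentHit, SubjectMeta

BASES = np.array(list("ACGT"))
PROK_ORIGINS = ("bacteria", "archaea")
EUK_LIKE_ORIGINS = ("eukaryote", "mitochondrion", "chloroplast")

#: the worked-example universal primer pair planted by the default community:
#: forward at E. coli 342-357, reverse (sense strand) at 790-806
FORWARD_MOTIF = "CTACGGGGGGCAGCAG"
REVERSE_MOTIF = "GGACTACCGGGGTATCT"
#: a broad-range decoy conserved in eukaryote-like sets too (planted within
#: 2 mismatches there), so the exclusion filter has a true positive to remove
DECOY_MOTIF = "GTGCCAGCAGCCGCG"


@dataclass
class TaxonSpec:
    phylum: str
    genus: str
    abundance: float = 0.0
    origin: str = "bacteria"
    domain: Optional[str] = None

    @property
    def record_id(self) -> str:
        return f"{self.origin[:3]}_{self.phylum}_{self.genus}"

    @property
    def lineage(self) -> Lineage:
        domain = self.domain or (
            "Archaea" if self.origin == "archaea"
            else "Bacteria" if self.origin == "bacteria"
            else "Eukaryota"
        )
        return Lineage(domain=domain, phylum=self.phylum, genus=self.genus,
                       species=f"{self.genus} sp.")


@dataclass
class PlantedMotif:
    """A motif planted at a 1-based ungapped reference position.

    ``prok_max_mm`` bounds the divergence planted into each prokaryote member;
    eukaryote-like members are forced to diverge by at least ``euk_min_mm``
    (exclusion-safe motif) or, when ``euk_max_mm`` is set instead, planted
    within at most that many mismatches (a broad-range decoy).
    """

    ref_pos: int
    sequence: str
    prok_max_mm: int = 0
    euk_min_mm: Optional[int] = 3
    euk_max_mm: Optional[int] = None

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError("planted motifs must be concrete ACGT sequences")
        if (
            self.euk_min_mm is not None
            and self.euk_max_mm is not None
            and self.euk_max_mm < self.euk_min_mm
        ):
            raise ValueError(
                f"contradictory eukaryote divergence bounds for motif at {self.ref_pos}"
            )

    @property
    def end(self) -> int:
        return self.ref_pos + len(self.sequence) - 1


@dataclass
class CommunitySpec:
    """Parameters of a synthetic community and its reference sequence sets."""

    taxa: list[TaxonSpec]
    motifs: list[PlantedMotif] = field(default_factory=list)
    template_length: int = 900
    gc: float = 0.5
    background_divergence: float = 0.10  # prokaryote per-site divergence from template
    euk_divergence: float = 0.25  # eukaryote-like per-site divergence
    n_gap_columns: int = 4
    error_rate: float = 0.0  # read substitution-error rate
    seed: int = 0

    def __post_init__(self) -> None:
        prok_ab = [t.abundance for t in self.taxa if t.origin in PROK_ORIGINS]
        if prok_ab:
            if any(a <= 0 for a in prok_ab):
                raise ValueError("prokaryote taxon abundances must be positive")
            if abs(sum(prok_ab) - 1.0) > 1e-9:
                raise ValueError("prokaryote taxon abundances must sum to 1")
        for motif in self.motifs:
            if motif.ref_pos < 1 or motif.end > self.template_length:
                raise ValueError(
                    f"motif at {motif.ref_pos} falls outside the {self.template_length}-nt template"
                )

    @property
    def prok_taxa(self) -> list[TaxonSpec]:
        return [t for t in self.taxa if t.origin in PROK_ORIGINS]

    @property
    def euk_like_taxa(self) -> list[TaxonSpec]:
        return [t for t in self.taxa if t.origin in EUK_LIKE_ORIGINS]


def default_community_spec(seed: int = 0) -> CommunitySpec:
    """The standard study community: 20 prokaryote taxa over 5 phyla (4 genera each,
    geometric abundances), 5 eukaryote + 5 mitochondrion reference taxa, with the
    worked-example forward/reverse motifs planted at 342/790 and a broad-range decoy
    at 600."""
    phyla = [
        ("Proteobacteria", "bacteria"),
        ("Firmicutes", "bacteria"),
        ("Actinobacteria", "bacteria"),
        ("Bacteroidetes", "bacteria"),
        ("Euryarchaeota", "archaea"),
    ]
    taxa: list[TaxonSpec] = []
    weights = []
    for p, (phylum, origin) in enumerate(phyla):
        for g in range(4):
            taxa.append(TaxonSpec(phylum=phylum, genus=f"{phylum[:4]}_g{g + 1}", origin=origin))
            weights.append(0.85 ** (4 * p + g))
    total = sum(weights)
    for taxon, w in zip(taxa, weights):
        taxon.abundance = w / total
    for i in range(5):
        taxa.append(TaxonSpec(phylum="Ascomycota", genus=f"Euk_g{i + 1}", origin="eukaryote"))
    for i in range(5):
        taxa.append(TaxonSpec(phylum="Metazoa_mt", genus=f"Mito_g{i + 1}", origin="mitochondrion"))
    motifs = [
        PlantedMotif(ref_pos=342, sequence=FORWARD_MOTIF, euk_min_mm=3),
        PlantedMotif(ref_pos=600, sequence=DECOY_MOTIF, euk_min_mm=None, euk_max_mm=2),
        PlantedMotif(ref_pos=790, sequence=REVERSE_MOTIF, euk_min_mm=3),
    ]
    return CommunitySpec(taxa=taxa, motifs=motifs, seed=seed)


@dataclass
class SyntheticCommunity:
    """A generated community: alignment, labels and ungapped member sequences."""

    spec: CommunitySpec
    alignment: Alignment
    taxonomy: dict[str, Lineage]
    origins: dict[str, str]
    template: str
    members: dict[str, str]  # record id -> ungapped sequence

    def references_by_origin(self) -> dict[str, list[SeqRecord]]:
        grouped: dict[str, list[SeqRecord]] = {}
        for rec_id, sequence in self.members.items():
            origin = self.origins[rec_id]
            grouped.setdefault(origin, []).append(
                SeqRecord(id=rec_id, sequence=sequence,
                          lineage=self.taxonomy[rec_id], origin=origin)
            )
        return grouped

    def prokaryote_records(self) -> list[SeqRecord]:
        refs = self.references_by_origin()
        return [rec for origin in PROK_ORIGINS for rec in refs.get(origin, [])]

    def prokaryote_alignment(self) -> Alignment:
        """The bacterial/archaeal rows only - the substrate for the window scan
        (eukaryote and organelle sets enter later, at candidate evaluation)."""
        rows = [
            rec for rec in self.alignment if self.origins[rec.id] in PROK_ORIGINS
        ]
        return Alignment(rows)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=probs)


def _substitute(rng: np.random.Generator, codes: np.ndarray, positions: np.ndarray) -> None:
    """In-place random substitutions (always to a different base)."""
    codes[positions] = (codes[positions] + rng.integers(1, 4, size=len(positions))) % 4


def _motif_footprint(spec: CommunitySpec) -> np.ndarray:
    mask = np.zeros(spec.template_length, dtype=bool)
    for motif in spec.motifs:
        mask[motif.ref_pos - 1 : motif.end] = True
    return mask


def generate_alignment(spec: CommunitySpec) -> SyntheticCommunity:
    """Generate the labelled gapped alignment plus a reference record ``REF``.

    The reference (an E. coli stand-in carrying every motif exactly) anchors the
    coordinate system.  Prokaryote members diverge i.i.d. from the template outside
    motif footprints and by at most ``prok_max_mm`` inside each; eukaryote-like
    members diverge more strongly and have each motif's divergence constraint
    enforced by construction.  A few insertion columns (bases only in
    eukaryote-like rows, gaps elsewhere, including the reference) exercise the
    gapped coordinate mapping.
    """
    rng = np.random.default_rng(spec.seed)
    length = spec.template_length
    template = _random_sequence(rng, length, spec.gc)
    for motif in spec.motifs:
        template[motif.ref_pos - 1 : motif.end] = [
            "ACGT".index(c) for c in motif.sequence
        ]
    footprint = _motif_footprint(spec)
    free_positions = np.flatnonzero(~footprint)

    members: dict[str, np.ndarray] = {}
    taxonomy: dict[str, Lineage] = {}
    origins: dict[str, str] = {}

    ref_id = "REF"
    members[ref_id] = template.copy()
    taxonomy[ref_id] = Lineage(
        domain="Bacteria", phylum="Proteobacteria", genus="Escherichia", species="Escherichia coli"
    )
    origins[ref_id] = "bacteria"

    for taxon in spec.taxa:
        codes = template.copy()
        is_prok = taxon.origin in PROK_ORIGINS
        rate = spec.background_divergence if is_prok else spec.euk_divergence
        hit = free_positions[rng.random(len(free_positions)) < rate]
        _substitute(rng, codes, hit)
        for motif in spec.motifs:
            sites = np.arange(motif.ref_pos - 1, motif.end)
            if is_prok:
                n_mm = int(rng.integers(0, motif.prok_max_mm + 1))
                if n_mm:
                    _substitute(rng, codes, rng.choice(sites, size=n_mm, replace=False))
            elif motif.euk_max_mm is not None:
                codes[sites] = [  # plant the decoy, then at most euk_max_mm substitutions
                    "ACGT".index(c) for c in motif.sequence
                ]
                n_mm = int(rng.integers(0, motif.euk_max_mm + 1))
                if n_mm:
                    _substitute(rng, codes, rng.choice(sites, size=n_mm, replace=False))
            else:
                target = np.array(["ACGT".index(c) for c in motif.sequence])
                while int((codes[sites] != target).sum()) < (motif.euk_min_mm or 0):
                    _substitute(rng, codes, rng.choice(sites, size=1))
        members[taxon.record_id] = codes
        taxonomy[taxon.record_id] = taxon.lineage
        origins[taxon.record_id] = taxon.origin

    # Insertion columns: eukaryote-like rows get a base, everyone else (the
    # reference included) a gap.  Each motif gets one such column on each flank -
    # conserved rRNA stems abut variable-length regions - which also pins the
    # planted candidates exactly: a window straddling a motif boundary spans an
    # all-gap prokaryote column, so its consensus carries a gap and is never a
    # primer candidate.  Further columns land at random non-motif positions.
    euk_ids = [t.record_id for t in spec.euk_like_taxa]
    insert_points: list[int] = []
    for motif in spec.motifs:
        insert_points += [motif.ref_pos - 1, motif.end]
    if spec.n_gap_columns:
        allowed = np.flatnonzero(~footprint)
        insert_points += [
            int(p) for p in rng.choice(allowed, size=spec.n_gap_columns, replace=False)
        ]
    insert_points.sort()

    def to_gapped(rec_id: str, codes: np.ndarray) -> str:
        chars = list("".join(BASES[codes]))
        for point in reversed(insert_points):
            if rec_id in euk_ids:
                chars.insert(point, str(BASES[rng.integers(0, 4)]))
            else:
                chars.insert(point, "-")
        return "".join(chars)

    # draw insertion bases in a fixed record order for determinism
    rows = [
        AlignedRecord(
            id=rec_id,
            gapped_sequence=to_gapped(rec_id, codes),
            lineage=taxonomy[rec_id],
            origin=origins[rec_id],
        )
        for rec_id, codes in members.items()
    ]

    # The >= euk_min_mm guarantee must hold for the probe-match search over the
    # whole final sequence, not just the planted footprint: low-complexity motifs
    # can resurface by chance in the background (or across insertion points).
    # Scan each eukaryote-like row and mutate any offending site until clean.
    guarded = [m for m in spec.motifs if m.euk_min_mm]
    for row in rows:
        if row.origin not in EUK_LIKE_ORIGINS or not guarded:
            continue
        chars = list(row.gapped_sequence)
        base_index = [i for i, c in enumerate(chars) if c != GAP]
        dirty = True
        while dirty:
            dirty = False
            degapped = "".join(c for c in chars if c != GAP)
            for motif in guarded:
                site = best_site(motif.sequence, degapped)
                if site is not None and site[1] < motif.euk_min_mm:
                    pos = site[0] + int(rng.integers(0, len(motif.sequence)))
                    old = "ACGT".index(chars[base_index[pos]])
                    chars[base_index[pos]] = "ACGT"[(old + int(rng.integers(1, 4))) % 4]
                    dirty = True
        row.gapped_sequence = "".join(chars)
    return SyntheticCommunity(
        spec=spec,
        alignment=Alignment(rows),
        taxonomy=taxonomy,
        origins=origins,
        template="".join(BASES[template]),
        members={rec.id: rec.degapped for rec in rows},
    )


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

@dataclass
class ReadTruth:
    phylum: str
    genus: str
    flipped: bool = False
    violation: Optional[str] = None  # short | ambiguous | low_quality
    insert: Optional[str] = None


def _choose_taxa(
    rng: np.random.Generator, spec: CommunitySpec, n: int
) -> list[TaxonSpec]:
    taxa = spec.prok_taxa
    weights = np.array([t.abundance for t in taxa])
    idx = rng.choice(len(taxa), size=n, p=weights / weights.sum())
    return [taxa[i] for i in idx]


def generate_amplicon_reads(
    community: SyntheticCommunity,
    primer_pair: PrimerPair,
    n_reads: int = 500,
    error_rate: Optional[float] = None,
    flip_fraction: float = 0.5,
    frac_short: float = 0.0,
    frac_ambiguous: float = 0.0,
    frac_low_quality: float = 0.0,
    len_min: int = 350,
    seed: Optional[int] = None,
) -> tuple[list[Read], dict[str, ReadTruth]]:
    """Amplicon reads: forward oligo + template insert + revcomp(reverse oligo).

    Substitution errors hit the whole read at *error_rate* (default: the spec's);
    a *flip_fraction* of reads is emitted reverse-complemented.  Disjoint
    configurable fractions of reads are forced to violate each amplicon filter:
    truncated below *len_min*, given an ambiguous base, or given mean quality
    below 20.  The truth table records each read's source taxon, orientation,
    planted violation and the error-free insert.
    """
    spec = community.spec
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    rate = spec.error_rate if error_rate is None else error_rate
    fwd, rev = primer_pair.forward, primer_pair.reverse

    reads: list[Read] = []
    truth: dict[str, ReadTruth] = {}
    n_short = int(round(frac_short * n_reads))
    n_ambig = int(round(frac_ambiguous * n_reads))
    n_lowq = int(round(frac_low_quality * n_reads))
    if n_short + n_ambig + n_lowq > n_reads:
        raise ValueError("violation fractions exceed the read count")

    for i, taxon in enumerate(_choose_taxa(rng, spec, n_reads)):
        member = community.members[taxon.record_id]
        fwd_site = best_site(fwd.sequence, member)
        rev_site = best_site(rev.sequence, member)
        if fwd_site is None or rev_site is None or fwd_site[1] > 2 or rev_site[1] > 2:
            raise ValueError(f"taxon {taxon.record_id} lacks a primer site")
        insert = member[fwd_site[0] + len(fwd) : rev_site[0]]
        # sense-strand amplicon: forward oligo + insert + revcomp(reverse oligo),
        # and revcomp of the reverse oligo is the reverse primer's sense-strand source
        sequence = fwd.oligo + insert + rev.sequence
        chars = np.array(list(sequence))
        errors = np.flatnonzero(rng.random(len(chars)) < rate)
        if len(errors):
            codes = np.searchsorted(BASES, chars[errors])
            chars[errors] = BASES[(codes + rng.integers(1, 4, size=len(errors))) % 4]
        sequence = "".join(chars)

        violation = None
        qualities = list(rng.integers(28, 41, size=len(sequence)))
        if i < n_short:
            violation = "short"
            keep = max(30, len_min - int(rng.integers(20, 100)))
            sequence = sequence[:keep]
            qualities = qualities[:keep]
        elif i < n_short + n_ambig:
            violation = "ambiguous"
            pos = int(rng.integers(0, len(sequence)))
            sequence = sequence[:pos] + "N" + sequence[pos + 1 :]
        elif i < n_short + n_ambig + n_lowq:
            violation = "low_quality"
            qualities = list(rng.integers(5, 15, size=len(sequence)))

        flipped = bool(rng.random() < flip_fraction)
        if flipped:
            sequence = reverse_complement(sequence)
            qualities = qualities[::-1]

        read_id = f"amp_{i:05d}"
        reads.append(Read(id=read_id, sequence=sequence,
                          qualities=[int(q) for q in qualities]))
        truth[read_id] = ReadTruth(
            phylum=taxon.phylum, genus=taxon.genus, flipped=flipped,
            violation=violation, insert=insert,
        )
    return reads, truth


def generate_read_pairs(
    community: SyntheticCommunity,
    n_pairs: int = 200,
    read_length: int = 76,
    fragment_length: int = 200,
    frac_purity_fail: float = 0.0,
    frac_bflag: float = 0.0,
    seed: Optional[int] = None,
) -> tuple[list[ReadPair], dict[str, ReadTruth]]:
    """Paired short reads sampled from prokaryote members, mates on opposite strands.

    Disjoint fractions of pairs are forced to fail purity filtering or to carry two
    quality-2 bases within mate 1's first 60 nt.  Truth is keyed by pair id.
    """
    spec = community.spec
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    n_purity = int(round(frac_purity_fail * n_pairs))
    n_bflag = int(round(frac_bflag * n_pairs))
    if n_purity + n_bflag > n_pairs:
        raise ValueError("violation fractions exceed the pair count")

    pairs: list[ReadPair] = []
    truth: dict[str, ReadTruth] = {}
    for i, taxon in enumerate(_choose_taxa(rng, spec, n_pairs)):
        member = community.members[taxon.record_id]
        start = int(rng.integers(0, max(1, len(member) - fragment_length)))
        fragment = member[start : start + fragment_length]
        seq1 = fragment[:read_length]
        seq2 = reverse_complement(fragment)[:read_length]
        q1 = [int(q) for q in rng.integers(30, 41, size=len(seq1))]
        q2 = [int(q) for q in rng.integers(30, 41, size=len(seq2))]
        purity_ok = i >= n_purity
        if n_purity <= i < n_purity + n_bflag:
            q1[5] = q1[10] = 2
        pair_id = f"pair_{i:05d}"
        pairs.append(
            ReadPair(
                mate1=Read(id=f"{pair_id}/1", sequence=seq1, qualities=q1,
                           platform="sr_pair", mate=1, purity_ok=purity_ok),
                mate2=Read(id=f"{pair_id}/2", sequence=seq2, qualities=q2,
                           platform="sr_pair", mate=2, purity_ok=True),
            )
        )
        truth[pair_id] = ReadTruth(
            phylum=taxon.phylum, genus=taxon.genus,
            violation="purity" if not purity_ok else ("b_flag" if n_purity <= i < n_purity + n_bflag else None),
        )
    return pairs, truth


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------

@dataclass
class HitModel:
    """How mock similarity hits encode read provenance.

    *identity* is the percent identity of true-source hits; *tie_genera* > 1
    splits every read's best score across that many genera (the true genus plus
    deterministic partners); *decoy_identity*, when set, replaces the top-hit
    identity (e.g. 90 leaves reads genus-unassignable yet phylum-assignable);
    *with_worse_hit* adds a lower-bitscore distractor hit.
    """

    identity: float = 99.0
    evalue: float = 1e-50
    bitscore: float = 200.0
    tie_genera: int = 1
    decoy_identity: Optional[float] = None
    with_worse_hit: bool = False


def subject_database(spec: CommunitySpec) -> dict[str, SubjectMeta]:
    """One SSU-rRNA subject per community genus (prokaryote and eukaryote-like)."""
    meta: dict[str, SubjectMeta] = {}
    for taxon in spec.taxa:
        meta[f"SUBJ_{taxon.genus}"] = SubjectMeta(
            phylum=taxon.phylum, genus=taxon.genus, gene_class="SSU_rRNA"
        )
    return meta


def generate_hits(
    truth: dict[str, ReadTruth],
    spec: CommunitySpec,
    model: HitModel = HitModel(),
    alnlen: int = 350,
    mate_strands: tuple[str, str] = ("+", "-"),
    seed: Optional[int] = None,
) -> tuple[dict[str, list[AlignmentHit]], dict[str, SubjectMeta]]:
    """Mock hits per read id; identities/bit scores encode the true source taxon.

    With ``tie_genera=k`` each read receives k equal-bitscore best hits: its true
    genus and k-1 partner genera chosen deterministically by rotation through the
    prokaryote genus list (so tie-splitting arithmetic has an exact expectation).
    """
    rng = np.random.default_rng((spec.seed + 3) if seed is None else seed)
    meta = subject_database(spec)
    prok_genera = [t.genus for t in spec.prok_taxa]
    genus_index = {g: i for i, g in enumerate(prok_genera)}
    genus_to_phylum = {t.genus: t.phylum for t in spec.taxa}

    hits: dict[str, list[AlignmentHit]] = {}
    for read_id, rt in truth.items():
        strand = mate_strands[0]
        if read_id.endswith("/2"):
            strand = mate_strands[1]
        top_identity = model.decoy_identity if model.decoy_identity is not None else model.identity
        read_hits: list[AlignmentHit] = []
        base = genus_index[rt.genus]
        for k in range(model.tie_genera):
            genus = prok_genera[(base + k) % len(prok_genera)]
            read_hits.append(
                AlignmentHit(
                    query_id=read_id,
                    subject_id=f"SUBJ_{genus}",
                    identity=top_identity,
                    alnlen=alnlen,
                    evalue=model.evalue,
                    bitscore=model.bitscore,
                    strand=strand,
                    phylum=genus_to_phylum[genus],
                    genus=genus,
                    gene_class="SSU_rRNA",
                )
            )
        if model.with_worse_hit:
            other = prok_genera[int(rng.integers(0, len(prok_genera)))]
            read_hits.append(
                AlignmentHit(
                    query_id=read_id,
                    subject_id=f"SUBJ_{other}",
                    identity=max(85.0, top_identity - 5.0),
                    alnlen=alnlen,
                    evalue=model.evalue * 1e3,
                    bitscore=model.bitscore * 0.75,
                    strand=strand,
                    phylum=genus_to_phylum[other],
                    genus=other,
                    gene_class="SSU_rRNA",
                )
            )
        hits[read_id] = read_hits
    return hits, meta


def pair_truth_to_mate_truth(truth: dict[str, ReadTruth]) -> dict[str, ReadTruth]:
    """Expand per-pair truth into per-mate truth (``<pair>/1`` and ``<pair>/2``)."""
    mates: dict[str, ReadTruth] = {}
    for pair_id, rt in truth.items():
        mates[f"{pair_id}/1"] = rt
        mates[f"{pair_id}/2"] = rt
    return mates


def expected_profile(truth: dict[str, ReadTruth], rank: str = "genus") -> dict[str, float]:
    """Ground-truth read counts per taxon (for comparison with recovered profiles)."""
    counts: dict[str, float] = {}
    for rt in truth.values():
        taxon = rt.genus if rank == "genus" else rt.phylum
        counts[taxon] = counts.get(taxon, 0.0) + 1.0
    return counts


# ---------------------------------------------------------------------------
# Spec (de)serialization
# ---------------------------------------------------------------------------

def spec_from_yaml(path) -> CommunitySpec:
    """Load a CommunitySpec from a YAML config file."""
    with open(path) as handle:
        data = yaml.safe_load(handle)
    taxa = [TaxonSpec(**t) for t in data.pop("taxa")]
    motifs = [PlantedMotif(**m) for m in data.pop("motifs", [])]
    return CommunitySpec(taxa=taxa, motifs=motifs, **data)


def spec_to_yaml(spec: CommunitySpec, path) -> None:
    data = {
        "taxa": [
            {"phylum": t.phylum, "genus": t.genus, "abundance": t.abundance,
             "origin": t.origin}
            for t in spec.taxa
        ],
        "motifs": [
            {"ref_pos": m.ref_pos, "sequence": m.sequence, "prok_max_mm": m.prok_max_mm,
             "euk_min_mm": m.euk_min_mm, "euk_max_mm": m.euk_max_mm}
            for m in spec.motifs
        ],
        "template_length": spec.template_length,
        "gc": spec.gc,
        "background_divergence": spec.background_divergence,
        "euk_divergence": spec.euk_divergence,
        "n_gap_columns": spec.n_gap_columns,
        "error_rate": spec.error_rate,
        "seed": spec.seed,
    }
    with open(path, "w") as handle:
        yaml.safe_dump(data, handle, sort_keys=False)
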