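"""Sequence, alignment and taxonomy I/O plus reference-set normalization and curation.

Reference rRNA collections (RDP-style 16S sets, organelle/eukaryote SSU sets) arrive as
FASTA plus a tab-separated taxonomy file.  Before any coverage arithmetic the sets are
normalized (U->T, uppercase), stripped of records with ambiguity codes, subsampled to
one record per taxon to reduce taxonomic bias, and curated: unclassified genera,
over-long records (typically mis-annotated 23S genes) and records with extreme
homopolymer runs are removed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

GAP = "-"
UNAMBIGUOUS = frozenset("ACGT")
ORIGINS = ("bacteria", "archaea", "eukaryote", "mitochondrion", "chloroplast")

LINEAGE_RANKS = ("domain", "phylum", "genus", "species")


class MalformedRecordError(ValueError):
    """Raised for records that violate basic well-formedness (e.g. empty sequence)."""


@dataclass(frozen=True)
class Lineage:
    """Partial lineage; any rank may be unknown (None)."""

    domain: Optional[str] = None
    phylum: Optional[str] = None
    genus: Optional[str] = None
    species: Optional[str] = None

    def rank(self, name: str) -> Optional[str]:
        if name not in LINEAGE_RANKS:
            raise ValueError(f"unknown rank {name!r}")
        return getattr(self, name)

    def to_string(self) -> str:
        return ";".join(getattr(self, r) or "" for r in LINEAGE_RANKS)

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        parts = [p.strip() or None for p in text.split(";")]
        parts += [None] * (len(LINEAGE_RANKS) - len(parts))
        return cls(*parts[: len(LINEAGE_RANKS)])


@dataclass
class SeqRecord:
    """An unaligned rRNA gene sequence with optional lineage and origin labels."""

    id: str
    sequence: str
    lineage: Optional[Lineage] = None
    origin: Optional[str] = None
    gene_class: str = "SSU_rRNA"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise MalformedRecordError(f"record {self.id!r} has an empty sequence")


@dataclass
class AlignedRecord:
    """One row of a gapped multiple sequence alignment."""

    id: str
    gapped_sequence: str
    lineage: Optional[Lineage] = None
    origin: Optional[str] = None

    @property
    def degapped(self) -> str:
        return self.gapped_sequence.replace(GAP, "")


class Alignment:
    """A multiple sequence alignment: equal-length gapped rows, unique ids."""

    def __init__(self, records: Sequence[AlignedRecord]):
        records = list(records)
        if not records:
            raise MalformedRecordError("alignment has no records")
        length = len(records[0].gapped_sequence)
        for rec in records:
            if len(rec.gapped_sequence) != length:
                raise MalformedRecordError(
                    f"record {rec.id!r} has gapped length "
                    f"{len(rec.gapped_sequence)}, expected {length}"
                )
            if not rec.degapped:
                raise MalformedRecordError(f"record {rec.id!r} is all gaps")
        self.records = records
        self.length = length
        self._by_id = {rec.id: rec for rec in records}

    def __iter__(self) -> Iterator[AlignedRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, record_id: str) -> AlignedRecord:
        try:
            return self._by_id[record_id]
        except KeyError:
            raise KeyError(f"record {record_id!r} not in alignment") from None


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_taxonomy(path: str | Path) -> dict[str, Lineage]:
    """Read ``id<TAB>domain;phylum;genus;species`` (empty fields allowed)."""
    table: dict[str, Lineage] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            record_id, _, lineage_text = line.partition("\t")
            table[record_id] = Lineage.from_string(lineage_text)
    return table


def write_taxonomy(table: dict[str, Lineage], path: str | Path) -> None:
    with open(path, "w") as handle:
        for record_id, lineage in table.items():
            handle.write(f"{record_id}\t{lineage.to_string()}\n")


def read_fasta(
    path: str | Path,
    taxonomy: Optional[dict[str, Lineage]] = None,
    origins: Optional[dict[str, str]] = None,
) -> list[SeqRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SeqRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                lineage=(taxonomy or {}).get(rec.id),
                origin=(origins or {}).get(rec.id),
            )
        )
    return records


def write_fasta(records: Iterable[SeqRecord | AlignedRecord], path: str | Path) -> None:
    bio = []
    for rec in records:
        seq = rec.gapped_sequence if isinstance(rec, AlignedRecord) else rec.sequence
        bio.append(_BioRecord(Seq(seq), id=rec.id, description=""))
    SeqIO.write(bio, str(path), "fasta")


def read_alignment(
    path: str | Path,
    taxonomy: Optional[dict[str, Lineage]] = None,
    origins: Optional[dict[str, str]] = None,
) -> Alignment:
    rows = [
        AlignedRecord(
            id=rec.id,
            gapped_sequence=str(rec.seq).upper(),
            lineage=(taxonomy or {}).get(rec.id),
            origin=(origins or {}).get(rec.id),
        )
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return Alignment(rows)


# ---------------------------------------------------------------------------
# Normalization and curation
# ---------------------------------------------------------------------------

def normalize_rrna(record: SeqRecord) -> SeqRecord:
    """Uppercase the sequence and convert RNA uracil to DNA thymine.

    No other characters are altered; ambiguity codes pass through untouched
    (they are handled by :func:`discard_ambiguous`).
    """
    if not record.sequence:
        raise MalformedRecordError(f"record {record.id!r} has an empty sequence")
    return replace(record, sequence=record.sequence.upper().replace("U", "T"))


def discard_ambiguous(records: Iterable[SeqRecord]) -> list[SeqRecord]:
    """Keep only records whose sequences are entirely over {A,C,G,T}."""
    return [rec for rec in records if set(rec.sequence) <= UNAMBIGUOUS]


@dataclass
class SubsampleReport:
    rank: str
    n_input: int = 0
    n_kept: int = 0
    n_missing_rank: int = 0


def subsample_one_per_taxon(
    records: Sequence[SeqRecord],
    rank: str,
    seed: int,
) -> tuple[list[SeqRecord], SubsampleReport]:
    """Randomly keep exactly one record per distinct value of *rank*.

    Selection is uniform within each taxon and deterministic for a fixed seed.
    Records with the rank unpopulated are dropped and counted in the report.
    Output preserves the order of first appearance of each taxon, so an input
    already unique at the rank is returned unchanged.
    """
    if rank not in ("species", "genus"):
        raise ValueError(f"subsampling rank must be species or genus, got {rank!r}")
    report = SubsampleReport(rank=rank, n_input=len(records))
    groups: dict[str, list[SeqRecord]] = {}
    for rec in records:
        value = rec.lineage.rank(rank) if rec.lineage else None
        if value is None:
            report.n_missing_rank += 1
            continue
        groups.setdefault(value, []).append(rec)
    rng = random.Random(seed)
    kept = [members[rng.randrange(len(members))] for members in groups.values()]
    report.n_kept = len(kept)
    return kept, report


def max_homopolymer_run(sequence: str) -> int:
    """Length of the longest single-base run in *sequence*."""
    best = run = 0
    prev = None
    for base in sequence:
        run = run + 1 if base == prev else 1
        prev = base
        best = max(best, run)
    return best


@dataclass
class RemovalReport:
    """Per-rule removal counts; each removed record counted once, in rule order."""

    n_input: int = 0
    n_kept: int = 0
    unclassified: int = 0
    length: int = 0
    homopolymer: int = 0

    @property
    def n_removed(self) -> int:
        return self.unclassified + self.length + self.homopolymer

    def to_tsv(self) -> str:
        lines = ["rule\tcount"]
        for rule in ("unclassified", "length", "homopolymer"):
            lines.append(f"{rule}\t{getattr(self, rule)}")
        lines.append(f"kept\t{self.n_kept}")
        return "\n".join(lines) + "\n"


def curate_reference_db(
    records: Sequence[SeqRecord],
    max_len: int = 2000,
    homopolymer_max: int = 14,
) -> tuple[list[SeqRecord], RemovalReport]:
    """Remove unclassified-genus, over-long and homopolymer-laden reference records.

    Removal rules are applied in a fixed order (unclassified genus, length strictly
    greater than *max_len*, any single-base run longer than *homopolymer_max*); a
    record tripping several rules is counted under the first.
    """
    report = RemovalReport(n_input=len(records))
    kept: list[SeqRecord] = []
    for rec in records:
        genus = rec.lineage.genus if rec.lineage else None
        if genus is None or genus.lower() == "unclassified":
            report.unclassified += 1
        elif len(rec.sequence) > max_len:
            report.length += 1
        elif max_homopolymer_run(rec.sequence) > homopolymer_max:
            report.homopolymer += 1
        else:
            kept.append(rec)
    report.n_kept = len(kept)
    return kept, report
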