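"""Platform-specific read filtering and primer trimming for amplicon/shotgun data.

Long amplicon reads (454-style) are filtered on ambiguity, length bounds and mean
Phred quality, then primer remnants are excised with a bounded-mismatch terminal
search; reads sequenced off the antisense strand are flipped so every surviving read
starts on the sense strand.  Short paired reads (early-Illumina style) are filtered
on the purity flag and on the count of quality-flag 'B' bases (Phred value 2 in that
pipeline generation) within the first 60 nt of either mate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from primerforge.seqio import UNAMBIGUOUS, reverse_complement
from primerforge.window_scan import hamming


@dataclass
class Read:
    id: str
    sequence: str
    qualities: Optional[list[int]] = None
    platform: str = "lr_amplicon"  # lr_amplicon | sr_pair
    mate: int = 0  # 1, 2, or 0 (unpaired)
    purity_ok: bool = True

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality length != sequence length")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_quality(self) -> Optional[float]:
        if self.qualities is None:
            return None
        return sum(self.qualities) / len(self.qualities)


@dataclass
class ReadPair:
    mate1: Optional[Read]
    mate2: Optional[Read]


def read_fastq(path: str | Path) -> list[Read]:
    """Read Sanger Phred+33 FASTQ."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            Read(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=list(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    bio = []
    for read in reads:
        rec = _BioRecord(Seq(read.sequence), id=read.id, description="")
        rec.letter_annotations["phred_quality"] = read.qualities or [40] * len(read)
        bio.append(rec)
    SeqIO.write(bio, str(path), "fastq")


@dataclass
class AmpliconFilterReport:
    """Removal counts in fixed rule order: ambiguity, length, quality."""

    n_input: int = 0
    n_kept: int = 0
    ambiguous: int = 0
    length: int = 0
    quality: int = 0
    unscorable: int = 0


def filter_amplicon_reads(
    reads: Sequence[Read],
    len_min: int,
    len_max: int,
    min_mean_q: Optional[float] = 20.0,
) -> tuple[list[Read], AmpliconFilterReport]:
    """Drop amplicon reads failing the ambiguity / length / mean-quality rules.

    Rules are checked in fixed order and each removed read is counted once:
    any non-ACGT base; length outside ``[len_min, len_max]``; arithmetic mean
    Phred quality strictly below *min_mean_q* (a mean of exactly *min_mean_q*
    is kept).  Reads without qualities cannot be scored when *min_mean_q* is
    set; they are removed and counted separately as unscorable.
    """
    report = AmpliconFilterReport(n_input=len(reads))
    kept: list[Read] = []
    for read in reads:
        if set(read.sequence) - UNAMBIGUOUS:
            report.ambiguous += 1
        elif len(read) < len_min or len(read) > len_max:
            report.length += 1
        elif min_mean_q is not None and read.qualities is None:
            report.unscorable += 1
        elif min_mean_q is not None and read.mean_quality < min_mean_q:
            report.quality += 1
        else:
            kept.append(read)
    report.n_kept = len(kept)
    return kept, report


@dataclass
class TrimResult:
    read: Read
    orientation: str  # "as-is" | "flipped"
    forward_trimmed: bool = True
    reverse_trimmed: bool = False


def _flip(read: Read) -> Read:
    qualities = list(reversed(read.qualities)) if read.qualities is not None else None
    return replace(read, sequence=reverse_complement(read.sequence), qualities=qualities)


def _search_terminal(
    sequence: str, oligo: str, max_mm: int, offsets: Iterable[int], prefer_late: bool
) -> Optional[int]:
    """Best (fewest-mismatch) oligo site among candidate offsets, or None."""
    k = len(oligo)
    best: Optional[tuple[int, int]] = None  # (mm, offset)
    ordered = sorted(offsets, reverse=prefer_late)
    for offset in ordered:
        if offset < 0 or offset + k > len(sequence):
            continue
        mm = hamming(sequence[offset : offset + k], oligo)
        if mm <= max_mm and (best is None or mm < best[0]):
            best = (mm, offset)
            if mm == 0:
                break
    return None if best is None else best[1]


def trim_primers(
    read: Read,
    forward_oligo: str,
    reverse_oligo: str,
    max_mm: int = 2,
    search_window: int = 30,
) -> Optional[TrimResult]:
    """Excise primer remnants and normalize orientation to the sense strand.

    The forward oligo is sought (<= *max_mm* mismatches) at offsets within the
    first *search_window* nt of the read; failing that, of the read's reverse
    complement (in which case the read is flipped first).  Everything up to and
    including the forward site is removed; the reverse oligo's reverse complement
    is then removed from the tail when present within the last *search_window* nt.
    Returns None (read dropped) when no forward site exists on either strand.
    """
    fwd_offsets = range(0, min(search_window, len(read) - len(forward_oligo)) + 1)
    offset = _search_terminal(read.sequence, forward_oligo, max_mm, fwd_offsets, False)
    orientation = "as-is"
    oriented = read
    if offset is None:
        oriented = _flip(read)
        offset = _search_terminal(
            oriented.sequence, forward_oligo, max_mm, fwd_offsets, False
        )
        orientation = "flipped"
        if offset is None:
            return None

    start = offset + len(forward_oligo)
    sequence = oriented.sequence[start:]
    qualities = oriented.qualities[start:] if oriented.qualities is not None else None

    rev_target = reverse_complement(reverse_oligo)
    k = len(rev_target)
    rev_offsets = range(max(0, len(sequence) - k - search_window), len(sequence) - k + 1)
    rev_offset = _search_terminal(sequence, rev_target, max_mm, rev_offsets, True)
    reverse_trimmed = rev_offset is not None
    if reverse_trimmed:
        sequence = sequence[:rev_offset]
        qualities = qualities[:rev_offset] if qualities is not None else None

    if not sequence:
        return None
    trimmed = replace(oriented, sequence=sequence, qualities=qualities)
    return TrimResult(read=trimmed, orientation=orientation, reverse_trimmed=reverse_trimmed)


@dataclass
class TrimReport:
    n_input: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    n_flipped: int = 0


def trim_many(
    reads: Sequence[Read],
    forward_oligo: str,
    reverse_oligo: str,
    max_mm: int = 2,
    search_window: int = 30,
) -> tuple[list[Read], TrimReport]:
    report = TrimReport(n_input=len(reads))
    kept: list[Read] = []
    for read in reads:
        result = trim_primers(read, forward_oligo, reverse_oligo, max_mm, search_window)
        if result is None:
            report.n_dropped += 1
            continue
        if result.orientation == "flipped":
            report.n_flipped += 1
        kept.append(result.read)
    report.n_kept = len(kept)
    return kept, report


@dataclass
class PairFilterReport:
    """Removal counts in fixed rule order: missing mate, purity, B-flag."""

    n_input: int = 0
    n_kept: int = 0
    missing_mate: int = 0
    purity: int = 0
    b_flag: int = 0


def _too_many_b(read: Read, b_flag_quality: int, head: int, max_b: int) -> bool:
    if read.qualities is None:
        return False
    n_b = sum(1 for q in read.qualities[:head] if q == b_flag_quality)
    return n_b > max_b


def filter_short_read_pairs(
    pairs: Sequence[ReadPair],
    b_flag_quality: int = 2,
    head: int = 60,
    max_b: int = 1,
) -> tuple[list[ReadPair], PairFilterReport]:
    """Drop read pairs failing purity or early-cycle B-flag quality rules.

    A pair is removed when a mate is missing, when either mate failed purity
    filtering, or when either mate carries more than *max_b* bases at quality
    *b_flag_quality* among its first *head* bases (exactly *max_b* is kept).
    """
    report = PairFilterReport(n_input=len(pairs))
    kept: list[ReadPair] = []
    for pair in pairs:
        if pair.mate1 is None or pair.mate2 is None:
            report.missing_mate += 1
        elif not (pair.mate1.purity_ok and pair.mate2.purity_ok):
            report.purity += 1
        elif _too_many_b(pair.mate1, b_flag_quality, head, max_b) or _too_many_b(
            pair.mate2, b_flag_quality, head, max_b
        ):
            report.b_flag += 1
        else:
            kept.append(pair)
    report.n_kept = len(kept)
    return kept, report
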