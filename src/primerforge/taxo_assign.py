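"""Fractional best-hit taxonomic assignment and community-profile comparison.

Reads are assigned from tabular similarity hits (standard 12-column blast tabular
dialect) against a curated rRNA reference set.  Assignment works at two independent
identity tiers - genus (>=94% identity by default) and phylum (>=85%) - and splits
a read's unit weight equally across all hits tied at the best bit score.  For
paired shotgun reads, a pair contributes one unit only when both mates agree on the
taxon, hit SSU rRNA subjects, and align in a consistent direction.  Profiles are
compared by Spearman rank correlation and competition-style rank abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

GENUS_MIN_IDENTITY = 94.0
PHYLUM_MIN_IDENTITY = 85.0

HIT_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass
class SubjectMeta:
    phylum: Optional[str] = None
    genus: Optional[str] = None
    gene_class: str = "SSU_rRNA"


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    identity: float  # percentage
    alnlen: int
    evalue: float
    bitscore: float
    strand: str = "+"
    phylum: Optional[str] = None
    genus: Optional[str] = None
    gene_class: str = "SSU_rRNA"


def read_subject_metadata(path: str | Path) -> dict[str, SubjectMeta]:
    """Read ``subject_id<TAB>phylum<TAB>genus<TAB>gene_class`` (header optional)."""
    meta: dict[str, SubjectMeta] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("subject_id\t"):
                continue
            fields = line.split("\t")
            fields += [""] * (4 - len(fields))
            meta[fields[0]] = SubjectMeta(
                phylum=fields[1] or None,
                genus=fields[2] or None,
                gene_class=fields[3] or "SSU_rRNA",
            )
    return meta


def write_subject_metadata(meta: Mapping[str, SubjectMeta], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("subject_id\tphylum\tgenus\tgene_class\n")
        for subject_id, m in meta.items():
            handle.write(
                f"{subject_id}\t{m.phylum or ''}\t{m.genus or ''}\t{m.gene_class}\n"
            )


def read_hits(
    path: str | Path,
    subject_metadata: Optional[Mapping[str, SubjectMeta]] = None,
) -> tuple[list[AlignmentHit], int]:
    """Parse 12-column blast-tabular hits; strand is inferred from sstart > send.

    Malformed rows (wrong column count, unparsable numerics) are skipped and
    counted; returns ``(hits, n_malformed)``.
    """
    hits: list[AlignmentHit] = []
    malformed = 0
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(HIT_COLUMNS):
                malformed += 1
                continue
            try:
                pident = float(fields[2])
                alnlen = int(fields[3])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError:
                malformed += 1
                continue
            meta = (subject_metadata or {}).get(fields[1], SubjectMeta())
            hits.append(
                AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    identity=pident,
                    alnlen=alnlen,
                    evalue=evalue,
                    bitscore=bitscore,
                    strand="-" if sstart > send else "+",
                    phylum=meta.phylum,
                    genus=meta.genus,
                    gene_class=meta.gene_class,
                )
            )
    return hits, malformed


def write_hits(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Emit hits in the 12-column tabular dialect (strand encoded via sstart/send)."""
    with open(path, "w") as handle:
        for h in hits:
            sstart, send = (h.alnlen, 1) if h.strand == "-" else (1, h.alnlen)
            handle.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity:.2f}\t{h.alnlen}\t0\t0"
                f"\t1\t{h.alnlen}\t{sstart}\t{send}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


def filter_hits(
    hits: Sequence[AlignmentHit], max_evalue: float, min_alnlen: int
) -> list[AlignmentHit]:
    """Keep hits with e-value strictly below *max_evalue* and length >= *min_alnlen*."""
    return [h for h in hits if h.evalue < max_evalue and h.alnlen >= min_alnlen]


@dataclass
class ReadAssignment:
    """Fractional taxon weights for one read at each identity tier (empty = unassigned)."""

    genus: dict[str, float] = field(default_factory=dict)
    phylum: dict[str, float] = field(default_factory=dict)

    def at(self, rank: str) -> dict[str, float]:
        return getattr(self, rank)


def _taxon(hit: AlignmentHit, rank: str) -> Optional[str]:
    return hit.genus if rank == "genus" else hit.phylum


def _best_hits(hits: Sequence[AlignmentHit]) -> list[AlignmentHit]:
    best = max(h.bitscore for h in hits)
    return [h for h in hits if h.bitscore == best]


def _tier_fractions(
    hits: Sequence[AlignmentHit], min_identity: float, rank: str
) -> dict[str, float]:
    qualifying = [
        h for h in hits if h.identity >= min_identity and _taxon(h, rank) is not None
    ]
    if not qualifying:
        return {}
    bests = _best_hits(qualifying)
    share = 1.0 / len(bests)
    fractions: dict[str, float] = {}
    for h in bests:
        taxon = _taxon(h, rank)
        fractions[taxon] = fractions.get(taxon, 0.0) + share
    return fractions


def assign_read(
    hits: Sequence[AlignmentHit],
    genus_min_identity: float = GENUS_MIN_IDENTITY,
    phylum_min_identity: float = PHYLUM_MIN_IDENTITY,
) -> ReadAssignment:
    """Assign one read from its (already e-value/length filtered) hits.

    Each tier is evaluated independently: only hits at or above the tier's
    identity threshold compete; the unit weight is split 1/n over the n hits
    tied at the best bit score (ties within one taxon accumulate).  A read can
    be phylum-assigned yet genus-unassigned.
    """
    return ReadAssignment(
        genus=_tier_fractions(hits, genus_min_identity, "genus"),
        phylum=_tier_fractions(hits, phylum_min_identity, "phylum"),
    )


def _mate_call(
    hits: Sequence[AlignmentHit], min_identity: float, rank: str
) -> Optional[tuple[str, Optional[str]]]:
    """A mate's unambiguous (taxon, strand) call at a tier, or None."""
    qualifying = [
        h for h in hits if h.identity >= min_identity and _taxon(h, rank) is not None
    ]
    if not qualifying:
        return None
    bests = _best_hits(qualifying)
    if any(h.gene_class != "SSU_rRNA" for h in bests):
        return None
    taxa = {_taxon(h, rank) for h in bests}
    if len(taxa) != 1:
        return None
    strands = {h.strand for h in bests}
    strand = strands.pop() if len(strands) == 1 else None
    return next(iter(taxa)), strand


def assign_pair(
    hits_mate1: Sequence[AlignmentHit],
    hits_mate2: Sequence[AlignmentHit],
    rank: str = "genus",
    genus_min_identity: float = GENUS_MIN_IDENTITY,
    phylum_min_identity: float = PHYLUM_MIN_IDENTITY,
    require_opposite_strands: bool = True,
) -> dict[str, float]:
    """Assign a read pair at *rank*; a qualifying pair contributes one unit.

    The pair counts only when both mates resolve to the same single taxon among
    SSU-rRNA best hits and their best-hit strands are consistent: opposite by
    default (paired ends face each other on the template), or equal when
    *require_opposite_strands* is False.  Inter-mate distance is ignored.
    """
    min_identity = genus_min_identity if rank == "genus" else phylum_min_identity
    call1 = _mate_call(hits_mate1, min_identity, rank)
    call2 = _mate_call(hits_mate2, min_identity, rank)
    if call1 is None or call2 is None:
        return {}
    (taxon1, strand1), (taxon2, strand2) = call1, call2
    if taxon1 != taxon2:
        return {}
    if strand1 is None or strand2 is None:
        return {}
    consistent = (strand1 != strand2) if require_opposite_strands else (strand1 == strand2)
    if not consistent:
        return {}
    return {taxon1: 1.0}


def assign_pairs(
    hits_by_pair: Sequence[tuple[Sequence[AlignmentHit], Sequence[AlignmentHit]]],
    rank: str = "genus",
    **kwargs,
) -> list[dict[str, float]]:
    return [assign_pair(h1, h2, rank=rank, **kwargs) for h1, h2 in hits_by_pair]


@dataclass
class TaxonomicProfile:
    rank: str
    abundances: dict[str, float] = field(default_factory=dict)
    assigned_total: float = 0.0
    input_read_count: int = 0

    def fraction(self, taxon: str) -> float:
        return self.abundances.get(taxon, 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.abundances.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(rows, columns=["taxon", "abundance"])


def build_profile(
    assignments: Iterable[Mapping[str, float]],
    rank: str,
    input_read_count: Optional[int] = None,
) -> TaxonomicProfile:
    """Sum per-read fractional contributions into a taxonomic profile."""
    assignments = list(assignments)
    profile = TaxonomicProfile(
        rank=rank,
        input_read_count=input_read_count if input_read_count is not None else len(assignments),
    )
    for fractions in assignments:
        for taxon, weight in fractions.items():
            profile.abundances[taxon] = profile.abundances.get(taxon, 0.0) + weight
        profile.assigned_total += sum(fractions.values())
    return profile


def compare_profiles(
    p1: TaxonomicProfile,
    p2: TaxonomicProfile,
    taxa: Optional[Sequence[str]] = None,
) -> float:
    """Spearman rank correlation between two profiles over a common taxon list.

    Defaults to the union of taxa (absent taxa count as 0); ties receive average
    ranks.  Fewer than three taxa makes the correlation meaningless and raises.
    """
    if p1.rank != p2.rank:
        raise ValueError(f"profiles at different ranks: {p1.rank} vs {p2.rank}")
    if taxa is None:
        taxa = sorted(set(p1.abundances) | set(p2.abundances))
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa for a rank correlation")
    v1 = [p1.fraction(t) for t in taxa]
    v2 = [p2.fraction(t) for t in taxa]
    return float(stats.spearmanr(v1, v2).statistic)


def rank_abundance(
    profile: TaxonomicProfile, top_n: Optional[int] = None
) -> list[tuple[str, float, int]]:
    """Taxa by descending abundance with competition ranks (ties share the smaller
    rank; the following rank is skipped).  Truncated to *top_n* entries."""
    if not profile.abundances:
        raise ValueError("rank_abundance requires a non-empty profile")
    ordered = sorted(profile.abundances.items(), key=lambda kv: (-kv[1], kv[0]))
    ranked: list[tuple[str, float, int]] = []
    for i, (taxon, abundance) in enumerate(ordered):
        if i > 0 and abundance == ranked[-1][1]:
            rank = ranked[-1][2]
        else:
            rank = i + 1
        ranked.append((taxon, abundance, rank))
    return ranked[:top_n] if top_n is not None else ranked
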