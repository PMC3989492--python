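"""End-to-end universal-primer discovery: scan -> select -> merge -> exclude -> pair.

Ties the per-module operations together the way the full workflow runs: scan a
labelled alignment for conserved windows, keep candidate windows with near-universal
prokaryotic coverage inside the usable reference interval, merge neighbouring windows
into longer concrete primers while maintaining per-phylum coverage, drop candidates
that would co-amplify mitochondrial or eukaryotic rRNA, attach genus-majority
coverage, and rank forward/reverse pairings under the amplicon-length constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

from primerforge.primer_design import (
    PrimerCandidate,
    PrimerPair,
    merge_neighbouring,
    pair_primers,
)
from primerforge.probe_match import (
    eukaryote_exclusion_filter,
    filter_by_position,
    genus_coverage,
    min_mismatch,
)
from primerforge.seqio import Lineage, SeqRecord
from primerforge.window_scan import WindowResult, scan, select_candidates


@dataclass
class PipelineResult:
    windows: list[WindowResult]
    selected: list[WindowResult]
    candidates: list[PrimerCandidate]
    kept: list[PrimerCandidate]
    excluded: list[tuple[PrimerCandidate, str]]
    pairs: list[PrimerPair]

    @property
    def top_pair(self) -> Optional[PrimerPair]:
        return self.pairs[0] if self.pairs else None


def per_phylum_sequence_coverage(
    records: Sequence[SeqRecord], max_mm: int = 1
) -> "callable":
    """Coverage function for merge checks: % of each phylum's records with a site
    within *max_mm* of a candidate sequence (sense-strand matching)."""

    by_phylum: dict[str, list[SeqRecord]] = {}
    for rec in records:
        if rec.lineage and rec.lineage.phylum:
            by_phylum.setdefault(rec.lineage.phylum, []).append(rec)

    def coverage(sequence: str) -> dict[str, float]:
        result = {}
        for phylum, members in by_phylum.items():
            matched = sum(
                1
                for rec in members
                if (mm := min_mismatch(sequence, rec.sequence)) is not None
                and mm <= max_mm
            )
            result[phylum] = 100.0 * matched / len(members)
        return result

    return coverage


def design_primer_pairs(
    alignment,
    reference_id: str,
    prok_records: Sequence[SeqRecord],
    mito_records: Sequence[SeqRecord],
    euk_records: Sequence[SeqRecord],
    taxonomy: Optional[Mapping[str, Lineage]] = None,
    width: int = 15,
    max_mm: int = 1,
    min_coverage: float = 90.0,
    min_phylum_fraction: float = 0.9,
    keep_interval: tuple[int, int] = (30, 1200),
    merge_tolerance: float = 0.0,
    euk_max_mm: int = 2,
    euk_max_cov: float = 50.0,
    min_span: int = 350,
    max_span: int = 550,
) -> PipelineResult:
    """Run the complete primer-discovery workflow on a labelled alignment."""
    windows = scan(
        alignment, taxonomy=taxonomy, width=width, max_mm=max_mm, reference_id=reference_id
    )
    selected = select_candidates(windows, min_coverage, min_phylum_fraction)
    selected = [w for w in selected if not w.ref_pos_flagged]
    selected = filter_by_position(selected, *keep_interval)

    coverage_fn = per_phylum_sequence_coverage(prok_records, max_mm=max_mm)
    candidates = merge_neighbouring(selected, coverage_fn, tolerance=merge_tolerance)

    kept, excluded = eukaryote_exclusion_filter(
        candidates, mito_records, euk_records, max_mm=euk_max_mm, max_cov=euk_max_cov
    )
    for cand in kept:
        cand.coverage = genus_coverage(cand.sequence, prok_records, max_mm=max_mm).percent

    forwards = [replace(c, orientation="forward") for c in kept]
    reverses = [replace(c, orientation="reverse") for c in kept]
    pairs = pair_primers(forwards, reverses, min_span=min_span, max_span=max_span)
    return PipelineResult(
        windows=windows,
        selected=selected,
        candidates=candidates,
        kept=kept,
        excluded=excluded,
        pairs=pairs,
    )
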