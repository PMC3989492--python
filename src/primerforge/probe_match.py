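"""Mismatch-tolerant primer matching against unaligned reference sets.

This is a probe-match style evaluation: the primer is compared, ungapped, against
every same-length substring of each reference sequence (forward primers against the
sense strand; reverse primers via their reverse complement), and a sequence "matches
within k mismatches" when its best site has Hamming distance <= k.  Two coverage
metrics are built on top of it:

* per-sequence coverage - percentage of sequences in a group with a site within the
  allowance (used for chloroplast/mitochondrion/eukaryote sets at <=2 mismatches;
  three or more mismatches are assumed to prevent PCR amplification), and
* genus-majority coverage - percentage of genera in a phylum in which a strict
  majority of member sequences match within the allowance (used for prokaryote
  reference sets at <=1 mismatch, robust to the uneven per-genus sampling of
  public rRNA databases).

The eukaryote-exclusion rule rejects candidates covering more than half of the
mitochondrial or eukaryotic reference sequences within two mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from primerforge.seqio import SeqRecord, reverse_complement
from primerforge.window_scan import _AMBIG, encode

ORIENTATIONS = ("forward", "reverse")


@dataclass
class CoverageTable:
    """Coverage of one primer over labelled sequence groups."""

    primer_id: str
    metric: str  # per_sequence | genus_majority
    max_mm: int
    percent: dict[str, float] = field(default_factory=dict)
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)  # matched, total

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "primer_id": self.primer_id,
                "metric": self.metric,
                "max_mm": self.max_mm,
                "group": group,
                "percent": pct,
                "matched": self.counts[group][0],
                "total": self.counts[group][1],
            }
            for group, pct in self.percent.items()
        ]
        return pd.DataFrame(rows)


def _validate_primer(primer: str) -> None:
    if not primer:
        raise ValueError("primer must be non-empty")
    bad = set(primer) - set("ACGT")
    if bad:
        raise ValueError(
            f"primer contains non-ACGT characters {sorted(bad)}; "
            "resolve degenerate primers first"
        )


def best_site(primer: str, template: str) -> Optional[tuple[int, int]]:
    """Best ungapped site of *primer* on *template*: ``(offset0, mismatches)``.

    Ties go to the leftmost offset.  Returns None when the template is shorter
    than the primer.  Ambiguity characters in the template mismatch everything.
    """
    k = len(primer)
    if k == 0 or k > len(template):
        return None
    t = encode(template)
    p = encode(primer)
    windows = sliding_window_view(t, k)
    mism = ((windows != p) | (windows == _AMBIG)).sum(axis=1)
    offset = int(mism.argmin())
    return offset, int(mism[offset])


def min_mismatch(primer: str, template: str, orientation: str = "forward") -> Optional[int]:
    """Minimum Hamming distance of the primer to any same-length template substring.

    ``orientation="reverse"`` matches the primer's reverse complement against the
    sense strand (standard PCR semantics).  Indels are not modelled.  Returns
    None when the template is shorter than the primer (no site).
    """
    _validate_primer(primer)
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    if orientation == "reverse":
        primer = reverse_complement(primer)
    site = best_site(primer, template)
    return None if site is None else site[1]


def _group_key(record: SeqRecord, group_by: str) -> Optional[str]:
    if group_by == "origin":
        return record.origin
    if record.lineage is None:
        return None
    return record.lineage.rank(group_by)


def sequence_coverage(
    primer: str,
    records: Sequence[SeqRecord],
    max_mm: int,
    orientation: str = "forward",
    group_by: str = "origin",
    primer_id: Optional[str] = None,
) -> CoverageTable:
    """Per-sequence coverage: % of each group's records with a site <= *max_mm*.

    Records whose *group_by* label is absent are skipped; empty groups are
    omitted from the table.
    """
    table = CoverageTable(primer_id=primer_id or primer, metric="per_sequence", max_mm=max_mm)
    grouped: dict[str, list[SeqRecord]] = {}
    for rec in records:
        key = _group_key(rec, group_by)
        if key is not None:
            grouped.setdefault(key, []).append(rec)
    for group, members in grouped.items():
        matched = 0
        for rec in members:
            mm = min_mismatch(primer, rec.sequence, orientation)
            if mm is not None and mm <= max_mm:
                matched += 1
        table.percent[group] = 100.0 * matched / len(members)
        table.counts[group] = (matched, len(members))
    return table


def genus_coverage(
    primer: str,
    records: Sequence[SeqRecord],
    max_mm: int = 1,
    orientation: str = "forward",
    primer_id: Optional[str] = None,
) -> CoverageTable:
    """Genus-majority coverage per phylum.

    A genus counts as covered when strictly more than half of its member
    sequences match the primer within *max_mm* (exactly half does not count);
    the reported percentage is covered genera / genera in the phylum.
    """
    table = CoverageTable(primer_id=primer_id or primer, metric="genus_majority", max_mm=max_mm)
    genera: dict[str, dict[str, list[SeqRecord]]] = {}
    for rec in records:
        if rec.lineage is None or not rec.lineage.phylum or not rec.lineage.genus:
            raise ValueError(f"record {rec.id!r} lacks phylum/genus for genus coverage")
        genera.setdefault(rec.lineage.phylum, {}).setdefault(rec.lineage.genus, []).append(rec)
    for phylum, by_genus in genera.items():
        covered = 0
        for members in by_genus.values():
            matched = 0
            for rec in members:
                mm = min_mismatch(primer, rec.sequence, orientation)
                if mm is not None and mm <= max_mm:
                    matched += 1
            if 2 * matched > len(members):
                covered += 1
        table.percent[phylum] = 100.0 * covered / len(by_genus)
        table.counts[phylum] = (covered, len(by_genus))
    return table


def eukaryote_exclusion_filter(
    candidates: Sequence,
    mito_records: Sequence[SeqRecord],
    euk_records: Sequence[SeqRecord],
    max_mm: int = 2,
    max_cov: float = 50.0,
) -> tuple[list, list[tuple[object, str]]]:
    """Drop candidates that cover too much mitochondrial or eukaryotic rRNA.

    A candidate (any object with ``sequence`` and ``orientation`` attributes) is
    excluded when its per-sequence coverage within *max_mm* exceeds *max_cov*
    percent in either group; a candidate at exactly *max_cov* is kept.
    """

    def _pct(candidate, records: Sequence[SeqRecord]) -> float:
        if not records:
            return 0.0
        matched = sum(
            1
            for rec in records
            if (mm := min_mismatch(candidate.sequence, rec.sequence, candidate.orientation))
            is not None
            and mm <= max_mm
        )
        return 100.0 * matched / len(records)

    kept: list = []
    excluded: list[tuple[object, str]] = []
    for cand in candidates:
        mito_pct = _pct(cand, mito_records)
        euk_pct = _pct(cand, euk_records)
        if mito_pct > max_cov or euk_pct > max_cov:
            excluded.append(
                (cand, f"mitochondrion={mito_pct:.1f}%, eukaryote={euk_pct:.1f}% at <={max_mm} mm")
            )
        else:
            kept.append(cand)
    return kept, excluded


def filter_by_position(
    candidates: Sequence, keep_min: int = 30, keep_max: int = 1200
) -> list:
    """Keep candidates whose reference start falls inside ``[keep_min, keep_max]``.

    Terminal 16S regions are missing from many database records and 3'-distal
    sites are beyond amplicon read reach, so candidates there are dropped.
    Accepts any objects carrying a ``ref_pos`` or ``ref_start`` attribute.
    """
    kept = []
    for cand in candidates:
        pos = getattr(cand, "ref_start", None)
        if pos is None:
            pos = cand.ref_pos
        if keep_min <= pos <= keep_max:
            kept.append(cand)
    return kept


def coverage_matrix(
    primers: Sequence,
    prok_records: Sequence[SeqRecord],
    euk_groups: Mapping[str, Sequence[SeqRecord]],
    prok_max_mm: int = 1,
    euk_max_mm: int = 2,
) -> pd.DataFrame:
    """Labelled coverage matrix: primers x (prokaryotic phyla + organelle/eukaryote groups).

    Prokaryotic phyla are scored with the genus-majority metric at *prok_max_mm*;
    each group in *euk_groups* (e.g. chloroplast / mitochondrion / eukaryote) with
    the per-sequence metric at *euk_max_mm*.  *primers* are objects with ``sequence``
    and ``orientation`` (and optionally an id) or plain ``(id, sequence, orientation)``
    tuples.
    """
    rows = []
    index = []
    for primer in primers:
        if isinstance(primer, tuple):
            primer_id, sequence, orientation = primer
        else:
            primer_id = getattr(primer, "id", None) or primer.sequence
            sequence, orientation = primer.sequence, primer.orientation
        row: dict[str, float] = {}
        if prok_records:
            row.update(
                genus_coverage(sequence, prok_records, prok_max_mm, orientation).percent
            )
        for group, records in euk_groups.items():
            if not records:
                continue
            matched = sum(
                1
                for rec in records
                if (mm := min_mismatch(sequence, rec.sequence, orientation)) is not None
                and mm <= euk_max_mm
            )
            row[group] = 100.0 * matched / len(records)
        rows.append(row)
        index.append(primer_id)
    frame = pd.DataFrame(rows, index=index)
    return frame[sorted(frame.columns)] if len(frame.columns) else frame
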