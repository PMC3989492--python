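"""Sliding-window consensus scan over a taxonomically labelled rRNA alignment.

A fixed-width window (default 15 nt, step 1) slides across the alignment.  For each
window the module computes

* the consensus: the observed window slice that the largest number of member slices
  fall within one mismatch of (gaps count as a fifth symbol),
* per-phylum coverage: the percentage of each phylum's members within the mismatch
  allowance of that consensus,
* a per-window sequence-variability score (summed per-column entropy over
  {A,C,G,T,-}), and
* the window's start coordinate in a designated ungapped reference sequence
  (conventionally the E. coli 16S rRNA gene, the community-standard numbering).

Windows that are highly covered across (almost) all bacterial and archaeal phyla are
the universal-primer candidate sequences passed on to :mod:`primerforge.primer_design`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from primerforge.seqio import GAP, Alignment, Lineage

#: symbol codes: A,C,G,T,- -> 0..4; everything else (IUPAC ambiguity) -> 255
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT" + GAP):
    _CODE[ord(_c)] = _i
_AMBIG = 255

#: Fig-style display bins for coverage percentages.
COVERAGE_BINS = (
    (50.0, "black"),
    (80.0, "blue"),
    (90.0, "green"),
    (100.0, "yellow"),
)


def bin_coverage(percentage: float) -> str:
    """Map a coverage percentage to its display bin (black/blue/green/yellow/red)."""
    if not 0.0 <= percentage <= 100.0:
        raise ValueError(f"coverage {percentage} outside [0, 100]")
    for upper, colour in COVERAGE_BINS:
        if percentage < upper:
            return colour
    return "red"


def encode(sequence: str) -> np.ndarray:
    """Encode a sequence over {A,C,G,T,-} + ambiguity codes as uint8 symbol codes."""
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def hamming(a: str, b: str) -> int:
    """Hamming distance where any ambiguity code mismatches everything, itself included."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    ea, eb = encode(a), encode(b)
    return int(((ea != eb) | (ea == _AMBIG) | (eb == _AMBIG)).sum())


@dataclass
class WindowResult:
    """Consensus, coverage and variability for one alignment window."""

    start_col: int  # 1-based alignment column
    ref_pos: int  # 1-based position in the ungapped reference (0 = before first base)
    width: int
    consensus: str
    consensus_freq: int
    phylum_coverage: dict[str, float] = field(default_factory=dict)
    variability: float = 0.0
    ref_pos_flagged: bool = False  # True when the window starts before the reference


def map_to_reference_coords(
    alignment: Alignment, reference_id: str
) -> tuple[list[int], list[bool]]:
    """Map every alignment column to a 1-based ungapped reference position.

    Columns where the reference carries a base map to that base's position; gap
    columns inherit the nearest preceding base position.  Columns before the first
    reference base map to 0 and are flagged.
    Returns ``(positions, flagged)``, both indexed by column - 1.
    """
    row = alignment.get(reference_id).gapped_sequence
    positions: list[int] = []
    flagged: list[bool] = []
    pos = 0
    for char in row:
        if char != GAP:
            pos += 1
        positions.append(pos)
        flagged.append(pos == 0)
    return positions, flagged


def _pairwise_mismatches(matrix: np.ndarray) -> np.ndarray:
    """All-vs-all mismatch counts between rows of an encoded slice matrix."""
    ambig = matrix == _AMBIG
    mism = (matrix[:, None, :] != matrix[None, :, :]) | ambig[:, None, :] | ambig[None, :, :]
    return mism.sum(axis=2)


def window_consensus(slices: Sequence[str], max_mm: int = 1) -> tuple[str, int]:
    """Most frequent slice "within *max_mm* mismatches" among observed slices.

    The frequency of an observed slice s is the number of member slices at Hamming
    distance <= max_mm from s (the gap is a fifth symbol; ambiguity codes mismatch
    every symbol including themselves).  Ties are broken lexicographically, with
    "-" ordered before "A" (plain ASCII order).
    """
    if not slices:
        raise ValueError("window_consensus requires at least one slice")
    width = len(slices[0])
    if any(len(s) != width for s in slices):
        raise ValueError("all window slices must have equal width")
    matrix = np.stack([encode(s) for s in slices])
    freq = (_pairwise_mismatches(matrix) <= max_mm).sum(axis=1)
    best = int(freq.max())
    consensus = min(slices[i] for i in np.flatnonzero(freq == best))
    return consensus, best


def phylum_coverage_rate(
    consensus: str,
    slices_by_phylum: Mapping[str, Sequence[str]],
    max_mm: int = 1,
) -> dict[str, float]:
    """Per phylum, percentage of member slices within *max_mm* of the consensus."""
    coverage: dict[str, float] = {}
    for phylum, members in slices_by_phylum.items():
        if not members:
            continue
        matched = sum(1 for s in members if hamming(consensus, s) <= max_mm)
        coverage[phylum] = 100.0 * matched / len(members)
    return coverage


def window_variability(slices: Sequence[str], method: str = "shannon") -> float:
    """Summed per-column entropy of the 5-symbol distribution {A,C,G,T,-} in bits.

    Ambiguity codes are excluded from each column's distribution (counts are
    renormalized).  ``method="shannon"`` (default) scores a column by its Shannon
    entropy, so 0 = fully conserved; ``method="kl_uniform"`` scores by the
    relative entropy against the uniform 5-symbol background instead.
    """
    if not slices:
        raise ValueError("window_variability requires at least one slice")
    if method not in ("shannon", "kl_uniform"):
        raise ValueError(f"unknown variability method {method!r}")
    matrix = np.stack([encode(s) for s in slices])
    total = 0.0
    for col in matrix.T:
        counts = np.bincount(col[col != _AMBIG], minlength=5)[:5]
        n = counts.sum()
        if n == 0:
            continue
        p = counts[counts > 0] / n
        shannon = float(-(p * np.log2(p)).sum())
        total += math.log2(5) - shannon if method == "kl_uniform" else shannon
    return total


def _lineage_of(record, taxonomy: Optional[Mapping[str, Lineage]]) -> Optional[Lineage]:
    if record.lineage is not None:
        return record.lineage
    if taxonomy is not None:
        return taxonomy.get(record.id)
    return None


def scan(
    alignment: Alignment,
    taxonomy: Optional[Mapping[str, Lineage]] = None,
    width: int = 15,
    max_mm: int = 1,
    reference_id: Optional[str] = None,
    variability_method: str = "shannon",
) -> list[WindowResult]:
    """Slide a *width*-nt window (step 1) across the alignment.

    Returns one :class:`WindowResult` per start column ``1..L-width+1``.  Phylum
    coverage is computed over records whose lineage (attached or via *taxonomy*)
    has a phylum.  When *reference_id* is given, windows carry the reference
    coordinate of their first column.
    """
    if alignment.length < width:
        raise ValueError(
            f"alignment length {alignment.length} shorter than window width {width}"
        )
    if reference_id is not None:
        positions, flagged = map_to_reference_coords(alignment, reference_id)
    else:
        positions = list(range(1, alignment.length + 1))
        flagged = [False] * alignment.length

    matrix = np.stack([encode(rec.gapped_sequence) for rec in alignment])
    phylum_rows: dict[str, list[int]] = {}
    for i, rec in enumerate(alignment):
        lineage = _lineage_of(rec, taxonomy)
        if lineage and lineage.phylum:
            phylum_rows.setdefault(lineage.phylum, []).append(i)

    results: list[WindowResult] = []
    for start in range(alignment.length - width + 1):
        window = matrix[:, start : start + width]
        ambig = window == _AMBIG
        mism = (
            (window[:, None, :] != window[None, :, :])
            | ambig[:, None, :]
            | ambig[None, :, :]
        )
        dist = mism.sum(axis=2)
        freq = (dist <= max_mm).sum(axis=1)
        best = int(freq.max())
        tied = np.flatnonzero(freq == best)
        strings = {
            i: alignment.records[i].gapped_sequence[start : start + width] for i in tied
        }
        consensus_row = min(tied, key=lambda i: strings[i])
        consensus = strings[consensus_row]
        # distance of every member slice to the consensus row, reused for coverage
        member_dist = dist[consensus_row]
        coverage = {
            phylum: 100.0 * float((member_dist[rows] <= max_mm).mean())
            for phylum, rows in phylum_rows.items()
        }
        variability = window_variability(
            [rec.gapped_sequence[start : start + width] for rec in alignment],
            method=variability_method,
        )
        results.append(
            WindowResult(
                start_col=start + 1,
                ref_pos=positions[start],
                width=width,
                consensus=consensus,
                consensus_freq=best,
                phylum_coverage=coverage,
                variability=variability,
                ref_pos_flagged=flagged[start],
            )
        )
    return results


def select_candidates(
    windows: Sequence[WindowResult],
    min_coverage: float = 90.0,
    min_phylum_fraction: float = 0.9,
) -> list[WindowResult]:
    """Keep windows usable as primer candidates.

    A window passes when its consensus is gap-free and ambiguity-free (a
    synthesizable oligo) and its coverage reaches *min_coverage* percent in at
    least *min_phylum_fraction* of the phyla present.
    """
    selected = []
    for win in sorted(windows, key=lambda w: w.start_col):
        if set(win.consensus) - set("ACGT"):
            continue
        if not win.phylum_coverage:
            continue
        n_ok = sum(1 for pct in win.phylum_coverage.values() if pct >= min_coverage)
        if n_ok >= min_phylum_fraction * len(win.phylum_coverage):
            selected.append(win)
    return selected


def windows_to_table(windows: Sequence[WindowResult]) -> pd.DataFrame:
    """Tabulate windows: one row per window, one column per phylum coverage."""
    phyla = sorted({p for w in windows for p in w.phylum_coverage})
    rows = []
    for w in windows:
        row = {
            "start_col": w.start_col,
            "ref_pos": w.ref_pos,
            "consensus": w.consensus,
            "consensus_freq": w.consensus_freq,
            "variability": w.variability,
        }
        for p in phyla:
            row[f"coverage_{p}"] = w.phylum_coverage.get(p, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
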