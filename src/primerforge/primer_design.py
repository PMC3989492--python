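"""Candidate merging, degenerate-primer resolution and forward/reverse pairing.

Neighbouring candidate windows that agree on their overlap are merged into longer
concrete primers (longer oligos reduce random, non-specific priming), but only while
the merge maintains per-phylum coverage.  Published degenerate primers can be
resolved to the concrete variant with the best prokaryotic coverage so that all
candidates are comparable as non-degenerate oligos.  Finally forward and reverse
candidates are paired under amplicon-length constraints set by the sequencing
platform's usable read length.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from primerforge.probe_match import genus_coverage
from primerforge.seqio import SeqRecord, reverse_complement
from primerforge.window_scan import WindowResult

CoverageFn = Callable[[str], Mapping[str, float]]


@dataclass
class PrimerCandidate:
    """A concrete primer in sense-strand orientation with reference coordinates.

    ``sequence`` is always stored on the sense strand; the synthesizable oligo for
    a reverse candidate is the derived :attr:`oligo` (reverse complement).  This
    avoids silent double-complementing when candidates change roles.
    """

    sequence: str
    ref_start: int
    ref_end: int
    orientation: str = "forward"
    provenance: list[int] = field(default_factory=list)
    coverage: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.ref_end - self.ref_start + 1 != len(self.sequence):
            raise ValueError(
                f"candidate span {self.ref_start}-{self.ref_end} inconsistent with "
                f"sequence length {len(self.sequence)}"
            )
        if set(self.sequence) - set("ACGT"):
            raise ValueError("candidate sequence must be gap-free and ambiguity-free")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def oligo(self) -> str:
        """The 5'->3' sequence to synthesize."""
        if self.orientation == "reverse":
            return reverse_complement(self.sequence)
        return self.sequence

    @property
    def name(self) -> str:
        """Conventional primer name: reference start + orientation letter."""
        return f"{self.ref_start}{'F' if self.orientation == 'forward' else 'R'}"


@dataclass
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate

    def __post_init__(self) -> None:
        if self.forward.ref_end >= self.reverse.ref_start:
            raise ValueError("forward primer must end before the reverse primer starts")
        if self.amplicon_span <= len(self.forward) + len(self.reverse):
            raise ValueError("amplicon must contain an insert between the primers")

    @property
    def amplicon_span(self) -> int:
        return self.reverse.ref_end - self.forward.ref_start + 1

    @property
    def name(self) -> str:
        return f"{self.forward.name}-{self.reverse.name}"


def _merged_sequence(run: Sequence[WindowResult]) -> str:
    seq = run[0].consensus
    for window in run[1:]:
        seq += window.consensus[-1]
    return seq


def _run_acceptable(
    run: Sequence[WindowResult], coverage_fn: Optional[CoverageFn], tolerance: float
) -> bool:
    if len(run) == 1 or coverage_fn is None:
        return True
    merged_cov = coverage_fn(_merged_sequence(run))
    phyla = {p for w in run for p in w.phylum_coverage}
    for phylum in phyla:
        floor = min(
            w.phylum_coverage[phylum] for w in run if phylum in w.phylum_coverage
        )
        if merged_cov.get(phylum, 0.0) < floor - tolerance:
            return False
    return True


def merge_neighbouring(
    windows: Sequence[WindowResult],
    coverage_fn: Optional[CoverageFn] = None,
    tolerance: float = 0.0,
    orientation: str = "forward",
) -> list[PrimerCandidate]:
    """Merge runs of windows at consecutive reference positions into longer primers.

    Windows whose start positions are consecutive and whose consensi agree on every
    overlap form a run; a run of k windows of width w merges into a (w + k - 1)-nt
    candidate.  When *coverage_fn* is given (mapping a candidate sequence to
    per-phylum coverage), a merge is accepted only if no phylum's coverage drops
    below the minimum over the constituent windows minus *tolerance*; otherwise the
    run is split greedily left-to-right into the longest acceptable prefixes.
    Overlap disagreements simply split the run.
    """
    ordered = sorted(windows, key=lambda w: (w.ref_pos, w.start_col))
    for win in ordered:
        if set(win.consensus) - set("ACGT"):
            raise ValueError(
                f"window at {win.ref_pos} has a gapped/ambiguous consensus; "
                "select candidates first"
            )

    runs: list[list[WindowResult]] = []
    for win in ordered:
        if runs:
            prev = runs[-1][-1]
            contiguous = win.ref_pos == prev.ref_pos + 1
            overlap_ok = prev.consensus[1:] == win.consensus[: win.width - 1]
            if contiguous and overlap_ok:
                runs[-1].append(win)
                continue
        runs.append([win])

    candidates: list[PrimerCandidate] = []
    for run in runs:
        i = 0
        while i < len(run):
            for j in range(len(run), i, -1):  # longest acceptable prefix
                if _run_acceptable(run[i:j], coverage_fn, tolerance):
                    break
            piece = run[i:j]
            seq = _merged_sequence(piece)
            start = piece[0].ref_pos
            candidates.append(
                PrimerCandidate(
                    sequence=seq,
                    ref_start=start,
                    ref_end=start + len(seq) - 1,
                    orientation=orientation,
                    provenance=[w.ref_pos for w in piece],
                )
            )
            i = j
    return candidates


def expand_iupac(sequence: str, cap: int = 1024) -> list[str]:
    """All concrete ACGT expansions of an IUPAC sequence, lexicographically sorted."""
    choices = []
    n = 1
    for char in sequence.upper():
        if char not in ambiguous_dna_values:
            raise ValueError(f"invalid IUPAC character {char!r}")
        bases = sorted(ambiguous_dna_values[char])
        n *= len(bases)
        if n > cap:
            raise ValueError(
                f"degenerate expansion exceeds cap of {cap} variants; "
                "raise the cap to proceed"
            )
        choices.append(bases)
    return ["".join(combo) for combo in itertools.product(*choices)]


def resolve_degenerate(
    primer_iupac: str,
    records: Sequence[SeqRecord],
    max_mm: int = 1,
    orientation: str = "forward",
    cap: int = 1024,
) -> tuple[str, pd.DataFrame]:
    """Pick the concrete expansion with the best prokaryotic genus-majority coverage.

    Every concrete variant is scored by its mean per-phylum genus-majority coverage
    over *records*; the winner is the variant with the highest mean (ties broken by
    lexicographic order).  The report lists every variant's per-phylum coverage so
    alternative objectives can be audited.
    """
    variants = expand_iupac(primer_iupac, cap=cap)
    rows = []
    best_variant = None
    best_score = -1.0
    for variant in variants:  # already lexicographically sorted: first win is the tie-break
        table = genus_coverage(variant, records, max_mm=max_mm, orientation=orientation)
        score = (
            sum(table.percent.values()) / len(table.percent) if table.percent else 0.0
        )
        row = {"variant": variant, "mean_coverage": score}
        row.update({f"coverage_{p}": v for p, v in sorted(table.percent.items())})
        rows.append(row)
        if score > best_score:
            best_score = score
            best_variant = variant
    return best_variant, pd.DataFrame(rows)


def _mean_coverage(candidate: PrimerCandidate) -> float:
    if not candidate.coverage:
        return 0.0
    return sum(candidate.coverage.values()) / len(candidate.coverage)


def pair_primers(
    forwards: Sequence[PrimerCandidate],
    reverses: Sequence[PrimerCandidate],
    min_span: int,
    max_span: int = 550,
) -> list[PrimerPair]:
    """All admissible forward x reverse pairs, ranked.

    A pair is admissible when the forward candidate ends before the reverse starts,
    the amplicon contains a non-empty insert, and ``min_span <= amplicon_span <=
    max_span``.  Pairs are ranked by descending mean prokaryotic coverage (mean over
    both primers' attached per-phylum coverage), then descending amplicon span, then
    coordinates - so the ranking is stable under permutation of the inputs.
    """
    pairs: list[PrimerPair] = []
    for fwd, rev in itertools.product(forwards, reverses):
        if fwd.ref_end >= rev.ref_start:
            continue
        span = rev.ref_end - fwd.ref_start + 1
        if span <= len(fwd) + len(rev):
            continue
        if not min_span <= span <= max_span:
            continue
        fwd = replace(fwd, orientation="forward") if fwd.orientation != "forward" else fwd
        rev = replace(rev, orientation="reverse") if rev.orientation != "reverse" else rev
        pairs.append(PrimerPair(forward=fwd, reverse=rev))
    pairs.sort(
        key=lambda p: (
            -(_mean_coverage(p.forward) + _mean_coverage(p.reverse)) / 2.0,
            -p.amplicon_span,
            p.forward.ref_start,
            p.reverse.ref_start,
        )
    )
    return pairs


def candidates_to_table(candidates: Sequence[PrimerCandidate]) -> pd.DataFrame:
    rows = []
    for cand in candidates:
        row = {
            "name": cand.name,
            "sequence": cand.sequence,
            "oligo": cand.oligo,
            "ref_start": cand.ref_start,
            "ref_end": cand.ref_end,
            "orientation": cand.orientation,
            "length": len(cand),
        }
        if cand.coverage:
            row["mean_coverage"] = _mean_coverage(cand)
        rows.append(row)
    return pd.DataFrame(rows)


def pairs_to_table(pairs: Sequence[PrimerPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair": p.name,
                "forward_oligo": p.forward.oligo,
                "reverse_oligo": p.reverse.oligo,
                "forward_span": f"{p.forward.ref_start}-{p.forward.ref_end}",
                "reverse_span": f"{p.reverse.ref_start}-{p.reverse.ref_end}",
                "amplicon_span": p.amplicon_span,
                "mean_coverage": (_mean_coverage(p.forward) + _mean_coverage(p.reverse)) / 2.0,
            }
            for p in pairs
        ]
    )
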