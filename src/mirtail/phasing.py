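"""Phased secondary-siRNA (phasiRNA) analysis.

Dicer processes a double-stranded precursor into duplexes with 2-nt 3'
overhangs, so an antisense read whose leftmost sense-axis coordinate is s
is in register with the sense read starting at s + 2; strand combining
applies exactly that shift before scoring. The phasing score at a register
position p over a window of ``window_cycles`` cycles of length ``cycle`` is

    score(p) = (k - 2) * ln(1 + scale * P / (pseudo + U))   if k >= min_k
             = 0                                            otherwise

with P the summed abundance at in-register positions p, p+cycle, ...,
U the abundance everywhere else in the window, and k the number of
occupied in-register positions. Defaults: cycle 21 nt, 9-cycle window,
min_k 3, scale 10, pseudo-count 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from mirtail.mapper import ExactMatchIndex
from mirtail.refio import Interval, ReadSet

DEFAULT_CYCLE = 21
DEFAULT_WINDOW_CYCLES = 9
DEFAULT_MIN_K = 3
DEFAULT_OVERHANG_SHIFT = 2


def combine_strands(sense_starts: Mapping[int, float],
                    antisense_starts: Mapping[int, float],
                    shift: int = DEFAULT_OVERHANG_SHIFT,
                    ) -> tuple[dict[int, float], float]:
    """Merge strand-specific start-position abundances onto sense registers.

    ``antisense_starts`` are keyed by the read's leftmost covered position
    on the SENSE axis; each contributes at position + ``shift``. Returns
    (combined abundance, abundance dropped because the shifted position
    fell below 0).
    """
    combined: dict[int, float] = dict(sense_starts)
    dropped = 0.0
    for pos, ab in antisense_starts.items():
        p = pos + shift
        if p < 0:
            dropped += ab
            continue
        combined[p] = combined.get(p, 0.0) + ab
    return combined, dropped


def phase_score(abundance: Mapping[int, float],
                positions: range | None = None,
                cycle: int = DEFAULT_CYCLE,
                window_cycles: int = DEFAULT_WINDOW_CYCLES,
                min_k: int = DEFAULT_MIN_K,
                scale: float = 10.0,
                pseudo: float = 1.0) -> dict[int, float]:
    """Per-position phasing score over combined-strand abundance."""
    if cycle < 2:
        raise ValueError(f"cycle must be >= 2, got {cycle}")
    if window_cycles < min_k:
        raise ValueError(
            f"window_cycles={window_cycles} must be >= min_k={min_k}")
    if positions is None:
        if not abundance:
            return {}
        positions = range(min(abundance), max(abundance) + 1)
    window = cycle * window_cycles
    scores: dict[int, float] = {}
    for p in positions:
        in_register = [abundance.get(p + i * cycle, 0.0)
                       for i in range(window_cycles)]
        P = sum(in_register)
        k = sum(1 for a in in_register if a > 0)
        U = sum(ab for pos, ab in abundance.items()
                if p <= pos < p + window) - P
        if k >= min_k:
            scores[p] = (k - 2) * math.log(1.0 + scale * P / (pseudo + U))
        else:
            scores[p] = 0.0
    return scores


@dataclass
class PhasingTrack:
    """Combined-strand abundance and phasing score along one locus."""

    locus_id: str
    combined_abundance: dict[int, float]
    phase_scores: dict[int, float]
    cycle: int = DEFAULT_CYCLE
    window_cycles: int = DEFAULT_WINDOW_CYCLES
    min_k: int = DEFAULT_MIN_K
    dropped_abundance: float = 0.0

    @property
    def max_score_position(self) -> int | None:
        if not self.phase_scores:
            return None
        return max(self.phase_scores, key=lambda p: (self.phase_scores[p], -p))

    def to_frame(self):
        import pandas as pd

        positions = sorted(set(self.combined_abundance) | set(self.phase_scores))
        return pd.DataFrame({
            "position": positions,
            "combined_abundance": [self.combined_abundance.get(p, 0.0)
                                   for p in positions],
            "phase_score": [self.phase_scores.get(p, 0.0) for p in positions],
        })


def build_track(locus_id: str,
                sense_starts: Mapping[int, float],
                antisense_starts: Mapping[int, float],
                cycle: int = DEFAULT_CYCLE,
                window_cycles: int = DEFAULT_WINDOW_CYCLES,
                min_k: int = DEFAULT_MIN_K,
                shift: int = DEFAULT_OVERHANG_SHIFT) -> PhasingTrack:
    """Strand-combine and score in one step."""
    combined, dropped = combine_strands(sense_starts, antisense_starts, shift)
    scores = phase_score(combined, cycle=cycle, window_cycles=window_cycles,
                         min_k=min_k)
    return PhasingTrack(locus_id, combined, scores, cycle, window_cycles,
                        min_k, dropped)


@dataclass
class LocusAbundance:
    """Per-position small-RNA abundance along a locus, transcript-oriented.

    ``sense``/``antisense`` hold raw counts keyed by the read's leftmost
    sense-axis position within the locus; ``rpm_total`` is the locus total
    normalized to the library's retained reads. ``trigger_pos`` marks an
    annotated trigger (miRNA-binding) site in the same coordinates.
    """

    locus_id: str
    library_id: str
    sense: dict[int, int] = field(default_factory=dict)
    antisense: dict[int, int] = field(default_factory=dict)
    rpm_total: float = 0.0
    trigger_pos: int | None = None

    @property
    def total_reads(self) -> int:
        return sum(self.sense.values()) + sum(self.antisense.values())

    def profile_rpm(self, library_total: int) -> dict[int, float]:
        out: dict[int, float] = {}
        for src in (self.sense, self.antisense):
            for p, c in src.items():
                out[p] = out.get(p, 0.0) + c * 1e6 / library_total
        return out


def locus_profile(locus: Interval, reads: ReadSet, index: ExactMatchIndex,
                  library_total: int | None = None) -> LocusAbundance:
    """Per-position abundance of reads whose hits fall within a locus.

    Positions are transcript-oriented and 0-based relative to the locus 5'
    end (for a '-' locus the axis is flipped so that position 0 is the
    transcript 5' end); each read registers at its leftmost covered
    position on the sense axis. Reads on the locus strand go to ``sense``,
    the others to ``antisense``. A ``trigger_pos`` attribute on the locus
    (genomic) is converted to the same transcript coordinates.
    """
    lengths = index.genome.lengths
    if locus.chrom not in lengths or locus.end > lengths[locus.chrom]:
        raise ValueError(
            f"locus {locus.name or locus.cls} outside genome")
    locus_strand = locus.strand if locus.strand in "+-" else "+"
    total = library_total if library_total is not None else reads.total_retained
    la = LocusAbundance(locus.name or f"{locus.chrom}:{locus.start}-{locus.end}",
                        reads.library_id)

    def to_transcript(start: int, end: int) -> int:
        # leftmost covered position on the transcript (sense) axis
        if locus_strand == "+":
            return start - locus.start
        return locus.end - end

    for seq, count in reads.counts.items():
        for hit in index.map(seq):
            if (hit.chrom == locus.chrom and hit.start >= locus.start
                    and hit.end <= locus.end):
                pos = to_transcript(hit.start, hit.end)
                target = la.sense if hit.strand == locus_strand else la.antisense
                target[pos] = target.get(pos, 0) + count
    la.rpm_total = la.total_reads * 1e6 / total if total else 0.0
    trig = locus.attrs.get("trigger_pos")
    if trig is not None:
        la.trigger_pos = (trig - locus.start if locus_strand == "+"
                          else locus.end - 1 - trig)
    return la


def tasirna_abundance(loci: list[Interval],
                      readsets: Mapping[str, ReadSet],
                      index: ExactMatchIndex,
                      library_totals: Mapping[str, int] | None = None):
    """Per-(locus, library) RPM totals — the ta-siRNA abundance comparison
    table ("relative read number ... normalized to total small RNAs")."""
    import pandas as pd

    rows = []
    for locus in loci:
        for lib, rs in readsets.items():
            total = library_totals[lib] if library_totals else None
            la = locus_profile(locus, rs, index, library_total=total)
            rows.append((la.locus_id, lib, la.total_reads, la.rpm_total))
    return pd.DataFrame(
        rows, columns=["locus_id", "library_id", "reads", "rpm_total"])
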