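"""Exact-match genome placement, structural-RNA removal, RPM normalization.

Perfect-match-only semantics: the original analysis used perfect genome
matches, and untemplated-tail detection depends on a read failing to map
exactly, so no mismatch tolerance is offered. A k-mer anchor table plus
verification gives the same hits as a naive full-genome scan for any query
of length >= k (oracle-tested).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from mirtail.refio import (
    IntervalSet,
    ReadSet,
    ReferenceGenome,
    ValidationError,
    revcomp,
)

DEFAULT_ANCHOR_K = 12


@dataclass(frozen=True, order=True)
class GenomicHit:
    """A perfect-match placement on forward-strand coordinates.

    For a '-' hit the query equals the reverse complement of
    genome[start:end].
    """

    chrom: str
    start: int
    end: int
    strand: str


class ExactMatchIndex:
    """k-mer anchor table over both strands of a reference genome.

    Anchors are the forward-genome k-mers; a query is searched in both
    orientations, so every genomic k-mer on either strand is retrievable.
    N-containing genome positions never enter the table, hence never match.
    """

    def __init__(self, genome: ReferenceGenome, k: int = DEFAULT_ANCHOR_K):
        if k < 1:
            raise ValueError(f"anchor k must be >= 1, got {k}")
        shortest = min(genome.lengths.values())
        if k > shortest:
            raise ValueError(
                f"anchor k={k} exceeds shortest chromosome ({shortest} nt)")
        self.genome = genome
        self.k = k
        table: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.sequences.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" in kmer:
                    continue
                table.setdefault(kmer, []).append((chrom, i))
        self._table = table

    def map(self, seq: str) -> list[GenomicHit]:
        """All perfect-match placements of ``seq`` on both strands,
        deterministically ordered by (chrom, start, strand)."""
        n = len(seq)
        if n < self.k:
            raise ValueError(
                f"query length {n} shorter than anchor k={self.k}")
        hits: list[GenomicHit] = []
        seqs = self.genome.sequences
        for (query, strand) in ((seq, "+"), (revcomp(seq), "-")):
            for chrom, off in self._table.get(query[:self.k], ()):
                if seqs[chrom][off:off + n] == query:
                    hits.append(GenomicHit(chrom, off, off + n, strand))
        hits.sort()
        return hits


def build_index(genome: ReferenceGenome, k: int = DEFAULT_ANCHOR_K) -> ExactMatchIndex:
    return ExactMatchIndex(genome, k)


def map_exact(seq: str, index: ExactMatchIndex) -> list[GenomicHit]:
    return index.map(seq)


class StructuralFilterResult(NamedTuple):
    retained: ReadSet
    removed_by_class: dict[str, int]


def filter_structural(reads: ReadSet, index: ExactMatchIndex,
                      structural: IntervalSet,
                      strand_specific: bool = False,
                      policy: str = "any") -> StructuralFilterResult:
    """Remove reads matching annotated structural RNAs (tRNA/rRNA/sn(o)RNA).

    A read is removed entirely when a perfect-match hit overlaps a
    structural interval by >= 1 nt. ``policy='any'`` (default) removes a
    read if ANY of its hits is structural — the conservative reading;
    ``policy='all'`` requires every hit to be structural. Overlap is
    strand-agnostic unless ``strand_specific``. Removed counts are tallied
    per structural class (a read overlapping several classes counts toward
    the first by sorted order). Reads with no genomic hit at all are
    retained: they may still decompose into head+tail downstream.
    """
    if policy not in ("any", "all"):
        raise ValueError(f"policy must be 'any' or 'all', got {policy!r}")
    retained = ReadSet(reads.library_id, total_input=reads.total_input,
                       n_length_filtered=reads.n_length_filtered,
                       n_ambiguous=reads.n_ambiguous)
    removed: dict[str, int] = {}
    for seq, count in reads.counts.items():
        hits = index.map(seq)
        overlaps = []
        for h in hits:
            strand = h.strand if strand_specific else None
            overlaps.append(structural.overlapping(h.chrom, h.start, h.end,
                                                   strand=strand))
        is_structural = [bool(o) for o in overlaps]
        if hits and (any(is_structural) if policy == "any"
                     else all(is_structural)):
            cls = sorted(iv.cls for o in overlaps for iv in o)[0]
            removed[cls] = removed.get(cls, 0) + count
        else:
            retained.counts[seq] = count
    return StructuralFilterResult(retained, removed)


def rpm(reads: ReadSet, denominator: int | None = None) -> dict[str, float]:
    """Reads-per-million per distinct sequence.

    The default denominator is the library's retained total (all reads
    surviving the structural filter, whether or not they map), matching
    normalization "to total small RNAs"; pass ``denominator`` to use a
    different total (e.g. mapped-only).
    """
    total = reads.total_retained if denominator is None else denominator
    if total <= 0:
        raise ValueError(f"library {reads.library_id!r} has no retained reads")
    return {seq: count * 1e6 / total for seq, count in reads.counts.items()}
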