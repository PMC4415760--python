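"""Head/tail decomposition and the truncation-tailing variant matrix.

The core procedure: a read that does not map perfectly to the genome is
trimmed one nucleotide at a time from its 3' end until the remaining 5'
prefix maps perfectly. That longest genome-mapped prefix is the "head";
the trimmed remainder is the untemplated "tail". Heads 5'-anchored on an
annotated mature miRNA are classified as (truncation, tailing) variants:
truncation X = nucleotides missing from the annotated 3' end, tailing
Y = untemplated nucleotides added. (0,0) is the exact mature species.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from mirtail.mapper import ExactMatchIndex, GenomicHit
from mirtail.refio import MirnaAnnotation, ReadSet

DEFAULT_MIN_HEAD = 15

_DNA2RNA = str.maketrans("T", "U")


def tail_as_rna(tail: str) -> str:
    """Render an internal DNA-alphabet tail in the RNA alphabet for reports."""
    return tail.translate(_DNA2RNA)


@dataclass(frozen=True)
class HeadTail:
    """A read split into genome-mapped head and untemplated tail.

    ``head + tail`` reconstructs the read exactly. ``status`` is
    ``mapped_full`` (empty tail), ``decomposed`` (non-empty tail), or
    ``unassignable`` (no prefix of length >= min_head maps; head holds the
    whole read and tail is empty by convention).
    """

    head: str
    tail: str
    hits: tuple[GenomicHit, ...]
    status: str

    @property
    def read(self) -> str:
        return self.head + self.tail


def decompose(seq: str, index: ExactMatchIndex,
              min_head: int = DEFAULT_MIN_HEAD) -> HeadTail:
    """Find the longest perfectly-mapping 5' prefix of ``seq``.

    Prefix lengths are tried from full length downward (equivalently:
    trimming one nt at a time from the 3' end until the remainder maps);
    the first success with length >= ``min_head`` wins, guaranteeing head
    maximality.
    """
    if len(seq) < min_head:
        raise ValueError(
            f"read of length {len(seq)} shorter than min_head={min_head}")
    if min_head < index.k:
        raise ValueError(
            f"min_head={min_head} must be >= anchor k={index.k}")
    for head_len in range(len(seq), min_head - 1, -1):
        head = seq[:head_len]
        hits = index.map(head)
        if hits:
            status = "mapped_full" if head_len == len(seq) else "decomposed"
            return HeadTail(head, seq[head_len:], tuple(hits), status)
    return HeadTail(seq, "", (), "unassignable")


@dataclass(frozen=True)
class MirnaVariant:
    """One read's classification against one annotated miRNA.

    ``truncation`` counts nucleotides missing from the mature 3' end; a
    negative value marks a genome-templated 3' extension (head longer than
    the mature sequence), which is excluded from the variant matrix proper.
    """

    mirna_id: str
    truncation: int
    tail_seq: str
    count: int

    @property
    def tail_len(self) -> int:
        return len(self.tail_seq)


def _head_five_prime(hit: GenomicHit) -> int:
    # Half-open convention: the 5' end of a '-' placement is `end`.
    return hit.start if hit.strand == "+" else hit.end


def assign(ht: HeadTail, annotations: list[MirnaAnnotation],
           count: int = 1) -> list[MirnaVariant]:
    """Assign a decomposed read to annotated miRNAs by 5'-anchored matching.

    A head matches an annotation when some hit lies on the annotation's
    chromosome and strand with the head's genomic 5' end coinciding exactly
    with the mature 5' end; 5'-shifted isomiRs are therefore never counted
    as truncation variants. A head matching n annotations yields n variants,
    each carrying the full read count (multi-family counting); one
    annotation yields at most one variant regardless of how many genomic
    hits support it.
    """
    if ht.status == "unassignable":
        return []
    variants: list[MirnaVariant] = []
    head_len = len(ht.head)
    for ann in annotations:
        for hit in ht.hits:
            if (hit.chrom == ann.chrom and hit.strand == ann.strand
                    and _head_five_prime(hit) == ann.five_prime):
                variants.append(MirnaVariant(
                    ann.mirna_id,
                    truncation=len(ann.mature_seq) - head_len,
                    tail_seq=ht.tail,
                    count=count))
                break
    return variants


@dataclass
class TruncTailMatrix:
    """Per-miRNA read abundance indexed by (nt truncated, nt tailed).

    ``cells`` holds counts keyed by (truncation >= 0, tail_len >= 0);
    ``tails`` retains the per-cell tail-sequence breakdown for composition
    analysis; ``excluded`` tallies templated-extension reads (negative
    truncation), which are not matrix cells.
    """

    mirna_id: str
    library_id: str = ""
    cells: dict[tuple[int, int], int] = field(default_factory=dict)
    tails: dict[tuple[int, int], Counter] = field(default_factory=dict)
    excluded: dict[int, int] = field(default_factory=dict)

    def add(self, variant: MirnaVariant) -> None:
        if variant.mirna_id != self.mirna_id:
            raise ValueError(
                f"variant for {variant.mirna_id!r} added to matrix for "
                f"{self.mirna_id!r}")
        if variant.truncation < 0:
            self.excluded[variant.truncation] = (
                self.excluded.get(variant.truncation, 0) + variant.count)
            return
        key = (variant.truncation, variant.tail_len)
        self.cells[key] = self.cells.get(key, 0) + variant.count
        if variant.tail_len:
            self.tails.setdefault(key, Counter())[variant.tail_seq] += (
                variant.count)

    @property
    def total(self) -> int:
        return sum(self.cells.values())

    @property
    def total_excluded(self) -> int:
        return sum(self.excluded.values())

    def margin_by_truncation(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for (t, _), c in self.cells.items():
            out[t] = out.get(t, 0) + c
        return out

    def margin_by_tail_len(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for (_, y), c in self.cells.items():
            out[y] = out.get(y, 0) + c
        return out

    def fractions(self) -> dict[tuple[int, int], float]:
        """Within-miRNA relative abundance per cell (the circle sizes of a
        bubble-matrix plot)."""
        total = self.total
        if total == 0:
            return {}
        return {k: c / total for k, c in self.cells.items()}


def build_matrix(variants: list[MirnaVariant], mirna_id: str,
                 library_id: str = "") -> TruncTailMatrix:
    """Aggregate variants of one miRNA into a truncation-tailing matrix."""
    m = TruncTailMatrix(mirna_id, library_id)
    for v in variants:
        m.add(v)
    return m


@dataclass
class LibraryProfile:
    """Per-library decomposition result: matrices plus read accounting."""

    library_id: str
    matrices: dict[str, TruncTailMatrix]
    headtails: dict[str, HeadTail]
    n_mapped_full: int = 0
    n_decomposed: int = 0
    n_unassignable: int = 0


def profile_library(reads: ReadSet, index: ExactMatchIndex,
                    annotations: list[MirnaAnnotation],
                    min_head: int = DEFAULT_MIN_HEAD) -> LibraryProfile:
    """Decompose every read of a library and build one matrix per miRNA."""
    matrices = {a.mirna_id: TruncTailMatrix(a.mirna_id, reads.library_id)
                for a in annotations}
    headtails: dict[str, HeadTail] = {}
    profile = LibraryProfile(reads.library_id, matrices, headtails)
    for seq, count in reads.counts.items():
        ht = decompose(seq, index, min_head)
        headtails[seq] = ht
        if ht.status == "mapped_full":
            profile.n_mapped_full += count
        elif ht.status == "decomposed":
            profile.n_decomposed += count
        else:
            profile.n_unassignable += count
            continue
        for variant in assign(ht, annotations, count=count):
            matrices[variant.mirna_id].add(variant)
    return profile


def matrix_table(matrices: dict[str, TruncTailMatrix],
                 library_total: int | None = None):
    """Long-format DataFrame (mirna, library, truncation, tail_len, count,
    rpm) — the interchange table for stats, phasing and plotting layers."""
    import pandas as pd

    rows = []
    for m in matrices.values():
        for (t, y), c in sorted(m.cells.items()):
            rpm_val = (c * 1e6 / library_total) if library_total else float("nan")
            rows.append((m.mirna_id, m.library_id, t, y, c, rpm_val))
    return pd.DataFrame(
        rows, columns=["mirna_id", "library_id", "truncation", "tail_len",
                       "count", "rpm"])
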