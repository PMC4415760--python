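"""Input parsing and the pipeline's core data model.

Internal conventions: DNA alphabet (U is converted to T on input; tails are
rendered back as U only in reports), 0-based half-open coordinates. File I/O
follows each format's native convention (GFF3 1-based inclusive, BED 0-based
half-open).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from intervaltree import IntervalTree

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_SEQ = re.compile(r"^[ACGTN]+$")

STRUCTURAL_CLASSES = ("tRNA", "rRNA", "snRNA", "snoRNA", "TAS", "target", "other")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """An input violates a documented invariant."""


@dataclass
class ReferenceGenome:
    """Chromosome name -> uppercase ACGTN sequence."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not _VALID_SEQ.match(seq):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ValidationError(
                    f"chromosome {name!r} contains invalid characters {bad}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Strand-adjusted substring; '-' returns the reverse complement."""
        seq = self.sequences[chrom]
        if not (0 <= start < end <= len(seq)):
            raise ValidationError(
                f"interval {chrom}:{start}-{end} outside chromosome (len {len(seq)})"
            )
        sub = seq[start:end]
        return revcomp(sub) if strand == "-" else sub


@dataclass(frozen=True)
class MirnaAnnotation:
    """A mature miRNA: identity, genomic locus, strand, and sequence.

    ``mature_seq`` is the strand-adjusted genome substring at
    ``chrom:[start, end)`` — the annotated mature species against which
    3'-truncation is measured.
    """

    mirna_id: str
    chrom: str
    strand: str
    start: int
    end: int
    mature_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.mirna_id}: strand must be + or -")
        if len(self.mature_seq) != self.end - self.start:
            raise ValidationError(
                f"{self.mirna_id}: sequence length {len(self.mature_seq)} != "
                f"interval length {self.end - self.start}"
            )

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the mature 5' end (half-open convention:
        start on '+', end on '-')."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class ReadRecord:
    """A distinct small-RNA sequence and its occurrence count in one library."""

    seq: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValidationError(f"read {self.seq}: count must be >= 1")


@dataclass
class ReadSet:
    """A collapsed small-RNA library: distinct sequence -> count.

    ``total_input`` is the raw read count before length/N filtering, so
    downstream accounting can conserve totals.
    """

    library_id: str
    counts: dict[str, int] = field(default_factory=dict)
    total_input: int = 0
    n_length_filtered: int = 0
    n_ambiguous: int = 0

    @property
    def records(self) -> list[ReadRecord]:
        return [ReadRecord(s, c) for s, c in sorted(self.counts.items())]

    @property
    def total_retained(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    strand: str = "."
    cls: str = "other"
    name: str = ""
    attrs: dict = field(default_factory=dict, hash=False, compare=False)

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"interval {self.name or self.chrom}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )


class IntervalSet:
    """Genomic intervals with fast overlap queries (per-chromosome trees)."""

    def __init__(self, intervals: Iterable[Interval] = (),
                 genome: ReferenceGenome | None = None):
        self.intervals: list[Interval] = list(intervals)
        if genome is not None:
            lengths = genome.lengths
            for iv in self.intervals:
                if iv.chrom not in lengths or iv.end > lengths[iv.chrom]:
                    raise ValidationError(
                        f"interval {iv.name or iv.cls} [{iv.start},{iv.end}) "
                        f"outside chromosome {iv.chrom}"
                    )
        self._trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, iv
            )

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def overlapping(self, chrom: str, start: int, end: int,
                    strand: str | None = None) -> list[Interval]:
        """Intervals overlapping [start, end) by >= 1 nt; strand-agnostic
        unless a strand is given (then '.' intervals still match)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(start, end)]
        if strand is not None:
            hits = [h for h in hits if h.strand in (".", strand)]
        return sorted(hits, key=lambda iv: (iv.start, iv.end, iv.cls))


# ---------------------------------------------------------------------------
# readers


def read_genome(path: str | Path) -> ReferenceGenome:
    """Parse a FASTA genome; sequences are uppercased, names must be unique."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValidationError(f"duplicate chromosome name {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not sequences:
        raise ValidationError(f"no FASTA records found in {path}")
    return ReferenceGenome(sequences)


def _parse_gff3_attrs(field9: str) -> dict[str, str]:
    attrs = {}
    for part in field9.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def _sniff_gff3(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return len(line.rstrip("\n").split("\t")) == 9
    return False


def read_mirna_annotations(path: str | Path,
                           genome: ReferenceGenome) -> list[MirnaAnnotation]:
    """Load mature-miRNA annotations from GFF3 or TSV.

    Both dialects carry 1-based inclusive coordinates; they are converted to
    0-based half-open. The mature sequence is extracted from the genome and,
    when the file provides a sequence column (TSV) , cross-checked against it.
    """
    path = Path(path)
    rows: list[tuple[str, str, str, int, int, str | None]] = []
    if _sniff_gff3(path):
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                attrs = _parse_gff3_attrs(f[8])
                mirna_id = attrs.get("Name") or attrs.get("ID")
                if mirna_id is None:
                    raise ValidationError(
                        f"GFF3 record without Name/ID attribute: {line.strip()}"
                    )
                rows.append((mirna_id, f[0], f[6], int(f[3]), int(f[4]),
                             attrs.get("sequence")))
    else:
        import pandas as pd

        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"mirna_id", "chrom", "strand", "start", "end"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"TSV missing columns: {sorted(missing)}")
        for row in df.itertuples(index=False):
            given = getattr(row, "mature_seq", None)
            rows.append((str(row.mirna_id), str(row.chrom), str(row.strand),
                         int(row.start), int(row.end),
                         None if given is None else str(given)))

    annotations: list[MirnaAnnotation] = []
    seen: set[str] = set()
    for mirna_id, chrom, strand, start1, end1, given in rows:
        if mirna_id in seen:
            raise ValidationError(f"duplicate mirna_id {mirna_id!r}")
        seen.add(mirna_id)
        start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
        if chrom not in genome.sequences:
            raise ValidationError(f"{mirna_id}: unknown chromosome {chrom!r}")
        mature = genome.fetch(chrom, start, end, strand)
        if given is not None:
            given_dna = given.upper().replace("U", "T")
            if given_dna != mature:
                raise ValidationError(
                    f"{mirna_id}: annotated sequence {given_dna} does not match "
                    f"genome substring {mature} at {chrom}:{start}-{end}({strand})"
                )
        annotations.append(
            MirnaAnnotation(mirna_id, chrom, strand, start, end, mature))
    return annotations


_COLLAPSED_HEADER = re.compile(r"^(?P<id>.*)_(?P<count>\d+)$")


def read_reads(path: str | Path, library_id: str | None = None,
               fmt: str = "auto", min_len: int = 15,
               max_len: int = 40) -> ReadSet:
    """Load a small-RNA library from FASTQ, FASTA, or collapsed FASTA.

    The collapsed dialect encodes the occurrence count as a ``_<count>``
    header suffix. Identical sequences are collapsed with summed counts.
    Reads outside [min_len, max_len] or containing N are discarded and
    tallied (the defaults mirror the 15-40 nt gel-purification window of
    small-RNA library construction). U is converted to T.
    """
    path = Path(path)
    if fmt == "auto":
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("@"):
            fmt = "fastq"
        elif first.startswith(">"):
            fmt = "fasta"
            headers = [rec.id for rec in SeqIO.parse(str(path), "fasta")]
            if headers and all(_COLLAPSED_HEADER.match(h) for h in headers):
                fmt = "collapsed"
        else:
            raise ValidationError(f"{path}: not FASTA or FASTQ")

    rs = ReadSet(library_id or path.stem)
    parse_fmt = "fastq" if fmt == "fastq" else "fasta"
    for rec in SeqIO.parse(str(path), parse_fmt):
        if fmt == "collapsed":
            m = _COLLAPSED_HEADER.match(rec.id)
            if m is None:
                raise ValidationError(
                    f"{path}: collapsed header {rec.id!r} lacks a numeric "
                    f"_<count> suffix"
                )
            count = int(m.group("count"))
        else:
            count = 1
        seq = str(rec.seq).upper().replace("U", "T")
        rs.total_input += count
        if not min_len <= len(seq) <= max_len:
            rs.n_length_filtered += count
            continue
        if "N" in seq or not _VALID_SEQ.match(seq):
            rs.n_ambiguous += count
            continue
        rs.counts[seq] = rs.counts.get(seq, 0) + count
    return rs


def write_collapsed_fasta(readset: ReadSet, path: str | Path,
                          prefix: str = "read") -> None:
    """Write a ReadSet in the collapsed dialect (``>id_count`` headers).

    Round-trips exactly with :func:`read_reads`.
    """
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(sorted(readset.counts.items()), 1):
            fh.write(f">{prefix}{i}_{count}\n{seq}\n")


def read_intervals(path: str | Path, genome: ReferenceGenome | None = None,
                   default_class: str = "other") -> IntervalSet:
    """Load intervals from BED (0-based half-open) or GFF3 (1-based inclusive).

    BED: columns chrom, start, end[, name, score, strand[, class]]; when no
    class column is present the name is used as the class if it is a known
    structural class, else ``default_class``. GFF3: the feature-type column
    is the class; a ``trigger`` attribute (1-based position) is surfaced in
    ``attrs['trigger_pos']`` as 0-based for phased-locus analysis.
    """
    path = Path(path)
    intervals: list[Interval] = []
    if _sniff_gff3(path):
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                attrs = _parse_gff3_attrs(f[8])
                extra = {}
                if "trigger" in attrs:
                    extra["trigger_pos"] = int(attrs["trigger"]) - 1
                intervals.append(Interval(
                    chrom=f[0], start=int(f[3]) - 1, end=int(f[4]),
                    strand=f[6], cls=f[2],
                    name=attrs.get("Name") or attrs.get("ID") or "",
                    attrs=extra))
    else:
        with open(path) as fh:
            for line in fh:
                if line.startswith(("#", "track", "browser")) or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                name = f[3] if len(f) > 3 else ""
                strand = f[5] if len(f) > 5 else "."
                if len(f) > 6:
                    cls = f[6]
                elif name in STRUCTURAL_CLASSES:
                    cls = name
                else:
                    cls = default_class
                intervals.append(Interval(
                    chrom=f[0], start=int(f[1]), end=int(f[2]),
                    strand=strand, cls=cls, name=name))
    return IntervalSet(intervals, genome=genome)
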