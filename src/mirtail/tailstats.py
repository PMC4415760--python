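"""Tailing statistics, abundance filters, and genotype comparisons.

The three headline proportions (all ratios of raw read counts, hence
scale-free):

* proportion tailed       = (tailed-only + truncated-and-tailed) / total
* tailing on full-length  = tailed-only / all full-length
* tailing on truncated    = truncated-and-tailed / all truncated

where "full-length" means truncation 0 and "tailed" means tail length >= 1.
Undefined ratios (empty denominators) propagate as missing (None), never
as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from mirtail.taildecomp import TruncTailMatrix, tail_as_rna

DEFAULT_RPM_THRESHOLD = 30.0
DEFAULT_DELTA_CUTOFF = 0.05


def prop_tailed(m: TruncTailMatrix) -> float | None:
    """Fraction of all reads of a miRNA carrying any untemplated tail."""
    total = m.total
    if total == 0:
        return None
    tailed = sum(c for (t, y), c in m.cells.items() if y >= 1)
    return tailed / total


def tailing_on_full_length(m: TruncTailMatrix) -> float | None:
    """Among full-length (truncation-0) reads, the fraction that is tailed."""
    full = {(t, y): c for (t, y), c in m.cells.items() if t == 0}
    denom = sum(full.values())
    if denom == 0:
        return None
    return sum(c for (t, y), c in full.items() if y >= 1) / denom


def tailing_on_truncated(m: TruncTailMatrix) -> float | None:
    """Among 3'-truncated reads, the fraction that is also tailed."""
    trunc = {(t, y): c for (t, y), c in m.cells.items() if t >= 1}
    denom = sum(trunc.values())
    if denom == 0:
        return None
    return sum(c for (t, y), c in trunc.items() if y >= 1) / denom


def tail_composition(tails: TruncTailMatrix | Iterable[tuple[str, int]],
                     ) -> tuple[dict[str, float], float] | None:
    """Per-nucleotide fractions over all tail positions, count-weighted.

    Accepts a matrix (uses its per-cell tail breakdown) or an iterable of
    (tail_seq, count). Returns (fractions keyed A/C/G/U, fraction of tailed
    reads whose tail is homopolymeric U), or None when no tails exist.
    """
    if isinstance(tails, TruncTailMatrix):
        pairs = [(seq, c) for counter in tails.tails.values()
                 for seq, c in counter.items()]
    else:
        pairs = [(s, c) for s, c in tails if s]
    total_positions = sum(len(s) * c for s, c in pairs)
    if total_positions == 0:
        return None
    comp = {nt: 0 for nt in "ACGT"}
    tailed_reads = 0
    poly_u_reads = 0
    for s, c in pairs:
        tailed_reads += c
        if set(s) == {"T"}:
            poly_u_reads += c
        for nt in s:
            comp[nt] += c
    fractions = {tail_as_rna(nt): n / total_positions
                 for nt, n in comp.items()}
    return fractions, poly_u_reads / tailed_reads


@dataclass
class TailingSummary:
    """Per-(miRNA, library) tailing profile."""

    mirna_id: str
    library_id: str
    prop_tailed: float | None
    tailing_on_full_length: float | None
    tailing_on_truncated: float | None
    total_reads: int
    total_rpm: float | None
    tail_nt_composition: dict[str, float] | None
    mono_tail_fraction: float | None


def summarize(m: TruncTailMatrix,
              library_total: int | None = None) -> TailingSummary:
    """Compute the full tailing summary of one matrix.

    ``library_total`` (retained reads in the library) enables total_rpm,
    which feeds the detection filter.
    """
    comp = tail_composition(m)
    tailed = sum(c for (t, y), c in m.cells.items() if y >= 1)
    mono = sum(c for (t, y), c in m.cells.items() if y == 1)
    return TailingSummary(
        mirna_id=m.mirna_id,
        library_id=m.library_id,
        prop_tailed=prop_tailed(m),
        tailing_on_full_length=tailing_on_full_length(m),
        tailing_on_truncated=tailing_on_truncated(m),
        total_reads=m.total,
        total_rpm=(m.total * 1e6 / library_total) if library_total else None,
        tail_nt_composition=comp[0] if comp else None,
        mono_tail_fraction=(mono / tailed) if tailed else None,
    )


def detection_filter(summaries_by_library: Mapping[str, Mapping[str, TailingSummary]],
                     threshold_rpm: float = DEFAULT_RPM_THRESHOLD) -> set[str]:
    """miRNAs reaching ``threshold_rpm`` (inclusive) in EVERY library.

    Mirrors the "detected at 30 reads per million or greater abundance in
    both libraries" criterion; a miRNA absent from any library is excluded.
    """
    if len(summaries_by_library) < 2:
        raise ValueError("detection filter needs >= 2 libraries")
    libs = list(summaries_by_library.values())
    candidates = set(libs[0])
    for lib in libs[1:]:
        candidates &= set(lib)
    kept = set()
    for mid in candidates:
        rpms = [summaries_by_library[lab][mid].total_rpm
                for lab in summaries_by_library]
        if all(r is not None and r >= threshold_rpm for r in rpms):
            kept.add(mid)
    return kept


@dataclass
class GenotypeComparison:
    """Signed deltas (library_b minus library_a) of the three statistics.

    Purely descriptive — the underlying study design is one library per
    genotype, so no inferential test is attached. ``reduced_tailing`` flags
    delta_prop_tailed <= -cutoff (an explicit artifact threshold, default
    0.05 absolute).
    """

    mirna_id: str
    library_a: str
    library_b: str
    delta_prop_tailed: float | None
    delta_full_length_tailing: float | None
    delta_truncated_tailing: float | None
    passes_detection_filter: bool = True
    reduced_tailing: bool | None = None


def _delta(a: float | None, b: float | None) -> float | None:
    if a is None or b is None:
        return None
    return b - a


def compare(a: TailingSummary, b: TailingSummary,
            threshold_rpm: float = DEFAULT_RPM_THRESHOLD,
            delta_cutoff: float = DEFAULT_DELTA_CUTOFF) -> GenotypeComparison:
    """Compare one miRNA's tailing between two libraries (genotypes)."""
    if a.mirna_id != b.mirna_id:
        raise ValueError(
            f"cannot compare {a.mirna_id!r} with {b.mirna_id!r}")
    d_prop = _delta(a.prop_tailed, b.prop_tailed)
    passes = (a.total_rpm is not None and b.total_rpm is not None
              and a.total_rpm >= threshold_rpm and b.total_rpm >= threshold_rpm)
    return GenotypeComparison(
        mirna_id=a.mirna_id,
        library_a=a.library_id,
        library_b=b.library_id,
        delta_prop_tailed=d_prop,
        delta_full_length_tailing=_delta(a.tailing_on_full_length,
                                         b.tailing_on_full_length),
        delta_truncated_tailing=_delta(a.tailing_on_truncated,
                                       b.tailing_on_truncated),
        passes_detection_filter=passes,
        reduced_tailing=None if d_prop is None else d_prop <= -delta_cutoff,
    )


def summary_table(summaries: Iterable[TailingSummary]):
    """Flat per-(miRNA, library) DataFrame of the tailing statistics."""
    import pandas as pd

    rows = []
    for s in summaries:
        comp = s.tail_nt_composition or {}
        rows.append({
            "mirna_id": s.mirna_id, "library_id": s.library_id,
            "total_reads": s.total_reads, "total_rpm": s.total_rpm,
            "prop_tailed": s.prop_tailed,
            "tailing_on_full_length": s.tailing_on_full_length,
            "tailing_on_truncated": s.tailing_on_truncated,
            "mono_tail_fraction": s.mono_tail_fraction,
            **{f"tail_frac_{nt}": comp.get(nt) for nt in "ACGU"},
        })
    return pd.DataFrame(rows)
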