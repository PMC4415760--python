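"""Synthetic small-RNA study generator with exact ground truth.

Emulates multi-genotype libraries from a methylation-deficient (hen1-like)
background: each miRNA molecule is 2'-O-methylated with some probability
(methylated molecules are fully protected — never truncated or tailed);
unmethylated molecules draw a 3'-truncation length, then pass through an
ordered cascade of nucleotidyl transferases. Two enzyme archetypes are
modeled:

* distributive mono-uridylation (URT1-like): adds exactly one U per acted
  molecule, with a strong preference for A-ending 3' termini;
* processive uridylation (HESO1-like): preferring U-ending termini, adds a
  tail of length 1 + Geometric(rho) without releasing the substrate.

Applied in order (distributive first, then processive) this reproduces the
sequential mono-uridylation-then-extension pattern: the distributive enzyme
converts the 3' end to U, which is the processive enzyme's preferred
substrate. Truncation is drawn independently of tailing.

The reference generator constrains mature sequences and their genomic
flanks so that a U tail can never coincide with a templated base, making
the (truncation, tail) ground truth exactly recoverable by the exact-match
decomposition pipeline. The expected (truncation, tail-length) distribution
of any regime is also available in closed form for recovery tests.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from mirtail.refio import (
    Interval,
    IntervalSet,
    MirnaAnnotation,
    ReadSet,
    ReferenceGenome,
    revcomp,
    write_collapsed_fasta,
)

DEFAULT_MAX_TRUNCATION = 5
DEFAULT_MIN_HEAD = 15


@dataclass
class EnzymeModel:
    """A nucleotidyl transferase acting on unmethylated 3' ends.

    ``preference`` maps the substrate's current 3' nucleotide (DNA
    alphabet) to the per-molecule probability of acting at all.
    Distributive mode adds exactly one ``nt_added``; processive mode, once
    engaged, adds 1 + Geometric(rho) nucleotides (support >= 1,
    mean 1/(1-rho)).
    """

    name: str
    mode: str  # "distributive_mono" | "processive"
    preference: dict[str, float]
    nt_added: str = "T"
    rho: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("distributive_mono", "processive"):
            raise ValueError(f"unknown enzyme mode {self.mode!r}")
        if not all(0.0 <= p <= 1.0 for p in self.preference.values()):
            raise ValueError(f"{self.name}: preferences must be in [0,1]")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"{self.name}: rho must be in [0,1)")

    def p_act(self, three_prime_nt: str) -> float:
        return self.preference.get(three_prime_nt, 0.0)


def urt1_like(p_a: float = 0.4, p_u: float = 0.15, p_c: float = 0.1,
              p_g: float = 0.1) -> EnzymeModel:
    """Distributive mono-uridylase preferring A-ending substrates."""
    return EnzymeModel("URT1", "distributive_mono",
                       {"A": p_a, "T": p_u, "C": p_c, "G": p_g})


def heso1_like(p_u: float = 0.5, p_g: float = 0.2, p_a: float = 0.08,
               p_c: float = 0.05, rho: float = 0.5) -> EnzymeModel:
    """Processive uridylase preferring U-ending substrates."""
    return EnzymeModel("HESO1", "processive",
                       {"T": p_u, "G": p_g, "A": p_a, "C": p_c}, rho=rho)


DEFAULT_TRUNCATION_DIST = (0.55, 0.2, 0.1, 0.08, 0.05, 0.02)
DEFAULT_METHYLATED_FRACTION = 0.1  # hen1-8 is a partial loss-of-function allele


@dataclass
class GenotypeRegime:
    """One genotype's generative parameters."""

    label: str
    methylated_fraction: float = DEFAULT_METHYLATED_FRACTION
    truncation_distribution: tuple[float, ...] = DEFAULT_TRUNCATION_DIST
    active_enzymes: tuple[EnzymeModel, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.methylated_fraction <= 1.0:
            raise ValueError("methylated_fraction must be in [0,1]")
        s = sum(self.truncation_distribution)
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"truncation distribution sums to {s}, not 1")


def hen1_regime(**kw) -> GenotypeRegime:
    """hen1-like background: both enzymes active (distributive first)."""
    return GenotypeRegime("hen1", active_enzymes=(urt1_like(), heso1_like()),
                          **kw)


def hen1_urt1_regime(**kw) -> GenotypeRegime:
    """Distributive enzyme knocked out; processive still active."""
    return GenotypeRegime("hen1 urt1", active_enzymes=(heso1_like(),), **kw)


def hen1_heso1_regime(**kw) -> GenotypeRegime:
    """Processive enzyme knocked out; distributive still active."""
    return GenotypeRegime("hen1 heso1", active_enzymes=(urt1_like(),), **kw)


def wildtype_regime() -> GenotypeRegime:
    """Full methylation protection: every molecule is the mature species."""
    return GenotypeRegime("wildtype", methylated_fraction=1.0,
                          truncation_distribution=(1.0,),
                          active_enzymes=(urt1_like(), heso1_like()))


def expected_variant_distribution(regime: GenotypeRegime, mature_seq: str,
                                  max_tail: int = 30,
                                  ) -> dict[tuple[int, int], float]:
    """Closed-form expected (truncation, tail_len) distribution.

    Computed by propagating the (tail length, current 3' nucleotide)
    state distribution through the enzyme cascade; tail lengths beyond
    ``max_tail`` are folded into the last length (negligible mass at
    default rho).
    """
    L = len(mature_seq)
    out: dict[tuple[int, int], float] = Counter()
    m = regime.methylated_fraction
    if m > 0:
        out[(0, 0)] += m
    for t, q_t in enumerate(regime.truncation_distribution):
        if q_t == 0 or m == 1.0:
            continue
        start_nt = mature_seq[L - t - 1]
        # state: (tail_len, 3' nt) -> prob
        state: dict[tuple[int, str], float] = {(0, start_nt): 1.0}
        for enz in regime.active_enzymes:
            nxt: Counter = Counter()
            for (y, nt), prob in state.items():
                p = enz.p_act(nt)
                if prob * p > 0:
                    if enz.mode == "distributive_mono":
                        nxt[(min(y + 1, max_tail), enz.nt_added)] += prob * p
                    else:  # processive: length 1 + Geometric(rho)
                        rho = enz.rho
                        for l in range(1, max_tail - y):
                            nxt[(y + l, enz.nt_added)] += (
                                prob * p * (1 - rho) * rho ** (l - 1))
                        nxt[(max_tail, enz.nt_added)] += (
                            prob * p * rho ** (max_tail - y - 1))
                nxt[(y, nt)] += prob * (1 - p)
            state = dict(nxt)
        for (y, _), prob in state.items():
            out[(t, y)] += (1 - m) * q_t * prob
    return dict(out)


@dataclass
class MirnaSpec:
    """Design of one embedded miRNA locus."""

    mirna_id: str
    length: int
    end_nt: str  # the annotated 3'-terminal nucleotide (DNA alphabet)


@dataclass
class SimReference:
    """A generated toy study reference with full locus bookkeeping."""

    genome: ReferenceGenome
    annotations: list[MirnaAnnotation]
    structural: IntervalSet
    tas_loci: list[Interval]
    seed: int

    def annotation(self, mirna_id: str) -> MirnaAnnotation:
        for a in self.annotations:
            if a.mirna_id == mirna_id:
                return a
        raise KeyError(mirna_id)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit genome FASTA, miRNA GFF3, structural BED and locus GFF3 —
        exactly the formats the refio readers consume."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "mirnas": out / "mirnas.gff3",
            "structural": out / "structural.bed",
            "loci": out / "loci.gff3",
        }
        with open(paths["genome"], "w") as fh:
            for chrom, seq in self.genome.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
        with open(paths["mirnas"], "w") as fh:
            fh.write("##gff-version 3\n")
            for a in self.annotations:
                fh.write(f"{a.chrom}\tmirtail_sim\tmiRNA\t{a.start + 1}\t"
                         f"{a.end}\t.\t{a.strand}\t.\t"
                         f"ID={a.mirna_id};Name={a.mirna_id}\n")
        with open(paths["structural"], "w") as fh:
            for iv in self.structural:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.cls}\t0\t"
                         f"{iv.strand if iv.strand in '+-' else '+'}\n")
        with open(paths["loci"], "w") as fh:
            fh.write("##gff-version 3\n")
            for iv in self.tas_loci:
                trig = iv.attrs.get("trigger_pos")
                attr = f"ID={iv.name};Name={iv.name}"
                if trig is not None:
                    attr += f";trigger={trig + 1}"
                fh.write(f"{iv.chrom}\tmirtail_sim\tTAS\t{iv.start + 1}\t"
                         f"{iv.end}\t.\t{iv.strand}\t.\t{attr}\n")
        return paths


def _count_occurrences(genome_seq: str, pattern: str) -> int:
    n, start = 0, 0
    while True:
        i = genome_seq.find(pattern, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def generate_reference(seed: int, n_mirnas: int = 3, n_structural: int = 2,
                       n_tas_loci: int = 1, genome_len: int = 20_000,
                       mirna_specs: list[MirnaSpec] | None = None,
                       max_truncation: int = DEFAULT_MAX_TRUNCATION,
                       min_head: int = DEFAULT_MIN_HEAD,
                       cycle: int = 21, n_cycles: int = 10,
                       chrom: str = "chr1",
                       max_retries: int = 50) -> SimReference:
    """Build a toy genome hosting miRNA, structural-RNA and phased loci.

    Mature miRNA sequences are embedded uniquely: the ``min_head``-length
    5' prefix of each mature sequence occurs exactly once genome-wide
    (both strands), so decomposition is unambiguous. The last
    ``max_truncation`` internal nucleotides of each mature sequence and
    the 8 genomic bases downstream of each locus avoid T, so an
    untemplated U tail is never absorbed as a templated match at any
    reachable truncation state.
    """
    if mirna_specs is None:
        lengths = [20, 22, 21]
        ends = ["A", "C", "G"]
        mirna_specs = [
            MirnaSpec(f"miR-sim{i + 1}", lengths[i % 3], ends[i % 3])
            for i in range(n_mirnas)
        ]
    flank = 8
    struct_len = 80
    tas_len = cycle * (n_cycles + 2) + 40
    need = (sum(s.length + flank for s in mirna_specs)
            + n_structural * struct_len + n_tas_loci * tas_len)
    if need * 3 > genome_len:
        raise ValueError(
            f"genome_len={genome_len} too small to host all loci; "
            f"need roughly >= {need * 3}")

    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    non_t = np.array(list("ACG"))
    cg = np.array(list("CG"))

    for _ in range(max_retries):
        genome_arr = rng.choice(alphabet, size=genome_len)
        occupied: list[tuple[int, int]] = []

        def place(length: int) -> int:
            for _ in range(200):
                pos = int(rng.integers(0, genome_len - length))
                if all(pos + length + 4 <= s or pos >= e + 4
                       for s, e in occupied):
                    occupied.append((pos, pos + length))
                    return pos
            raise RuntimeError(
                "could not place a locus; increase genome_len")

        # miRNA loci ('+' strand): mature seq + non-T flank downstream
        mirna_pos: list[tuple[MirnaSpec, int, str]] = []
        for spec in mirna_specs:
            body = rng.choice(alphabet, size=spec.length)
            tail_zone = min(max_truncation, spec.length - 1)
            body[-tail_zone - 1:-1] = rng.choice(non_t, size=tail_zone)
            body[-1] = spec.end_nt
            mature = "".join(body)
            pos = place(spec.length + flank)
            genome_arr[pos:pos + spec.length] = list(mature)
            genome_arr[pos + spec.length:pos + spec.length + flank] = (
                rng.choice(cg, size=flank))
            mirna_pos.append((spec, pos, mature))

        structural_ivs = []
        classes = ["tRNA", "rRNA", "snRNA", "snoRNA"]
        for i in range(n_structural):
            pos = place(struct_len)
            structural_ivs.append(Interval(chrom, pos, pos + struct_len, "+",
                                           classes[i % len(classes)],
                                           name=f"{classes[i % len(classes)]}-{i + 1}"))
        tas_loci = []
        for i in range(n_tas_loci):
            pos = place(tas_len)
            trigger = pos + 20
            tas_loci.append(Interval(chrom, pos, pos + tas_len, "+", "TAS",
                                     name=f"TAS-sim{i + 1}",
                                     attrs={"trigger_pos": trigger}))

        genome_seq = "".join(genome_arr)
        rc = revcomp(genome_seq)
        ok = all(
            _count_occurrences(genome_seq, mature[:min_head])
            + _count_occurrences(rc, mature[:min_head]) == 1
            for _, _, mature in mirna_pos
        )
        if ok:
            genome = ReferenceGenome({chrom: genome_seq})
            annotations = [
                MirnaAnnotation(spec.mirna_id, chrom, "+", pos,
                                pos + spec.length, mature)
                for spec, pos, mature in mirna_pos
            ]
            return SimReference(genome, annotations,
                                IntervalSet(structural_ivs, genome=genome),
                                tas_loci, seed)
    raise RuntimeError(
        f"failed to build a collision-free reference in {max_retries} tries; "
        f"increase genome_len")


@dataclass
class SimTruth:
    """Per-library ground truth: provenance of every simulated molecule and
    the closed-form expected distribution per miRNA."""

    library_id: str
    seed: int
    expected: dict[str, dict[tuple[int, int], float]]
    molecules: list[tuple[str, bool, int, str]]  # (mirna, methylated, trunc, tail)

    def observed(self, mirna_id: str) -> Counter:
        """Empirical (truncation, tail_len) counts for one miRNA."""
        c: Counter = Counter()
        for mid, _, t, tail in self.molecules:
            if mid == mirna_id:
                c[(t, len(tail))] += 1
        return c

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.molecules,
            columns=["mirna_id", "methylated", "truncation", "tail_seq"])


def _apply_enzymes(seq_3nt: str, enzymes: tuple[EnzymeModel, ...],
                   rng: np.random.Generator) -> str:
    tail = ""
    nt = seq_3nt
    for enz in enzymes:
        if rng.random() < enz.p_act(nt):
            if enz.mode == "distributive_mono":
                tail += enz.nt_added
            else:
                length = int(rng.geometric(1.0 - enz.rho))
                tail += enz.nt_added * length
            nt = enz.nt_added
    return tail


def simulate_library(regime: GenotypeRegime, reference: SimReference,
                     n_reads: int, seed: int,
                     mirna_weights: dict[str, float] | None = None,
                     structural_read_fraction: float = 0.0,
                     error_rate: float = 0.0,
                     ) -> tuple[ReadSet, SimTruth]:
    """Draw one genotype's library molecule by molecule.

    Each molecule picks a miRNA (uniform unless weighted), draws
    methylation, truncation and the enzyme cascade, and is emitted as a
    read. Optionally a fraction of extra reads is sampled from structural
    intervals (exact 21-mers) to exercise the structural filter.
    ``error_rate`` applies uniform per-base substitutions to the emitted
    reads; it defaults to 0 because the analysis pipeline is exact-match
    (an erroneous base usually renders a read unassignable).
    """
    rng = np.random.default_rng(seed)
    anns = reference.annotations
    ids = [a.mirna_id for a in anns]
    if mirna_weights is None:
        w = np.full(len(ids), 1.0 / len(ids))
    else:
        w = np.array([mirna_weights.get(i, 0.0) for i in ids], dtype=float)
        w = w / w.sum()
    mature = {a.mirna_id: a.mature_seq for a in anns}
    trunc_p = np.array(regime.truncation_distribution)

    n_structural = int(round(n_reads * structural_read_fraction))
    n_mirna = n_reads - n_structural

    rs = ReadSet(regime.label)
    molecules: list[tuple[str, bool, int, str]] = []
    choices = rng.choice(len(ids), size=n_mirna, p=w)
    for idx in choices:
        mid = ids[int(idx)]
        mseq = mature[mid]
        if rng.random() < regime.methylated_fraction:
            methylated, trunc, tail = True, 0, ""
        else:
            methylated = False
            trunc = int(rng.choice(len(trunc_p), p=trunc_p))
            tail = _apply_enzymes(mseq[len(mseq) - trunc - 1],
                                  regime.active_enzymes, rng)
        read = mseq[:len(mseq) - trunc] + tail
        if error_rate:
            bases = list(read)
            for j in range(len(bases)):
                if rng.random() < error_rate:
                    bases[j] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(bases)
        rs.counts[read] = rs.counts.get(read, 0) + 1
        molecules.append((mid, methylated, trunc, tail))

    if n_structural:
        ivs = list(reference.structural)
        chrom_seq = reference.genome.sequences
        for _ in range(n_structural):
            iv = ivs[int(rng.integers(0, len(ivs)))]
            start = int(rng.integers(iv.start, iv.end - 21))
            read = chrom_seq[iv.chrom][start:start + 21]
            rs.counts[read] = rs.counts.get(read, 0) + 1
    rs.total_input = rs.total_retained

    expected = {mid: expected_variant_distribution(regime, mature[mid])
                for mid in ids}
    return rs, SimTruth(regime.label, seed, expected, molecules)


def simulate_phased_locus(reference: SimReference, locus: Interval,
                          seed: int, cycle: int = 21, n_cycles: int = 9,
                          per_cycle_abundance: int | list[int] = 20,
                          offregister_fraction: float = 0.0,
                          library_id: str = "phased",
                          ) -> tuple[ReadSet, dict]:
    """Generate phased duplex reads downstream of a locus trigger site.

    Register i (i = 1..n_cycles) places a sense read at
    trigger + i*cycle and its duplex partner — antisense, 2-nt 3'
    overhangs on both ends — covering sense coordinates
    [start - 2, start + cycle - 2). All reads lie strictly 3' of the
    trigger. ``offregister_fraction`` of molecules are displaced by a
    random 1..cycle-1 offset. Only '+'-strand loci are supported.
    """
    if locus.strand not in ("+", "."):
        raise ValueError("simulate_phased_locus supports '+'-strand loci")
    trigger = locus.attrs.get("trigger_pos")
    if trigger is None:
        raise ValueError("locus has no trigger_pos attribute")
    if trigger + (n_cycles + 1) * cycle > locus.end:
        raise ValueError("locus too short for requested cycles")
    rng = np.random.default_rng(seed)
    seq = reference.genome.sequences[locus.chrom]
    if isinstance(per_cycle_abundance, int):
        per_cycle = [per_cycle_abundance] * n_cycles
    else:
        per_cycle = list(per_cycle_abundance)
        if len(per_cycle) != n_cycles:
            raise ValueError("per_cycle_abundance length != n_cycles")

    rs = ReadSet(library_id)
    n_off = 0
    registers = [trigger + i * cycle for i in range(1, n_cycles + 1)]
    for s, a in zip(registers, per_cycle):
        for _ in range(a):
            start = s
            if offregister_fraction and rng.random() < offregister_fraction:
                start = s + int(rng.integers(1, cycle))
                n_off += 1
            sense = seq[start:start + cycle]
            anti = revcomp(seq[start - 2:start + cycle - 2])
            for read in (sense, anti):
                rs.counts[read] = rs.counts.get(read, 0) + 1
    rs.total_input = rs.total_retained
    truth = {
        "locus_id": locus.name,
        "origin_transcript": registers[0] - locus.start,
        "registers_transcript": [s - locus.start for s in registers],
        "cycle": cycle,
        "n_offregister": n_off,
        "n_molecules": sum(per_cycle),
    }
    return rs, truth


def write_library(readset: ReadSet, truth: SimTruth | None,
                  out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated library (collapsed FASTA) and its truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    safe = readset.library_id.replace(" ", "_")
    paths = {"reads": out / f"reads_{safe}.fa"}
    write_collapsed_fasta(readset, paths["reads"])
    if truth is not None:
        paths["truth"] = out / f"truth_{safe}.tsv"
        truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
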