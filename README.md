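# mirtail

Small-RNA 3′ truncation/tailing profiling for plant-style miRNA turnover
studies, with phased secondary-siRNA (phasiRNA) register analysis and a
generative library simulator.

In plants, 2′-*O*-methylation of the 3′-terminal ribose protects miRNAs and
siRNAs from 3′ truncation (exonucleolytic nibbling) and 3′ tailing (addition
of untemplated nucleotides, mostly uridines, by nucleotidyl transferases).
In methylation-deficient backgrounds, miRNA populations become mixtures of
truncated, tailed, and truncated-and-tailed species. Sequencing such
libraries and asking *which* enzyme tails *which* form of each miRNA
requires separating the genome-templated part of every read from its
untemplated 3′ addition. `mirtail` implements that analysis end to end for
anyone profiling small-RNA 3′-end modification: library loading, exact-match
genome placement, structural-RNA filtering, head/tail decomposition, variant
matrices, tailing statistics, genotype contrasts, and phasing analysis.

## The method

**Head/tail decomposition.** A read that maps perfectly to the genome is
unmodified. A read that does not is trimmed one nucleotide at a time from
its 3′ end until the remainder maps perfectly: the longest genome-mapped 5′
prefix is the *head*, the trimmed remainder is the untemplated *tail*
(minimum head 15 nt by default). Matching is exact on both strands via an
in-package k-mer anchor index with a brute-force-equivalent contract.

**Variant matrices.** A head whose genomic 5′ end coincides with an
annotated mature miRNA 5′ end is classified by the coordinates
(X, Y) = (nucleotides truncated from the mature 3′ end, nucleotides
tailed on). (0,0) is the exact mature species; e.g. (1,1) is a 1-nt
truncated, 1-nt tailed form. Per-miRNA counts over (X, Y) form the
truncation–tailing matrix.

**Tailing statistics.** For each miRNA and library:

- proportion tailed = (tailed-only + truncated-and-tailed) / total reads,
- tailing on full-length = tailed-only / all full-length reads,
- tailing on truncated = truncated-and-tailed / all truncated reads,

plus tail nucleotide composition and the mono-tail fraction. Genotype
comparisons report signed deltas of these proportions for miRNAs detected
at ≥ 30 reads per million (RPM) in every library.

**Phasing.** Secondary siRNAs produced in 21-nt phase from a cleaved
transcript are detected by combining antisense abundance onto sense
registers under the Dicer 2-nt 3′-overhang convention (sense-axis start
+ 2) and scoring each register position p over a 9-cycle window:
score(p) = (k − 2) · ln(1 + 10·P/(1 + U)), where P is the in-register
abundance, U the off-register abundance, and k the number of occupied
registers (score 0 when k < 3).

**Simulator.** `mirtail.simdata` generates a toy genome with uniquely
embedded miRNA, structural-RNA and phased loci, then draws libraries from
genotype regimes built on two enzyme archetypes: a distributive
mono-uridylase preferring A-ending 3′ termini (URT1-like) and a processive
uridylase preferring U-ending termini (HESO1-like, tail length
1 + Geometric(ρ)), with per-molecule methylation protection and independent
truncation. Every regime's expected (X, Y) distribution is also available
in closed form, so pipeline recovery is testable cell by cell.

## Worked example

```bash
python examples/02_tailing_statistics.py
```

simulates the same miRNA under the double-enzyme regime and the
distributive-knockout regime and prints, among other lines:

```
=== hen1 (8000 reads of miR-sim1) ===
proportion tailed:        0.339
tailing on full-length:   0.375
tailing on truncated:     0.286
tail U fraction:          1.000

=== hen1 urt1 (8000 reads of miR-sim1) ===
proportion tailed:        0.060
```

Read: with both enzymes active, a third of all miR-sim1 reads carry an
untemplated tail, full-length molecules are tailed slightly more often than
truncated ones, and every tail nucleotide is U. Removing the distributive
mono-uridylase collapses the proportion tailed to 6%, the signature of an
enzyme that initiates most tailing on this A-ending miRNA. The other
examples show single-read decomposition (`01`), phasing-score tracks
(`03`), and the file-based end-to-end pipeline (`04`).

The same pipeline is scriptable from the shell:

```bash
mirtail simulate --seed 3 --out study/     # synthetic 2-genotype study
mirtail run -c study/study.yaml            # full pipeline, TSV + JSON out
mirtail stats study/results/matrices.tsv   # tailing statistics layer only
```

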