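# Methods

## Model and procedure

`mirtail` analyses small-RNA libraries from genomes where 3′-end
modification is informative — canonically, plant methylation-deficient
(*hen1*-like) backgrounds in which unprotected miRNAs are 3′-truncated by
exonucleases and 3′-tailed by nucleotidyl transferases. The pipeline's
stages and their contracts:

1. **Loading** (`refio`). Genome FASTA; mature miRNA annotations (GFF3 or
   TSV, 1-based inclusive on disk, 0-based half-open in memory; the mature
   sequence is always re-extracted from the genome and cross-checked
   against any provided sequence); structural-RNA and locus intervals
   (BED/GFF3); reads as FASTQ, FASTA, or collapsed FASTA with `_count`
   header suffixes. Reads outside the 15–40 nt window (the gel-purification
   range of standard small-RNA library construction) or containing N are
   discarded and tallied. The internal alphabet is DNA; U is converted to T
   on input and tails are rendered as U only in reports.

2. **Placement** (`mapper`). Exact-match-only placement on both strands via
   a k-mer anchor table (default k = 12) with full verification; for any
   query ≥ k nt the hits provably equal a brute-force sliding-window scan
   (property-tested against that oracle). No mismatch tolerance is offered:
   untemplated-tail detection is defined by exact-match failure. A read
   with ≥ 1 hit overlapping a structural interval (tRNA/rRNA/sn(o)RNA; any
   overlap ≥ 1 nt, strand-agnostic by default) is removed entirely;
   removals are tallied per class. RPM normalization divides by the
   library's retained total (all reads surviving the structural filter),
   i.e. "total small RNAs"; a mapped-only denominator is available by
   argument.

3. **Decomposition** (`taildecomp`). Prefix lengths are tried from the full
   read downward; the first mapping prefix of length ≥ `min_head`
   (default 15 nt, ≥ the anchor k) is the head. This is equivalent to
   trimming one nucleotide at a time from the 3′ end and guarantees head
   maximality, which is asserted against an exhaustive oracle. A tail
   nucleotide that coincides with the templated genomic base downstream is
   absorbed into the head by this rule — an inherent property of the
   longest-prefix definition that under-calls tailing at coincidence
   positions (see Simulator).

4. **Assignment.** A head is assigned to a miRNA when a hit lies on the
   annotation's strand with the head's genomic 5′ end equal to the mature
   5′ end (5′-anchored matching; truncation is a 3′-end coordinate, so the
   5′ end must be fixed, and 5′-shifted isomiRs are deliberately not
   counted as truncation variants). Truncation = mature length − head
   length. Heads longer than the mature sequence (genome-templated 3′
   extensions, truncation < 0) are tallied in the matrix's `excluded`
   field, never as cells. A head matching several annotations contributes
   its full count to each (family-style joint reporting); per annotation,
   a read is counted once regardless of hit multiplicity.

5. **Statistics** (`tailstats`). All three tailing proportions are ratios
   of raw counts and thus invariant under library scaling; RPM enters only
   through the detection filter (≥ 30 RPM in every library, inclusive) and
   abundance reports. Undefined ratios (0/0) propagate as missing values,
   never 0. Genotype contrasts are descriptive signed deltas — the design
   is one library per genotype, so no test statistic is attached; the
   `reduced_tailing` flag uses an explicit cutoff (|Δ proportion tailed|
   ≥ 0.05) that is a package decision, not an inherited definition.

6. **Phasing** (`phasing`). Antisense start-position abundance (keyed by
   leftmost sense-axis coordinate) is shifted +2 before summation with
   sense starts — the unique shift placing both strands of an equal-length
   Dicer duplex with 2-nt 3′ overhangs on one register. The score at
   position p is (k − 2)·ln(1 + 10·P/(1 + U)) over a window of
   `window_cycles` (9) cycles of `cycle` (21) nt, zero when fewer than
   `min_k` (3) registers are occupied; every constant is an argument.
   Scores are computed on raw counts by default (they compare positions
   within one library); locus abundance tables are RPM-normalized. Reads
   of length ≠ cycle contribute by their start position.

## Simulator

`simdata` emulates the study design the pipeline targets: multi-genotype
libraries with genotype-specific tailing regimes and a phased locus.

*Generative model per molecule:* methylation ~ Bernoulli(m); methylated
molecules are emitted as the exact mature sequence (full protection).
Otherwise truncation t is drawn from an explicit distribution
(independently of tailing), then an ordered enzyme cascade acts on the
current 3′ nucleotide: a distributive enzyme adds exactly one U with
probability `preference[3′ nt]`; a processive enzyme engages with
probability `preference[3′ nt]` and adds 1 + Geometric(ρ) uridines
(support ≥ 1, mean 1/(1 − ρ)). Applying distributive-then-processive
reproduces sequential mono-uridylation followed by extension, because the
mono-U intermediate ends in U — the processive enzyme's preferred
substrate.

*Defaults* (chosen once as a plausible partial-loss-of-methylation
background; per-figure in-vivo distributions are not published as numbers,
so these are declared parameters, not estimates): m = 0.1; truncation
distribution (0.55, 0.2, 0.1, 0.08, 0.05, 0.02) over 0–5 nt; distributive
preference {A: 0.4, U: 0.15, C: 0.1, G: 0.1}; processive preference
{U: 0.5, G: 0.2, A: 0.08, C: 0.05}, ρ = 0.5. Regime constructors provide
the genotype contrasts: both enzymes (`hen1_regime`), distributive-null
(`hen1_urt1_regime`), processive-null (`hen1_heso1_regime`), and full
protection (`wildtype_regime`, m = 1).

*Reference construction.* Mature sequences (defaults: a 20-mer ending in
A, a 22-mer ending in C, a 21-mer ending in G, exercising both enzymes'
preferences) are embedded at non-overlapping positions in a random genome
(default 20 kb) such that (i) each mature 15-nt 5′ prefix occurs exactly
once genome-wide counting both strands — verified by exhaustive scan with
rejection/retry — and (ii) the last `max_truncation` internal nucleotides
and the 8 bases downstream of each locus contain no T. Property (i) makes
head placement unambiguous; property (ii) means a U tail can never be
extended by a templated match from any reachable truncation state, so the
simulated (truncation, tail) labels are recovered *exactly* by the
pipeline, enabling cell-by-cell recovery tests. Real genomes satisfy
neither property — templated-coincidence positions under-call tailing
there, and multi-mapping heads occur — so passing recovery tests
demonstrates correctness of the algorithm, not absence of these
genome-dependent ambiguities.

*Phased locus.* Register i (i = 1..n) places a sense 21-mer at
trigger + i·cycle and its duplex partner covering sense coordinates
[start − 2, start + cycle − 2); a configurable fraction of molecules is
displaced off-register. Phased-locus simulation supports '+'-strand loci
(analysis of '−'-strand loci is supported; only their simulation is not).

*What the simulator does not model:* AGO loading and competition,
degradation kinetics downstream of tailing, exosome trimming, sequencing
error (an optional uniform substitution rate exists but defaults to 0
because the analysis is exact-match), adapter artifacts, and expression
heterogeneity beyond the per-miRNA weight vector.

*Expected distributions in closed form.* For any regime the expected
(truncation, tail length) distribution is computed by propagating the
(tail length, current 3′ nucleotide) state through the cascade; processive
tail mass beyond length 30 is folded into the last bin (≤ ρ³⁰ ≈ 10⁻⁹ at
default ρ). Simulated frequencies match within 3 binomial standard errors
for all cells with ≥ 1% mass, and the full pipeline reproduces the
simulated truth cell by cell (both asserted in the test suite).

## Numerical and design choices

- Determinism: all randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); regenerating a reference or library with
  the same seed is byte-identical, and pipeline runs on identical inputs
  produce byte-identical tables (timestamps live only in the report JSON).
- Tie-breaks: hits are ordered by (chrom, start, end, strand); the phasing
  maximum position breaks score ties toward the smaller coordinate.
- Degenerate inputs: empty matrices yield missing statistics; an empty
  library is an error for RPM; negative strand-combine shifts are dropped
  with a tally rather than wrapped.
- Configuration: every constant of consequence (min_head 15, read window
  15–40, anchor k 12, RPM threshold 30, cycle 21, window 9 cycles,
  min_k 3, overhang shift 2, delta cutoff 0.05) is surfaced in
  `PipelineConfig`, validated, logged in the report, and hashed into every
  output header.
- Problem sizes: tests and the acceptance script use a 20-kb toy genome,
  1,000 oracle reads, and libraries of 2,000–10,000 molecules — sizes at
  which the binomial tolerances above are meaningful and the whole suite
  runs in seconds.

## Known limitations

- Exact-match-only placement cannot use reads crossing assembly errors or
  SNVs; on real data a read with a 5′-proximal variant is unassignable.
- 5′ isomiRs are excluded by design (5′-anchored assignment); internal
  editing is not detected.
- The quantitative tailing landscape of real mutants depends on parameters
  (enzyme action probabilities, truncation spectrum, methylated fraction)
  that the simulator declares rather than estimates; only directional
  contrasts between regimes, not absolute levels, should be read as
  biology.
- Low-complexity reads are not specially filtered; a homopolymeric read
  that happens to match the genome is processed like any other.
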