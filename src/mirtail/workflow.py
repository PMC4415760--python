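"""End-to-end pipeline orchestration: configuration, run report, outputs.

A run is deterministic given identical inputs and configuration; every
tabular output is plain TSV with a header comment carrying the
configuration hash, and the report JSON records all decision-relevant
parameters.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import mirtail
from mirtail import refio, mapper, taildecomp, tailstats, phasing, simdata


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration.

    ``libraries`` maps genotype label -> reads path; the first entry is the
    comparison baseline. All tunables carry their pipeline defaults:
    min_head 15 nt, read window 15-40 nt, anchor k 12, detection threshold
    30 RPM, phasing cycle 21 nt over a 9-cycle window with min_k 3,
    2-nt overhang shift, comparison cutoff 0.05.
    """

    genome: str = ""
    mirna_annotations: str = ""
    libraries: dict[str, str] = field(default_factory=dict)
    structural: str | None = None
    loci: str | None = None
    out_dir: str = "mirtail_out"
    min_head: int = taildecomp.DEFAULT_MIN_HEAD
    min_len: int = 15
    max_len: int = 40
    anchor_k: int = mapper.DEFAULT_ANCHOR_K
    rpm_threshold: float = tailstats.DEFAULT_RPM_THRESHOLD
    delta_cutoff: float = tailstats.DEFAULT_DELTA_CUTOFF
    cycle: int = phasing.DEFAULT_CYCLE
    window_cycles: int = phasing.DEFAULT_WINDOW_CYCLES
    min_k: int = phasing.DEFAULT_MIN_K
    overhang_shift: int = phasing.DEFAULT_OVERHANG_SHIFT
    structural_policy: str = "any"
    structural_strand_specific: bool = False
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.anchor_k < 8:
            raise ValueError(f"anchor_k must be >= 8, got {self.anchor_k}")
        if self.min_head < self.anchor_k:
            raise ValueError(
                f"min_head={self.min_head} must be >= anchor_k={self.anchor_k}")
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("need 0 < min_len <= max_len")
        if self.min_len < self.min_head:
            raise ValueError(
                f"min_len={self.min_len} below min_head={self.min_head}: "
                f"such reads could never decompose")
        if self.rpm_threshold < 0:
            raise ValueError("rpm_threshold must be >= 0")
        if self.cycle < 2 or self.window_cycles < self.min_k:
            raise ValueError("invalid phasing parameters")
        if self.structural_policy not in ("any", "all"):
            raise ValueError("structural_policy must be 'any' or 'all'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def params_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mirtail {mirtail.__version__} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


@dataclass
class RunReport:
    """Everything a run produced, in memory plus on disk."""

    accounting: pd.DataFrame
    summaries: pd.DataFrame
    comparisons: pd.DataFrame
    detected: set[str]
    matrices: dict[str, dict[str, taildecomp.TruncTailMatrix]]
    tracks: dict[tuple[str, str], phasing.PhasingTrack]
    tasirna: pd.DataFrame | None
    out_paths: dict[str, Path]
    provenance: dict


def run(config: PipelineConfig) -> RunReport:
    """Execute the full pipeline and write all stage outputs."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.params_hash()

    genome = refio.read_genome(config.genome)
    annotations = refio.read_mirna_annotations(config.mirna_annotations, genome)
    structural = (refio.read_intervals(config.structural, genome=genome)
                  if config.structural else refio.IntervalSet())
    loci = (list(refio.read_intervals(config.loci, genome=genome))
            if config.loci else [])
    index = mapper.build_index(genome, k=config.anchor_k)

    accounting_rows = []
    summaries_by_lib: dict[str, dict[str, tailstats.TailingSummary]] = {}
    matrices: dict[str, dict[str, taildecomp.TruncTailMatrix]] = {}
    retained_sets: dict[str, refio.ReadSet] = {}
    library_totals: dict[str, int] = {}

    for label, path in config.libraries.items():
        reads = refio.read_reads(path, library_id=label,
                                 min_len=config.min_len,
                                 max_len=config.max_len)
        retained, removed = mapper.filter_structural(
            reads, index, structural,
            strand_specific=config.structural_strand_specific,
            policy=config.structural_policy)
        retained_sets[label] = retained
        library_totals[label] = retained.total_retained
        profile = taildecomp.profile_library(
            retained, index, annotations, min_head=config.min_head)
        matrices[label] = profile.matrices
        summaries_by_lib[label] = {
            mid: tailstats.summarize(m, library_total=retained.total_retained)
            for mid, m in profile.matrices.items()
        }
        accounting_rows.append({
            "library_id": label,
            "total_input": reads.total_input,
            "length_filtered": reads.n_length_filtered,
            "ambiguous": reads.n_ambiguous,
            "structural_removed": sum(removed.values()),
            **{f"removed_{cls}": n for cls, n in sorted(removed.items())},
            "retained": retained.total_retained,
            "mapped_full": profile.n_mapped_full,
            "decomposed": profile.n_decomposed,
            "unassignable": profile.n_unassignable,
        })

    accounting = pd.DataFrame(accounting_rows).fillna(0)
    summaries = tailstats.summary_table(
        s for lib in summaries_by_lib.values() for s in lib.values())

    labels = list(config.libraries)
    detected: set[str] = set()
    comparison_rows = []
    if len(labels) >= 2:
        detected = tailstats.detection_filter(
            summaries_by_lib, threshold_rpm=config.rpm_threshold)
        baseline = labels[0]
        for other in labels[1:]:
            for mid in sorted(summaries_by_lib[baseline]):
                if mid not in summaries_by_lib[other]:
                    continue
                c = tailstats.compare(summaries_by_lib[baseline][mid],
                                      summaries_by_lib[other][mid],
                                      threshold_rpm=config.rpm_threshold,
                                      delta_cutoff=config.delta_cutoff)
                comparison_rows.append(asdict(c))
    comparisons = pd.DataFrame(comparison_rows)

    tracks: dict[tuple[str, str], phasing.PhasingTrack] = {}
    tasirna = None
    if loci:
        for locus in loci:
            for label, rs in retained_sets.items():
                la = phasing.locus_profile(
                    locus, rs, index, library_total=library_totals[label])
                tracks[(la.locus_id, label)] = phasing.build_track(
                    la.locus_id, la.sense, la.antisense,
                    cycle=config.cycle, window_cycles=config.window_cycles,
                    min_k=config.min_k, shift=config.overhang_shift)
        tasirna = phasing.tasirna_abundance(
            loci, retained_sets, index, library_totals=library_totals)

    out_paths = {
        "accounting": out / "accounting.tsv",
        "summaries": out / "summaries.tsv",
        "matrices": out / "matrices.tsv",
        "comparisons": out / "comparisons.tsv",
        "report": out / "report.json",
    }
    _write_tsv(accounting, out_paths["accounting"], cfg_hash)
    _write_tsv(summaries, out_paths["summaries"], cfg_hash)
    matrix_frames = [
        taildecomp.matrix_table(mats, library_total=library_totals[label])
        for label, mats in matrices.items()
    ]
    _write_tsv(pd.concat(matrix_frames, ignore_index=True)
               if matrix_frames else pd.DataFrame(),
               out_paths["matrices"], cfg_hash)
    _write_tsv(comparisons, out_paths["comparisons"], cfg_hash)
    if tracks:
        track_frames = []
        for (locus_id, label), tr in tracks.items():
            df = tr.to_frame()
            df.insert(0, "library_id", label)
            df.insert(0, "locus_id", locus_id)
            track_frames.append(df)
        out_paths["phasing"] = out / "phasing_tracks.tsv"
        _write_tsv(pd.concat(track_frames, ignore_index=True),
                   out_paths["phasing"], cfg_hash)
    if tasirna is not None:
        out_paths["tasirna"] = out / "tasirna_abundance.tsv"
        _write_tsv(tasirna, out_paths["tasirna"], cfg_hash)

    provenance = {
        "version": mirtail.__version__,
        "config_hash": cfg_hash,
        "parameters": {k: v for k, v in asdict(config).items()
                       if k not in ("simulate",)},
        "detected_mirnas": sorted(detected),
        "elapsed_s": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(out_paths["report"], "w") as fh:
        json.dump(provenance, fh, indent=2)
    return RunReport(accounting, summaries, comparisons, detected, matrices,
                     tracks, tasirna, out_paths, provenance)


_REGIME_FACTORIES = {
    "hen1": simdata.hen1_regime,
    "hen1_urt1": simdata.hen1_urt1_regime,
    "hen1_heso1": simdata.hen1_heso1_regime,
    "wildtype": simdata.wildtype_regime,
}

DEFAULT_SIMULATION = {
    "seed": 0,
    "genome_len": 20_000,
    "n_mirnas": 3,
    "n_structural": 2,
    "n_tas_loci": 1,
    "n_reads": 5_000,
    "structural_read_fraction": 0.05,
    "genotypes": [
        {"label": "hen1-8", "kind": "hen1", "phased_per_cycle": 20},
        {"label": "hen1-8 urt1-1", "kind": "hen1_urt1", "phased_per_cycle": 5},
    ],
}


def simulate(config: PipelineConfig) -> PipelineConfig:
    """Write a complete synthetic study, immediately consumable by run().

    Returns a new PipelineConfig pointing at the generated files; the same
    config is also written as study.yaml in the output directory. Each
    genotype library combines miRNA reads under its tailing regime,
    structural-RNA background, and phased-locus duplex reads (the per-cycle
    abundance differing by genotype emulates reduced secondary-siRNA
    production when mono-uridylation is lost).
    """
    sim = {**DEFAULT_SIMULATION, **config.simulate}
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(sim["seed"])
    reference = simdata.generate_reference(
        seed, n_mirnas=sim["n_mirnas"], n_structural=sim["n_structural"],
        n_tas_loci=sim["n_tas_loci"], genome_len=sim["genome_len"],
        min_head=config.min_head, cycle=config.cycle)
    ref_paths = reference.write(out)

    libraries: dict[str, str] = {}
    for i, g in enumerate(sim["genotypes"]):
        kind = g.get("kind", "hen1")
        if kind not in _REGIME_FACTORIES:
            raise ValueError(f"unknown regime kind {kind!r}")
        regime = _REGIME_FACTORIES[kind]()
        regime.label = g.get("label", kind)
        reads, truth = simdata.simulate_library(
            regime, reference, int(sim["n_reads"]), seed + 1 + i,
            structural_read_fraction=float(sim["structural_read_fraction"]))
        for locus in reference.tas_loci:
            phased, _ = simdata.simulate_phased_locus(
                reference, locus, seed + 101 + i, cycle=config.cycle,
                per_cycle_abundance=int(g.get("phased_per_cycle", 20)),
                library_id=regime.label)
            for s, c in phased.counts.items():
                reads.counts[s] = reads.counts.get(s, 0) + c
            reads.total_input = reads.total_retained
        paths = simdata.write_library(reads, truth, out)
        libraries[regime.label] = str(paths["reads"])

    study = PipelineConfig(
        genome=str(ref_paths["genome"]),
        mirna_annotations=str(ref_paths["mirnas"]),
        structural=str(ref_paths["structural"]),
        loci=str(ref_paths["loci"]),
        libraries=libraries,
        out_dir=str(out / "results"),
        min_head=config.min_head, min_len=config.min_len,
        max_len=config.max_len, anchor_k=config.anchor_k,
        rpm_threshold=config.rpm_threshold, delta_cutoff=config.delta_cutoff,
        cycle=config.cycle, window_cycles=config.window_cycles,
        min_k=config.min_k, overhang_shift=config.overhang_shift)
    with open(out / "study.yaml", "w") as fh:
        yaml.safe_dump({k: v for k, v in asdict(study).items()
                        if k != "simulate"}, fh, sort_keys=False)
    return study
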