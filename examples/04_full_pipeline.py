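"""End-to-end study: simulate a two-genotype experiment, then run the
pipeline from files exactly as the CLI would.

Writes a study directory (genome FASTA, miRNA GFF3, structural BED, locus
GFF3, collapsed-FASTA libraries, ground-truth TSVs), runs every stage, and
prints the read accounting, the per-miRNA comparisons, and the ta-siRNA
abundance table.
"""

import tempfile

from mirtail import workflow

with tempfile.TemporaryDirectory() as tmp:
    cfg = workflow.PipelineConfig(out_dir=tmp)
    cfg.simulate = {"seed": 9, "n_reads": 5000}
    study = workflow.simulate(cfg)      # writes all input files + study.yaml
    report = workflow.run(study)        # reads them back and runs everything

    print("=== read accounting ===")
    print(report.accounting.to_string(index=False))
    print(f"\nmiRNAs passing the 30-RPM dual-library filter: "
          f"{sorted(report.detected)}")
    print("\n=== genotype comparison (baseline: first library) ===")
    cols = ["mirna_id", "delta_prop_tailed", "delta_full_length_tailing",
            "delta_truncated_tailing", "reduced_tailing"]
    print(report.comparisons[cols].to_string(index=False))
    print("\n=== ta-siRNA locus abundance (RPM) ===")
    print(report.tasirna.to_string(index=False))

print("\nNegative deltas mean the second genotype tails less; the phased")
print("locus loses abundance in the distributive-enzyme knockout while")
print("its phasing register is unchanged.")
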