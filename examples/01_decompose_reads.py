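"""Head/tail decomposition of small-RNA reads on a toy genome.

Builds a seeded reference, fabricates a few reads (exact, uridylated,
truncated+uridylated, unmappable), and shows how each is split into its
genome-templated head and untemplated tail.
"""

from mirtail import mapper, simdata, taildecomp
from mirtail.taildecomp import tail_as_rna

reference = simdata.generate_reference(seed=1)
index = mapper.build_index(reference.genome)
mirna = reference.annotations[0]
mature = mirna.mature_seq

reads = {
    "exact mature": mature,
    "mono-uridylated": mature + "T",
    "tri-uridylated": mature + "TTT",
    "2-nt truncated + UU tail": mature[:-2] + "TT",
    "random (unmappable)": "TGAGCCTAGCTTAGCATG",
}

print(f"miRNA {mirna.mirna_id}: {mature} ({len(mature)} nt, "
      f"{mirna.chrom}:{mirna.start}-{mirna.end}{mirna.strand})\n")
for label, read in reads.items():
    ht = taildecomp.decompose(read, index)
    variants = taildecomp.assign(ht, reference.annotations)
    coord = (f"({variants[0].truncation},{variants[0].tail_len})"
             if variants else "-")
    print(f"{label:28s} status={ht.status:12s} head={len(ht.head):2d} nt "
          f"tail={tail_as_rna(ht.tail) or '-':4s} variant={coord}")

print("\nThe (X,Y) coordinates count nucleotides truncated from (X) and")
print("tailed onto (Y) the annotated mature 3' end; (0,0) is the exact")
print("mature species, and an unmappable read yields no head at all.")
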