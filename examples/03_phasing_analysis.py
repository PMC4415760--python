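"""Phasing-score analysis of a simulated phased siRNA locus.

Simulates Dicer-style duplex reads (21-nt, 2-nt 3' overhangs) downstream
of a trigger site, combines strands under the overhang convention, and
scores 21-nt register phasing along the locus.
"""

from mirtail import mapper, phasing, simdata

reference = simdata.generate_reference(seed=1)
index = mapper.build_index(reference.genome)
locus = reference.tas_loci[0]

reads, truth = simdata.simulate_phased_locus(
    reference, locus, seed=4, per_cycle_abundance=15,
    offregister_fraction=0.1)

profile = phasing.locus_profile(locus, reads, index)
track = phasing.build_track(profile.locus_id, profile.sense,
                            profile.antisense)

print(f"locus {profile.locus_id}: {profile.total_reads} reads "
      f"({sum(profile.sense.values())} sense / "
      f"{sum(profile.antisense.values())} antisense)")
print(f"trigger site at transcript position {profile.trigger_pos}")
print(f"true phase origin: {truth['origin_transcript']}")
print(f"max phasing score: {max(track.phase_scores.values()):.2f} "
      f"at position {track.max_score_position}\n")

print("pos  abundance  score")
for p in sorted(track.combined_abundance):
    print(f"{p:4d}  {track.combined_abundance[p]:9.0f}  "
          f"{track.phase_scores.get(p, 0.0):6.2f}")

print("\nAbundance concentrates at 21-nt registers downstream of the")
print("trigger; the phasing score peaks at the true register origin even")
print("with 10% of molecules displaced off-register.")
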