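import math

import numpy as np
import pytest

from mirtail import mapper, refio, simdata, taildecomp
from mirtail.simdata import (
    EnzymeModel,
    GenotypeRegime,
    expected_variant_distribution,
    generate_reference,
    hen1_heso1_regime,
    hen1_regime,
    hen1_urt1_regime,
    simulate_library,
    wildtype_regime,
)


class TestGenerateReference:
    def test_seeded_determinism_byte_identical(self, tmp_path):
        a = generate_reference(seed=42)
        b = generate_reference(seed=42)
        assert a.genome.sequences == b.genome.sequences
        assert a.annotations == b.annotations
        (tmp_path / "a").mkdir(), (tmp_path / "b").mkdir()
        pa, pb = a.write(tmp_path / "a"), b.write(tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes()

    def test_annotations_validate_against_genome(self, sim_reference):
        for a in sim_reference.annotations:
            assert a.mature_seq == sim_reference.genome.fetch(
                a.chrom, a.start, a.end, a.strand)

    def test_mature_prefixes_unique_genome_wide(self, sim_reference):
        """Every mature 15-mer prefix occurs exactly once, counting both
        strands — the guarantee behind unambiguous decomposition."""
        seq = sim_reference.genome.sequences["chr1"]
        rc = refio.revcomp(seq)
        for a in sim_reference.annotations:
            prefix = a.mature_seq[:15]
            n = sum(seq[i:i + 15] == prefix for i in range(len(seq) - 14))
            n += sum(rc[i:i + 15] == prefix for i in range(len(rc) - 14))
            assert n == 1

    def test_written_files_round_trip_through_refio(self, sim_reference,
                                                    tmp_path):
        paths = sim_reference.write(tmp_path)
        genome = refio.read_genome(paths["genome"])
        anns = refio.read_mirna_annotations(paths["mirnas"], genome)
        assert anns == sim_reference.annotations
        structural = refio.read_intervals(paths["structural"], genome=genome)
        assert len(structural) == len(sim_reference.structural)
        loci = list(refio.read_intervals(paths["loci"], genome=genome))
        assert loci[0].attrs["trigger_pos"] == (
            sim_reference.tas_loci[0].attrs["trigger_pos"])

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError, match="genome_len"):
            generate_reference(seed=0, genome_len=500)


class TestRegimes:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            EnzymeModel("x", "weird", {"A": 0.5})
        with pytest.raises(ValueError):
            EnzymeModel("x", "processive", {"A": 1.5})
        with pytest.raises(ValueError):
            GenotypeRegime("g", truncation_distribution=(0.5, 0.4))

    def test_expected_distribution_sums_to_one(self):
        for regime in (hen1_regime(), hen1_urt1_regime(), hen1_heso1_regime(),
                       wildtype_regime()):
            dist = expected_variant_distribution(regime, "GGCTCGAAGTCGTA" + "CGGTCA")
            assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_distributive_only_closed_form(self):
        """One distributive enzyme, no truncation: P(0,1) = p(end nt)."""
        regime = GenotypeRegime("d", methylated_fraction=0.0,
                                truncation_distribution=(1.0,),
                                active_enzymes=(simdata.urt1_like(p_a=0.4),))
        dist = expected_variant_distribution(regime, "C" * 19 + "A")
        assert dist[(0, 1)] == pytest.approx(0.4)
        assert dist[(0, 0)] == pytest.approx(0.6)

    def test_sequential_cascade_closed_form(self):
        """Distributive then processive: the mono-U intermediate (now
        U-ending) feeds the processive enzyme, so P(0,1) =
        p1 * (1 - p2(U)) and tails >= 2 exist only via the cascade."""
        p1, p2, rho = 0.4, 0.5, 0.5
        regime = GenotypeRegime(
            "seq", methylated_fraction=0.0, truncation_distribution=(1.0,),
            active_enzymes=(
                EnzymeModel("d", "distributive_mono", {"A": p1}),
                EnzymeModel("p", "processive", {"T": p2}, rho=rho),
            ))
        dist = expected_variant_distribution(regime, "C" * 19 + "A")
        assert dist[(0, 0)] == pytest.approx(1 - p1)
        assert dist[(0, 1)] == pytest.approx(p1 * (1 - p2))
        # tail length 1 + l, l ~ Geometric(rho): P = p1*p2*(1-rho)*rho^(l-1)
        assert dist[(0, 2)] == pytest.approx(p1 * p2 * (1 - rho))
        assert dist[(0, 3)] == pytest.approx(p1 * p2 * (1 - rho) * rho)


class TestSimulateLibrary:
    def test_seeded_determinism(self, sim_reference):
        a, _ = simulate_library(hen1_regime(), sim_reference, 500, seed=3)
        b, _ = simulate_library(hen1_regime(), sim_reference, 500, seed=3)
        assert a.counts == b.counts

    def test_full_methylation_only_mature_species(self, sim_reference):
        reads, truth = simulate_library(wildtype_regime(), sim_reference,
                                        400, seed=1)
        matures = {a.mature_seq for a in sim_reference.annotations}
        assert set(reads.counts) <= matures
        for a in sim_reference.annotations:
            obs = truth.observed(a.mirna_id)
            assert set(obs) <= {(0, 0)}

    def test_closed_form_matches_simulation_within_3se(self, sim_reference):
        """Simulated cell frequencies match the analytic expectation within
        3 binomial standard errors for every cell with >= 1% mass."""
        regime = hen1_regime()
        _, truth = simulate_library(regime, sim_reference, 9_000, seed=17)
        for a in sim_reference.annotations:
            obs = truth.observed(a.mirna_id)
            n = sum(obs.values())
            for cell, p in truth.expected[a.mirna_id].items():
                if p < 0.01:
                    continue
                se = math.sqrt(p * (1 - p) / n)
                assert abs(obs[cell] / n - p) <= 3 * se, (a.mirna_id, cell)

    def test_sequential_enzyme_signature(self, sim_reference):
        """Both enzymes: mass at (0, >=2) exceeds the distributive-only
        regime; distributive-only: (0,1) is the modal tailed cell."""
        def frac(truth, mid, pred):
            obs = truth.observed(mid)
            n = sum(obs.values())
            return sum(c for cell, c in obs.items() if pred(cell)) / n

        _, both = simulate_library(hen1_regime(), sim_reference, 6000, seed=2)
        _, dist_only = simulate_library(hen1_heso1_regime(), sim_reference,
                                        6000, seed=2)
        mid = sim_reference.annotations[0].mirna_id
        assert (frac(both, mid, lambda c: c[0] == 0 and c[1] >= 2)
                > frac(dist_only, mid, lambda c: c[0] == 0 and c[1] >= 2))
        tailed = {c: n for c, n in dist_only.observed(mid).items() if c[1] >= 1}
        assert max(tailed, key=tailed.get) == (0, 1)

    def test_error_rate_perturbs_reads(self, sim_reference):
        clean, _ = simulate_library(wildtype_regime(), sim_reference, 300,
                                    seed=6)
        noisy, _ = simulate_library(wildtype_regime(), sim_reference, 300,
                                    seed=6, error_rate=0.05)
        matures = {a.mature_seq for a in sim_reference.annotations}
        assert set(clean.counts) <= matures
        assert set(noisy.counts) - matures  # some reads carry substitutions
        assert noisy.total_retained == 300

    def test_structural_reads_are_filtered_out(self, sim_reference,
                                               sim_index):
        reads, _ = simulate_library(hen1_regime(), sim_reference, 1000,
                                    seed=4, structural_read_fraction=0.2)
        res = mapper.filter_structural(reads, sim_index,
                                       sim_reference.structural)
        assert sum(res.removed_by_class.values()) == 200
        assert res.retained.total_retained == 800


class TestPipelineRecovery:
    def test_end_to_end_cellwise_recovery(self, sim_reference, sim_index):
        """refio -> mapper -> taildecomp reproduces the simulated
        (truncation, tail) truth distribution cell by cell."""
        regime = hen1_regime()
        reads, truth = simulate_library(regime, sim_reference, 4000, seed=8)
        profile = taildecomp.profile_library(reads, sim_index,
                                             sim_reference.annotations)
        for a in sim_reference.annotations:
            assert dict(profile.matrices[a.mirna_id].cells) == dict(
                truth.observed(a.mirna_id))
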