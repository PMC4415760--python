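"""Shared fixtures: a hand-built toy genome and a seeded simulated study."""

import pytest

from mirtail import mapper, refio, simdata


@pytest.fixture(scope="session")
def toy_genome() -> refio.ReferenceGenome:
    # 60 nt, hand-designed: positions 10..30 host a 20-mer "mature" sequence
    # ending in A, followed by C/G-only flank so a T tail is never templated.
    mature = "GATTCAGGCTCGAAGTCGTA"
    assert len(mature) == 20 and mature.endswith("A")
    seq = "CCGTACGGTC" + mature + "CGGCCGCGGC" + "ATATGGCCTTAGCAATCCGG"
    return refio.ReferenceGenome({"chr1": seq})


@pytest.fixture(scope="session")
def toy_mature(toy_genome) -> str:
    return toy_genome.fetch("chr1", 10, 30)


@pytest.fixture(scope="session")
def toy_annotation(toy_mature) -> refio.MirnaAnnotation:
    return refio.MirnaAnnotation("miR-toy", "chr1", "+", 10, 30, toy_mature)


@pytest.fixture(scope="session")
def toy_index(toy_genome) -> mapper.ExactMatchIndex:
    return mapper.build_index(toy_genome, k=8)


@pytest.fixture(scope="session")
def sim_reference() -> simdata.SimReference:
    return simdata.generate_reference(seed=11)


@pytest.fixture(scope="session")
def sim_index(sim_reference) -> mapper.ExactMatchIndex:
    return mapper.build_index(sim_reference.genome)


def brute_force_decompose(seq: str, genome: refio.ReferenceGenome,
                          min_head: int = 15):
    """Independent oracle: the longest prefix of ``seq`` (>= min_head)
    occurring anywhere in the genome on either strand, by exhaustive
    substring search. Returns (head_len, status) with head_len None when
    unassignable."""
    strands = [s for s in genome.sequences.values()]
    strands += [refio.revcomp(s) for s in genome.sequences.values()]
    for head_len in range(len(seq), min_head - 1, -1):
        prefix = seq[:head_len]
        if any(prefix in s for s in strands):
            status = "mapped_full" if head_len == len(seq) else "decomposed"
            return head_len, status
    return None, "unassignable"
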