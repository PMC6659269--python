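"""Shared fixtures: tiny deterministic genomes and alignment scenarios."""

from __future__ import annotations

import numpy as np
import pytest

from splicemap import (
    Read,
    ReadBatch,
    Reference,
    ReferenceSet,
    ScoringScheme,
)

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int, at: float = 0.5) -> str:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(list(BASES), size=length, p=p))


def mutate(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in BASES if b != base]
    return choices[int(rng.integers(3))]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture
def small_genome(rng) -> ReferenceSet:
    return ReferenceSet([Reference("chr1", random_dna(rng, 5000))])


def make_intron_genome(
    rng: np.random.Generator,
    exon1: int = 60,
    intron: int = 120,
    exon2: int = 60,
    donor: str = "GT",
    acceptor: str = "AG",
    flank: int = 200,
):
    """Genome with one two-exon gene; returns (reference, transcript
    sequence, exon/intron coordinates)."""
    seq = list(random_dna(rng, flank + exon1 + intron + exon2 + flank))
    e1s = flank
    e1e = e1s + exon1
    i_s = e1e
    i_e = i_s + intron
    e2s = i_e
    e2e = e2s + exon2
    seq[i_s : i_s + 2] = list(donor)
    seq[i_e - 2 : i_e] = list(acceptor)
    # keep the boundary unambiguous: bases just inside the intron must not
    # let the junction slide at equal score
    for k in (1, 2, 3):
        if seq[i_s + 1 + k] == seq[i_e + k - 1]:
            seq[i_s + 1 + k] = mutate(seq[i_s + 1 + k], rng)
    genome = ReferenceSet([Reference("chr1", "".join(seq))])
    tx = genome["chr1"][e1s:e1e] + genome["chr1"][e2s:e2e]
    coords = {"exon1": (e1s, e1e), "intron": (i_s, i_e), "exon2": (e2s, e2e)}
    return genome, tx, coords


def batch_of(*seqs: str, paired: bool = False) -> ReadBatch:
    return ReadBatch([Read(f"r{i}", s) for i, s in enumerate(seqs)], paired=paired)
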