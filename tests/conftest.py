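import random

import pytest

from primerval import (
    Lineage,
    PrimerPair,
    ReferenceRecord,
    load_default_primer_panel,
)

BASES = "ACGT"


def make_lineage(phylum="Nematoda", family="Rhabditidae", genus=None,
                 species=None, **extra):
    ranks = {"phylum": phylum, "family": family}
    if genus:
        ranks["genus"] = genus
    if species:
        ranks["species"] = species
    ranks.update(extra)
    return Lineage(ranks)


def random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(BASES) for _ in range(length))


def mutate_positions(rng: random.Random, seq: str, n: int) -> str:
    """Substitute n distinct positions with a different concrete base."""
    chars = list(seq)
    for i in rng.sample(range(len(chars)), n):
        chars[i] = rng.choice([b for b in BASES if b != chars[i]])
    return "".join(chars)


@pytest.fixture(scope="session")
def panel():
    return load_default_primer_panel()


@pytest.fixture(scope="session")
def euka02(panel):
    return next(p for p in panel if p.name == "Euka02")


@pytest.fixture
def toy_primer():
    return PrimerPair("toy", "GTACACACCGCCCGTC", "TGGTGGTGCCCTTCCG",
                      min_len=50, max_len=400)


@pytest.fixture
def toy_records():
    """Four records: three amplifiable by toy constructions, one not."""
    return [
        ReferenceRecord("r1", "ACGT" * 50,
                        make_lineage(genus="Caenorhabditis",
                                     species="Caenorhabditis elegans")),
        ReferenceRecord("r2", "TTGA" * 50,
                        make_lineage(genus="Caenorhabditis",
                                     species="Caenorhabditis briggsae")),
        ReferenceRecord("r3", "GGCA" * 50,
                        make_lineage(family="Dorylaimidae",
                                     genus="Dorylaimus",
                                     species="Dorylaimus stagnalis")),
        ReferenceRecord("r4", "AATT" * 50, make_lineage()),
    ]
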