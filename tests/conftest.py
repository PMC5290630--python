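"""Shared fixtures: mini-gene models built programmatically at test time."""

from __future__ import annotations

import pytest

from dystrokit import (
    ClassifierConfig,
    DomainMap,
    Exon,
    MiniGeneParams,
    TranscriptModel,
    make_minigene,
)

# Hand-built 6-exon mini-gene reproducing the splice+nonsense combination
# topology: exon 4's length is not a multiple of 3, and c.90C>A turns codon 30
# (TAC, in exon 5) into a TAA stop.  Skipping exon 4 shifts the frame so the
# substituted base no longer completes a stop codon.
_SPLICE_NONSENSE_EXONS = (
    "ATGGCTGAATCCGGACTTAAA",        # exon 1: ATG + 6 codons (21 nt)
    "GCCACCGACGAACTGCAT",           # exon 2 (18 nt)
    "CTGGTGAACCGTATCGCAGACGAA",     # exon 3 (24 nt)
    "GCAGTCCATGAATTGGCCAAGG",       # exon 4 (22 nt; 22 % 3 == 1)
    "ATTACGGTCTTCAAGCCATTGAGAAGG",  # exon 5 (27 nt; contains codon 30 = TAC)
    "AAGCTTGCAGAACCATTGATTAA",      # exon 6 (23 nt; ends with the terminator)
)


def build_splice_nonsense_model() -> TranscriptModel:
    exons = tuple(
        Exon(index=i, sequence=s) for i, s in enumerate(_SPLICE_NONSENSE_EXONS, 1)
    )
    model = TranscriptModel(
        name="splice_nonsense_minigene", exons=exons, cds_start=1, cds_end=135
    )
    # sanity of the designed topology
    assert model.exons[3].length % 3 != 0
    assert model.spliced_sequence[87:90] == "TAC"  # codon 30 at c.88-90
    assert model.exon_end(4) == 85  # c.85+1 is the exon-4 donor site
    return model


@pytest.fixture(scope="session")
def splice_nonsense_model() -> TranscriptModel:
    return build_splice_nonsense_model()


@pytest.fixture(scope="session")
def minigene() -> TranscriptModel:
    """Default mid-sized random mini-gene (12 exons)."""
    return make_minigene(MiniGeneParams(seed=11))


@pytest.fixture(scope="session")
def minigene_cfg(minigene) -> ClassifierConfig:
    return ClassifierConfig.scaled_to(minigene)


def build_dystrophin_like_model(seed: int = 5) -> TranscriptModel:
    """79-exon synthetic model with the classic exon 45/46/47 lengths
    (176/148/150 nt), all other exons of length 3n so whole-exon deletions
    are in-frame by default."""
    lengths = [120] * 79
    lengths[44], lengths[45], lengths[46] = 176, 148, 150
    return make_minigene(
        MiniGeneParams(n_exons=79, exon_lengths=tuple(lengths), seed=seed)
    )


@pytest.fixture(scope="session")
def dystrophin_like() -> TranscriptModel:
    return build_dystrophin_like_model()


@pytest.fixture(scope="session")
def default_dmap() -> DomainMap:
    return DomainMap.default_dystrophin()
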