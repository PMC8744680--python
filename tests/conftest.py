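import random

import pytest

from recaptss.tags import AlignedRead, TagCountTable


def make_table(counts: dict, library_size: int = 1_000_000) -> TagCountTable:
    """TagCountTable from {(chrom,pos,strand): count}; default library size
    makes count == TPM, which keeps expected values readable."""
    return TagCountTable(counts, library_size=library_size)


def random_reads(n: int, seed: int, chroms=("chr1", "chr2"), softclip_rate: float = 0.2):
    """Seeded random AlignedReads spanning both strands, with 5' soft clips
    on a fraction of reads."""
    rng = random.Random(seed)
    reads = []
    for _ in range(n):
        chrom = rng.choice(chroms)
        start = rng.randrange(0, 10_000)
        length = rng.randrange(30, 80)
        strand = rng.choice("+-")
        clip = ""
        if rng.random() < softclip_rate:
            clip = "".join(rng.choice("ACGT") for _ in range(rng.randrange(1, 4)))
        reads.append(
            AlignedRead(
                chrom=chrom,
                start=start,
                end=start + length,
                strand=strand,
                mapq=rng.choice([0, 3, 30, 255]),
                five_prime_softclip=len(clip),
                softclip_seq=clip,
            )
        )
    return reads


@pytest.fixture
def toy_reads():
    """Three reads tagging chr1:100(+) twice and chr1:249(-) once."""
    return [
        AlignedRead("chr1", 100, 150, "+"),
        AlignedRead("chr1", 100, 160, "+"),
        AlignedRead("chr1", 200, 250, "-"),
    ]
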