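"""Strand-aware single-nucleotide 5'-end tag counting.

A *5' end tag* is the genomic position of the 5'-most aligned nucleotide of a
read: for a forward-strand alignment the leftmost aligned base, for a
reverse-strand alignment the rightmost. Soft-clipped bases (e.g. nontemplated
nucleotides added during transcription initiation, or adapter remnants) do not
consume reference positions, so the tag is always the first *aligned* base;
the clipped sequence is retained for nontemplated-prefix profiling.

Per-position counts are normalised as tags per million primary mappable reads
(TPM; some of the literature calls the same quantity TRM, tags per million
mapped reads).
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

from ._util import STRANDS, revcomp

TagKey = tuple[str, int, str]  # (chrom, 0-based position, strand)


class UnmappedReadError(ValueError):
    """Raised when a tag is requested from an unmapped read."""


@dataclass(frozen=True)
class AlignedRead:
    """A minimal, aligner-independent view of one aligned read.

    ``start``/``end`` delimit the aligned reference span (0-based half-open,
    soft clips excluded). ``softclip_seq`` holds the bases soft-clipped at the
    read's 5' end, stored in reference-forward orientation exactly as they
    appear in the SAM record; for minus-strand reads consumers that need the
    transcript's own 5'->3' orientation must reverse-complement
    (``nontemplated_prefix_profile`` does).
    """

    chrom: str
    start: int
    end: int
    strand: str
    mapq: int = 60
    is_primary: bool = True
    is_mapped: bool = True
    five_prime_softclip: int = 0
    softclip_seq: str = ""

    def __post_init__(self) -> None:
        if self.is_mapped:
            if self.start >= self.end:
                raise ValueError(f"start must be < end, got [{self.start}, {self.end})")
            if self.strand not in STRANDS:
                raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if self.five_prime_softclip != len(self.softclip_seq):
            raise ValueError(
                "five_prime_softclip must equal len(softclip_seq): "
                f"{self.five_prime_softclip} != {len(self.softclip_seq)}"
            )
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")


def extract_five_prime_tag(read: AlignedRead) -> TagKey:
    """Return the (chrom, position, strand) of the read's 5'-end tag.

    The tag is the first aligned base in read orientation: ``start`` for a
    plus-strand read, ``end - 1`` for a minus-strand read. 5' soft clips are
    already excluded from the aligned span and therefore never shift the tag.

    Raises
    ------
    UnmappedReadError
        If the read is unmapped.
    ValueError
        If the read is not a primary alignment (callers are expected to
        filter; tagging a secondary alignment is almost always a bug).
    """
    if not read.is_mapped:
        raise UnmappedReadError("cannot extract a 5' tag from an unmapped read")
    if not read.is_primary:
        raise ValueError("refusing to tag a non-primary alignment")
    if read.strand == "+":
        return (read.chrom, read.start, "+")
    return (read.chrom, read.end - 1, "-")


class TagCountTable:
    """Per-(chrom, position, strand) 5'-end tag counts for one library.

    ``library_size`` is the library's total number of primary mappable reads
    and is the TPM denominator; it may exceed the sum of stored counts (tags
    from filtered reads still count toward the denominator).
    """

    def __init__(self, counts: dict[TagKey, int] | None = None, library_size: int = 0):
        self.counts: dict[TagKey, int] = dict(counts) if counts else {}
        self.library_size = int(library_size)

    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, key: TagKey) -> bool:
        return key in self.counts

    def __getitem__(self, key: TagKey) -> int:
        return self.counts[key]

    def get(self, key: TagKey, default: int = 0) -> int:
        return self.counts.get(key, default)

    def items(self):
        return self.counts.items()

    def keys(self):
        return self.counts.keys()

    def __eq__(self, other) -> bool:
        if not isinstance(other, TagCountTable):
            return NotImplemented
        return self.counts == other.counts and self.library_size == other.library_size

    def total_tags(self) -> int:
        return sum(self.counts.values())

    def tpm(self, key: TagKey) -> float:
        """Tags per million primary mappable reads at ``key`` (0 if absent)."""
        if self.library_size <= 0:
            raise ValueError("TPM undefined: library_size is 0")
        return self.counts.get(key, 0) / self.library_size * 1e6

    # --- CTSS-style TSV I/O -------------------------------------------------
    # Format: a `#library_size=N` header line followed by
    # chrom <TAB> pos0 <TAB> strand <TAB> count <TAB> tpm

    def write_ctss(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#library_size={self.library_size}\n")
            for (chrom, pos, strand), n in sorted(self.counts.items()):
                tpm = n / self.library_size * 1e6 if self.library_size else float("nan")
                fh.write(f"{chrom}\t{pos}\t{strand}\t{n}\t{tpm:.6g}\n")

    @classmethod
    def read_ctss(cls, path: str | Path, library_size: int | None = None) -> "TagCountTable":
        counts: dict[TagKey, int] = {}
        size = 0
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    if line.startswith("#library_size="):
                        size = int(line.split("=", 1)[1])
                    continue
                chrom, pos, strand, n = line.split("\t")[:4]
                counts[(chrom, int(pos), strand)] = int(n)
        if library_size is not None:
            size = library_size
        return cls(counts, library_size=size)


def tpm(table: TagCountTable, key: TagKey) -> float:
    """Module-level alias for :meth:`TagCountTable.tpm`."""
    return table.tpm(key)


def count_tags(
    reads: Iterable[AlignedRead],
    min_mapq: int = 0,
    primary_only: bool = True,
    library_size: int | None = None,
) -> TagCountTable:
    """Reduce a stream of aligned reads to a 5'-end tag count table.

    Unmapped reads never contribute. With ``primary_only`` (the default,
    matching ``samtools view -F 256``) secondary/supplementary alignments are
    dropped. Reads below ``min_mapq`` contribute no tag but still count toward
    the default library size, which is the number of primary mapped reads
    streamed; pass ``library_size`` to override (e.g. to reproduce a
    down-sampled normalisation).
    """
    counts: Counter[TagKey] = Counter()
    n_primary = 0
    for read in reads:
        if not read.is_mapped:
            continue
        if primary_only and not read.is_primary:
            continue
        if read.is_primary:
            n_primary += 1
        if read.mapq < min_mapq:
            continue
        if read.strand == "+":
            counts[(read.chrom, read.start, "+")] += 1
        else:
            counts[(read.chrom, read.end - 1, "-")] += 1
    size = n_primary if library_size is None else library_size
    return TagCountTable(dict(counts), library_size=size)


def downsample(
    reads: Sequence[AlignedRead], n: int, seed: int
) -> list[AlignedRead]:
    """Sample exactly ``n`` primary mapped reads uniformly without replacement.

    Reproducible for a fixed seed; the output preserves input order and is a
    subset of the input. Mirrors the common practice of down-sampling merged
    replicate libraries to a common depth before TSS calling.
    """
    primary_idx = [
        i for i, r in enumerate(reads) if r.is_mapped and r.is_primary
    ]
    if n > len(primary_idx):
        raise ValueError(
            f"cannot sample {n} reads: only {len(primary_idx)} primary mappable reads available"
        )
    rng = random.Random(seed)
    chosen = sorted(rng.sample(primary_idx, n))
    return [reads[i] for i in chosen]


def rrna_fraction(n_rrna_mapped: int, n_genome_mapped: int) -> float:
    """Percentage of genome-mapped reads that map to (processed) rRNA.

    ``n_rrna_mapped`` should be counted against a processed-rRNA reference
    (18S/28S/5.8S and the mitochondrial 12S/16S); 5S is Pol III-transcribed,
    hence triphosphorylated, and must be excluded from the reference.
    """
    if n_genome_mapped <= 0:
        raise ValueError("n_genome_mapped must be > 0")
    if n_rrna_mapped < 0:
        raise ValueError("n_rrna_mapped must be >= 0")
    return 100.0 * n_rrna_mapped / n_genome_mapped


@dataclass
class PrefixProfile:
    """Tally of 5' soft-clipped (nontemplated) prefixes at one position."""

    counts: dict[str, int] = field(default_factory=dict)
    a_prefix_fraction: float = 0.0
    n_reads: int = 0


def nontemplated_prefix_profile(reads_at_position: Sequence[AlignedRead]) -> PrefixProfile:
    """Profile nontemplated 5' prefixes among reads tagged at one position.

    Prefixes are reported in the transcript's own 5'->3' orientation, so the
    stored (reference-forward) clip of a minus-strand read is
    reverse-complemented first. The A-prefix fraction is the fraction of reads
    whose prefix is non-empty and consists only of adenosines — the signature
    of transcription-initiation stuttering seen at mitochondrial promoters.
    """
    if not reads_at_position:
        return PrefixProfile()
    keys = {extract_five_prime_tag(r) for r in reads_at_position}
    if len(keys) != 1:
        raise ValueError(f"reads span {len(keys)} distinct tag positions, expected 1")
    counts: Counter[str] = Counter()
    n_a = 0
    for r in reads_at_position:
        prefix = r.softclip_seq
        if r.strand == "-":
            prefix = revcomp(prefix)
        prefix = prefix.upper()
        counts[prefix] += 1
        if prefix and set(prefix) == {"A"}:
            n_a += 1
    n = len(reads_at_position)
    return PrefixProfile(dict(counts), a_prefix_fraction=n_a / n, n_reads=n)


# --- SAM/BAM ingestion ------------------------------------------------------


def _from_pysam(seg: pysam.AlignedSegment) -> AlignedRead:
    strand = "-" if seg.is_reverse else "+"
    clip_len = 0
    clip_seq = ""
    cig = seg.cigartuples or []
    if cig:
        if strand == "+" and cig[0][0] == 4:  # leading S = read 5' end
            clip_len = cig[0][1]
            if seg.query_sequence:
                clip_seq = seg.query_sequence[:clip_len]
        elif strand == "-" and cig[-1][0] == 4:  # trailing S = read 5' end
            clip_len = cig[-1][1]
            if seg.query_sequence:
                clip_seq = seg.query_sequence[-clip_len:]
    if clip_len and not clip_seq:
        clip_seq = "N" * clip_len
    return AlignedRead(
        chrom=seg.reference_name,
        start=seg.reference_start,
        end=seg.reference_end,
        strand=strand,
        mapq=seg.mapping_quality,
        is_primary=not (seg.is_secondary or seg.is_supplementary),
        five_prime_softclip=clip_len,
        softclip_seq=clip_seq,
    )


def iter_sam(
    path: str | Path, keep_secondary: bool = False, first_mate_only: bool = True
) -> Iterator[AlignedRead]:
    """Yield :class:`AlignedRead` from a SAM/BAM file.

    Unmapped records are skipped. Secondary/supplementary alignments are
    skipped unless ``keep_secondary`` (diagnostics only). For paired-end input
    only read 1 carries the 5' end of the original molecule, so mate 2 is
    skipped by default.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            if not keep_secondary and (seg.is_secondary or seg.is_supplementary):
                continue
            if first_mate_only and seg.is_paired and seg.is_read2:
                continue
            yield _from_pysam(seg)


def count_tags_from_sam(
    path: str | Path,
    min_mapq: int = 0,
    library_size: int | None = None,
) -> TagCountTable:
    """Convenience: :func:`count_tags` over a SAM/BAM file."""
    return count_tags(iter_sam(path), min_mapq=min_mapq, library_size=library_size)
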