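"""Relate called TSSs to gene annotation.

Covers four analyses:

* closest-downstream-exon gene assignment (a TSS belongs to a gene if it
  overlaps an exon or lies within a fixed distance upstream of one, in gene
  orientation);
* single-linkage clustering of unannotated TSSs into loci;
* anchor-relative positioning histograms (e.g. TSSs around mature tRNA 5'
  ends);
* flanking base-composition profiles (the -1[C/T] +1[A/G] initiator motif).

Coordinates are 0-based half-open throughout; GTF input is converted on read.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pyranges as pr
from intervaltree import IntervalTree
from pyfaidx import Fasta

from ._util import revcomp
from .tags import TagKey

Anchor = tuple[str, int, str]  # (chrom, pos0, strand)


@dataclass
class GeneModel:
    """A gene with typed, strand-aware exons (0-based half-open intervals)."""

    gene_id: str
    gene_type: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"gene {self.gene_id}: exon [{s}, {e}) is empty")

    @property
    def five_prime_start(self) -> int:
        """Genomic position of the annotated 5' end (first transcribed base)."""
        if self.strand == "+":
            return min(s for s, _ in self.exons)
        return max(e for _, e in self.exons) - 1


def read_gtf_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models (exon features grouped by gene_id) from a
    GENCODE-dialect GTF.

    Exon order within a gene follows file order, which downstream tie-breaks
    rely on ("first in annotation input order").
    """
    df = pr.read_gtf(str(path)).df
    df = df[df["Feature"] == "exon"]
    genes: dict[str, GeneModel] = {}
    for row in df.itertuples(index=False):
        gid = row.gene_id
        gtype = getattr(row, "gene_type", "") or ""
        g = genes.get(gid)
        if g is None:
            genes[gid] = GeneModel(
                gene_id=gid,
                gene_type=gtype,
                chrom=str(row.Chromosome),
                strand=row.Strand,
                exons=[(int(row.Start), int(row.End))],
            )
        else:
            g.exons.append((int(row.Start), int(row.End)))
    return list(genes.values())


@dataclass
class TssGeneAssignment:
    tss: TagKey
    gene_id: str | None
    gene_type: str | None = None
    distance: int | None = None  # 0 = overlap; positive = TSS upstream of exon


def _tss_key(t) -> TagKey:
    if isinstance(t, tuple):
        return t
    return (t.chrom, t.position, t.strand)


class _ExonIndex:
    """Per-(chrom, strand) exon index for overlap + nearest-downstream queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        anchors: dict[tuple[str, str], list[tuple[int, int, int]]] = defaultdict(list)
        self.entries: list[tuple[GeneModel, int, int]] = []
        order = 0
        for gene in genes:
            for s, e in gene.exons:
                self.entries.append((gene, s, e))
                self.trees[(gene.chrom, gene.strand)].addi(s, e, order)
                # anchor = first exon base in gene orientation, mapped so that
                # "downstream of the TSS" is always "anchor > query"
                anchor = s if gene.strand == "+" else -(e - 1)
                anchors[(gene.chrom, gene.strand)].append((anchor, order, order))
                order += 1
        self.anchor_arrays: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for key, lst in anchors.items():
            lst.sort()
            arr = np.array([a for a, _, _ in lst], dtype=np.int64)
            orders = np.array([o for _, o, _ in lst], dtype=np.int64)
            self.anchor_arrays[key] = (arr, orders)


def assign_tss_to_genes(
    tss_list: Sequence,
    genes: Sequence[GeneModel],
    max_upstream: int = 200,
) -> list[TssGeneAssignment]:
    """Assign each TSS to the gene of its closest same-strand exon.

    Candidate exons either overlap the TSS (distance 0) or begin downstream of
    it in gene orientation; exons entirely upstream of the TSS are never
    candidates (a TSS may sit upstream of or within its gene, not past it).
    The assignment is made iff the distance is <= ``max_upstream`` (inclusive).
    Ties are broken by annotation input order.
    """
    index = _ExonIndex(genes)
    out = []
    for t in tss_list:
        chrom, pos, strand = _tss_key(t)
        key = (chrom, strand)
        best: tuple[int, int] | None = None  # (distance, order)
        tree = index.trees.get(key)
        if tree is not None:
            hits = tree[pos]
            if hits:
                order = min(h.data for h in hits)
                best = (0, order)
        if best is None and key in index.anchor_arrays:
            arr, orders = index.anchor_arrays[key]
            q = pos if strand == "+" else -pos
            i = np.searchsorted(arr, q, side="right")
            if i < len(arr):
                dist = int(arr[i] - q)
                if dist <= max_upstream:
                    # among equal anchors take minimal input order
                    j = i
                    order = int(orders[i])
                    while j + 1 < len(arr) and arr[j + 1] == arr[i]:
                        j += 1
                        order = min(order, int(orders[j]))
                    best = (dist, order)
        if best is None:
            out.append(TssGeneAssignment((chrom, pos, strand), None))
        else:
            dist, order = best
            gene = index.entries[order][0]
            out.append(
                TssGeneAssignment((chrom, pos, strand), gene.gene_id, gene.gene_type, dist)
            )
    return out


@dataclass
class Locus:
    """A cluster of nearby unannotated TSSs on one strand."""

    chrom: str
    strand: str
    positions: list[int] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (self.positions[0], self.positions[-1] + 1)


def cluster_unannotated(tss_list: Sequence, max_gap: int = 20) -> list[Locus]:
    """Single-linkage clustering of TSS positions into loci, per (chrom, strand).

    Consecutive sorted positions at most ``max_gap`` bp apart chain into one
    locus. Idempotent and independent of input order.
    """
    by_key: dict[tuple[str, str], set[int]] = defaultdict(set)
    for t in tss_list:
        chrom, pos, strand = _tss_key(t)
        by_key[(chrom, strand)].add(pos)
    loci = []
    for (chrom, strand), positions in sorted(by_key.items()):
        current: list[int] = []
        for pos in sorted(positions):
            if current and pos - current[-1] > max_gap:
                loci.append(Locus(chrom, strand, current))
                current = []
            current.append(pos)
        if current:
            loci.append(Locus(chrom, strand, current))
    return loci


def relative_position_histogram(
    tss_list: Sequence,
    anchors: Sequence[Anchor],
    window: int,
) -> dict[int, int]:
    """Histogram of TSS offsets relative to the nearest same-strand anchor.

    The offset is the strand-oriented signed distance (negative = TSS upstream
    of the anchor in the anchor's orientation, e.g. -5 for a start 5 bp before
    a mature tRNA 5' end). Each TSS contributes at most once, to its nearest
    anchor; TSSs farther than ``window`` from every anchor are excluded. Ties
    in absolute distance resolve to the upstream (negative) offset.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    by_key: dict[tuple[str, str], np.ndarray] = {}
    grouped: dict[tuple[str, str], list[int]] = defaultdict(list)
    for chrom, pos, strand in anchors:
        grouped[(chrom, strand)].append(pos)
    for key, lst in grouped.items():
        by_key[key] = np.array(sorted(lst), dtype=np.int64)
    hist: Counter[int] = Counter()
    for t in tss_list:
        chrom, pos, strand = _tss_key(t)
        arr = by_key.get((chrom, strand))
        if arr is None or len(arr) == 0:
            continue
        i = np.searchsorted(arr, pos)
        candidates = []
        if i < len(arr):
            candidates.append(int(arr[i]))
        if i > 0:
            candidates.append(int(arr[i - 1]))
        offsets = []
        for a in candidates:
            off = pos - a if strand == "+" else a - pos
            offsets.append(off)
        offsets = [o for o in offsets if abs(o) <= window]
        if not offsets:
            continue
        offsets.sort(key=lambda o: (abs(o), o))
        hist[offsets[0]] += 1
    return dict(hist)


@dataclass
class CompositionProfile:
    """Strand-oriented base composition around TSSs.

    ``freq`` is indexed by offset with the TSS base labelled +1 (there is no
    offset 0, matching the usual initiator-motif convention: -1 is the base
    immediately upstream).
    """

    freq: pd.DataFrame
    frac_plus1_ag: float
    frac_minus1_ct: float
    n_used: int
    n_excluded: int


def base_composition_profile(
    tss_list: Sequence,
    genome: Fasta | str | Path,
    flank: int,
) -> CompositionProfile:
    """Per-offset A/C/G/T frequencies in ``[-flank, +flank]`` around TSSs.

    Sequences are read strand-oriented (reverse-complemented for minus-strand
    TSSs). TSSs too close to a contig edge are excluded and counted. Also
    reports the fraction of TSSs starting with A or G (+1 purine) and the
    fraction with a C or T immediately upstream (-1 pyrimidine).
    """
    if not isinstance(genome, Fasta):
        genome = Fasta(str(genome))
    bases = "ACGT"
    counts = np.zeros((2 * flank + 1, 4), dtype=np.int64)
    n_used = 0
    n_excluded = 0
    n_plus1_ag = 0
    n_minus1_ct = 0
    for t in tss_list:
        chrom, pos, strand = _tss_key(t)
        contig = genome[chrom]
        if pos - flank < 0 or pos + flank >= len(contig):
            n_excluded += 1
            continue
        seq = str(contig[pos - flank : pos + flank + 1]).upper()
        if strand == "-":
            seq = revcomp(seq)
        for i, b in enumerate(seq):
            j = bases.find(b)
            if j >= 0:
                counts[i, j] += 1
        n_used += 1
        if seq[flank] in "AG":
            n_plus1_ag += 1
        if flank >= 1 and seq[flank - 1] in "CT":
            n_minus1_ct += 1
    offsets = [k if k < 0 else k + 1 for k in range(-flank, flank + 1)]
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts / np.where(totals == 0, np.nan, totals)
    df = pd.DataFrame(freq, index=pd.Index(offsets, name="offset"), columns=list(bases))
    return CompositionProfile(
        freq=df,
        frac_plus1_ag=n_plus1_ag / n_used if n_used else math.nan,
        frac_minus1_ct=n_minus1_ct / n_used if n_used else math.nan,
        n_used=n_used,
        n_excluded=n_excluded,
    )


@dataclass
class OverlapResult:
    hit_flags: list[bool]
    interval_counts: list[int]
    counts_by_class: dict[str, int]


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read (chrom, start, end) intervals from BED/narrowPeak; extra columns
    are ignored. Malformed intervals raise with the offending line number."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}, line {lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(
                    f"{path}, line {lineno}: malformed interval [{start}, {end})"
                )
            intervals.append((chrom, start, end))
    return intervals


def interval_overlap(
    tss_list: Sequence,
    intervals: Sequence[tuple[str, int, int]] | str | Path,
) -> OverlapResult:
    """Point-in-interval overlap of TSSs against (strandless) BED intervals.

    Intervals are 0-based half-open: a TSS at the interval start hits, one at
    the end misses. Returns per-TSS hit flags, per-interval TSS counts, and
    hit tallies grouped by polymerase class for classified records.
    """
    if isinstance(intervals, (str, Path)):
        intervals = read_bed_intervals(intervals)
    for i, (chrom, start, end) in enumerate(intervals):
        if start >= end:
            raise ValueError(f"interval {i + 1}: malformed interval [{start}, {end})")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, (chrom, start, end) in enumerate(intervals):
        trees[chrom].addi(start, end, i)
    hit_flags = []
    interval_counts = [0] * len(intervals)
    counts_by_class: Counter[str] = Counter()
    for t in tss_list:
        chrom, pos, strand = _tss_key(t)
        hits = trees[chrom][pos] if chrom in trees else set()
        hit_flags.append(bool(hits))
        for h in hits:
            interval_counts[h.data] += 1
        if hits and not isinstance(t, tuple):
            counts_by_class[t.pol_class.value] += 1
    return OverlapResult(hit_flags, interval_counts, dict(counts_by_class))


def genes_with_tss(assignments: Iterable[TssGeneAssignment]) -> set[str]:
    """Distinct gene ids with at least one assigned TSS."""
    return {a.gene_id for a in assignments if a.gene_id is not None}
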