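"""Benchmarking of called TSSs against reference sets.

Implements the precision/sensitivity scheme used for TSS methods:

* precision = 100 x TP / (TP + FP), where TP are high-confidence Pol II TSSs
  overlapping a reference (annotation first-exon starts, CAGE positions
  within a +/-1 nt window, or open-chromatin peak intervals) and FP the
  remainder;
* sensitivity = TP / (TP + FN), where FN are reference TSSs of expressed
  transcripts (FPKM above a cutoff), supported by at least one peak, that no
  query TSS overlaps.

Also provides the transcript-body coverage profile (percentile-binned 5'-tag
or read coverage along transcripts) used to show 5'-end specificity, and the
qPCR percent-recovery formula used to validate enrichment chemistry.

Undefined metrics (zero denominators) propagate as NaN, never as silent 0.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotate import GeneModel, read_bed_intervals
from .tags import AlignedRead, TagCountTable

Position = tuple[str, int, str]
Peak = tuple[str, int, int]


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int = 0
    precision: float = math.nan  # percentage
    sensitivity: float = math.nan  # fraction
    n_fpkm_missing: int = 0


def _position_key(t) -> Position:
    if isinstance(t, tuple):
        return t[:3]
    return (t.chrom, t.position, t.strand)


class _PositionIndex:
    def __init__(self, positions: Sequence[Position], strand_aware: bool):
        self.strand_aware = strand_aware
        grouped: dict[tuple, list[int]] = defaultdict(list)
        for chrom, pos, strand in positions:
            key = (chrom, strand) if strand_aware else (chrom,)
            grouped[key].append(pos)
        self.arrays = {k: np.array(sorted(v), dtype=np.int64) for k, v in grouped.items()}

    def hit(self, chrom: str, pos: int, strand: str, window: int) -> bool:
        key = (chrom, strand) if self.strand_aware else (chrom,)
        arr = self.arrays.get(key)
        if arr is None or len(arr) == 0:
            return False
        i = np.searchsorted(arr, pos - window, side="left")
        return i < len(arr) and arr[i] <= pos + window


def match_positions(
    query_tss: Sequence,
    reference_positions: Sequence[Position],
    window: int,
    strand_aware: bool = True,
) -> list[bool]:
    """Per-query flags: does any reference position lie within +/-``window``?

    ``window=0`` is exact single-nucleotide matching; with ``strand_aware``
    only same-strand references count.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    index = _PositionIndex(reference_positions, strand_aware)
    return [index.hit(*_position_key(t), window) for t in query_tss]


def _peak_trees(peaks: Sequence[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for chrom, start, end in peaks:
        if start >= end:
            raise ValueError(f"malformed peak interval [{start}, {end})")
        trees[chrom].addi(start, end)
    return trees


def _in_peaks(trees: dict[str, IntervalTree], chrom: str, pos: int) -> bool:
    return chrom in trees and bool(trees[chrom][pos])


def precision(
    query_tss: Sequence,
    ref_positions: Sequence[Position] | None = None,
    peaks: Sequence[Peak] | str | Path | None = None,
    window: int = 0,
    strand_aware: bool = True,
) -> EvalResult:
    """Precision of query TSSs against one reference.

    Exactly one of ``ref_positions`` (position set, matched within
    +/-``window``, strand-aware) or ``peaks`` (intervals, point-in-interval)
    must be given. An empty query yields tp = fp = 0 and precision NaN.
    """
    if (ref_positions is None) == (peaks is None):
        raise ValueError("provide exactly one of ref_positions or peaks")
    if ref_positions is not None:
        flags = match_positions(query_tss, ref_positions, window, strand_aware)
    else:
        if isinstance(peaks, (str, Path)):
            peaks = read_bed_intervals(peaks)
        trees = _peak_trees(peaks)
        flags = [_in_peaks(trees, *_position_key(t)[:2]) for t in query_tss]
    tp = sum(flags)
    fp = len(flags) - tp
    prec = 100.0 * tp / (tp + fp) if tp + fp > 0 else math.nan
    return EvalResult(tp=tp, fp=fp, precision=prec)


@dataclass(frozen=True)
class RefTss:
    """An annotated reference TSS (first-exon start) tied to a transcript."""

    chrom: str
    position: int
    strand: str
    transcript_id: str


def sensitivity(
    query_tss: Sequence,
    ref_tss: Sequence[RefTss],
    fpkm: dict[str, float],
    fpkm_cutoff: float,
    peaks: Sequence[Peak] | str | Path,
    window: int = 0,
    strand_aware: bool = True,
) -> EvalResult:
    """Sensitivity of query TSSs given expression- and peak-supported references.

    TP = query TSSs overlapping any reference position (within
    +/-``window``). FN = reference TSSs that (1) belong to a transcript with
    FPKM >= ``fpkm_cutoff``, (2) overlap at least one peak, and (3) are not
    overlapped by any query TSS. References whose transcript has no FPKM
    entry are excluded and counted in ``n_fpkm_missing``.
    """
    if isinstance(peaks, (str, Path)):
        peaks = read_bed_intervals(peaks)
    trees = _peak_trees(peaks)
    ref_positions = [(r.chrom, r.position, r.strand) for r in ref_tss]
    query_flags = match_positions(query_tss, ref_positions, window, strand_aware)
    tp = sum(query_flags)
    fp = len(query_flags) - tp
    query_index = _PositionIndex([_position_key(t) for t in query_tss], strand_aware)
    fn = 0
    n_missing = 0
    for r in ref_tss:
        if r.transcript_id not in fpkm:
            n_missing += 1
            continue
        if fpkm[r.transcript_id] < fpkm_cutoff:
            continue
        if not _in_peaks(trees, r.chrom, r.position):
            continue
        if query_index.hit(r.chrom, r.position, r.strand, window):
            continue
        fn += 1
    if n_missing:
        warnings.warn(
            f"{n_missing} reference TSSs lacked an FPKM entry and were excluded",
            stacklevel=2,
        )
    sens = tp / (tp + fn) if tp + fn > 0 else math.nan
    prec = 100.0 * tp / (tp + fp) if tp + fp > 0 else math.nan
    return EvalResult(
        tp=tp, fp=fp, fn=fn, precision=prec, sensitivity=sens, n_fpkm_missing=n_missing
    )


# --- Transcript body coverage -----------------------------------------------


@dataclass
class CoverageResult:
    """Percentile-binned coverage along transcript bodies (5'->3')."""

    matrix: pd.DataFrame  # transcripts x 100 bins
    mean_profile: np.ndarray
    n_excluded_short: int
    n_excluded_low: int


def _transcript_positions(model: GeneModel) -> list[tuple[str, int]]:
    """Genomic (chrom, pos) of each transcript base in 5'->3' order."""
    exons = sorted(model.exons)
    positions = [(model.chrom, p) for s, e in exons for p in range(s, e)]
    if model.strand == "-":
        positions.reverse()
    return positions


def transcript_body_coverage(
    source: TagCountTable | Sequence[AlignedRead],
    transcripts: Sequence[GeneModel],
    min_len: int = 300,
    mode: str = "tags",
    fpkm: dict[str, float] | None = None,
    min_fpkm: float = 10.0,
    library_size: int | None = None,
) -> CoverageResult:
    """Coverage of 5'-end tags or read bodies across transcripts, binned into
    100 percentile bins 5'->3'.

    Transcripts of length <= ``min_len`` are excluded. In ``tags`` mode,
    ``source`` is a :class:`TagCountTable` and transcripts whose total
    overlapping tag count is below library_size / 10^6 are excluded (too few
    tags to profile). In ``reads`` mode, ``source`` is a read list whose
    aligned spans are piled up, and transcripts with FPKM < ``min_fpkm`` are
    excluded (requires ``fpkm``). A 5'-end-seq library should concentrate in
    the first bin; RNA-seq should be flat.
    """
    if mode not in ("tags", "reads"):
        raise ValueError("mode must be 'tags' or 'reads'")
    if mode == "tags":
        if not isinstance(source, TagCountTable):
            raise TypeError("tags mode requires a TagCountTable")
        if library_size is None:
            library_size = source.library_size
        min_tags = library_size / 1e6
    else:
        if fpkm is None:
            raise ValueError("reads mode requires an fpkm map")
        depth: dict[str, np.ndarray] = {}
        spans: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for r in source:
            spans[(r.chrom, r.strand)].append((r.start, r.end))

    rows = []
    names = []
    n_short = 0
    n_low = 0
    for model in transcripts:
        positions = _transcript_positions(model)
        length = len(positions)
        if length == 0:
            raise ValueError(f"transcript {model.gene_id} has zero length")
        if length <= min_len:
            n_short += 1
            continue
        per_base = np.zeros(length, dtype=float)
        if mode == "tags":
            for i, (chrom, pos) in enumerate(positions):
                per_base[i] = source.get((chrom, pos, model.strand), 0)
            if per_base.sum() < min_tags:
                n_low += 1
                continue
        else:
            if fpkm.get(model.gene_id, 0.0) < min_fpkm:
                n_low += 1
                continue
            key = (model.chrom, model.strand)
            for i, (chrom, pos) in enumerate(positions):
                per_base[i] = sum(1 for s, e in spans.get(key, ()) if s <= pos < e)
        bins = np.floor(np.arange(length) * 100 / length).astype(int)
        profile = np.bincount(bins, weights=per_base, minlength=100)
        rows.append(profile)
        names.append(model.gene_id)
    matrix = pd.DataFrame(rows, index=names, columns=range(100))
    mean = matrix.to_numpy().mean(axis=0) if len(rows) else np.full(100, math.nan)
    return CoverageResult(matrix, mean, n_short, n_low)


# --- qPCR percent recovery ---------------------------------------------------


@dataclass
class QpcrSample:
    """Replicate Cq values for an unenriched input and its enriched fraction."""

    cq_input: Sequence[float]
    cq_enriched: Sequence[float]

    def __post_init__(self) -> None:
        if not self.cq_input or not self.cq_enriched:
            raise ValueError("Cq lists must be non-empty")
        if any(c <= 0 for c in (*self.cq_input, *self.cq_enriched)):
            raise ValueError("Cq values must be > 0")


def qpcr_recovery(sample: QpcrSample) -> float:
    """Percent recovery after enrichment from qPCR quantification cycles.

    recovery = 100 x 2^-(mean(Cq_input) - mean(Cq_enriched)). Equal means give
    100% (the input is defined as 100%); each additional cycle of delay in the
    enriched fraction halves the recovery.
    """
    delta = float(np.mean(sample.cq_input)) - float(np.mean(sample.cq_enriched))
    return 100.0 * 2.0 ** (-delta)


# --- Reference-set container and loaders -------------------------------------


@dataclass
class ReferenceSet:
    """Bundle of references used by the precision/sensitivity benchmark."""

    ref_tss: list[RefTss]
    cage: TagCountTable | None = None
    peaks: list[Peak] | None = None
    fpkm: dict[str, float] | None = None


def read_ref_tss_bed6(path: str | Path) -> list[RefTss]:
    """Reference TSS positions from BED6 (name column = transcript id)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}, line {lineno}: expected BED6")
            chrom, start, _end, name, _score, strand = fields[:6]
            out.append(RefTss(chrom, int(start), strand, name))
    return out


def read_fpkm_table(path: str | Path) -> dict[str, float]:
    """``transcript_id <TAB> fpkm`` table -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["transcript_id", "fpkm"], comment="#")
    return dict(zip(df["transcript_id"].astype(str), df["fpkm"].astype(float)))
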