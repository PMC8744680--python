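"""TSS calling and Pol II / non-Pol II classification.

The pipeline compares three matched libraries at single-nucleotide
resolution:

* ``ALL`` — the enriched library (captures both m7G-capped and
  5'-triphosphorylated primary 5' ends);
* ``CT`` — the unenriched control (streptavidin step omitted; rich in
  processed/degraded 5' ends);
* ``CIP`` — the enriched library built from phosphatase-pretreated RNA
  (triphosphate ends destroyed, so non-Pol II starts drop out).

A *candidate* TSS is any position with ALL-library TPM >= 1. Candidates
enriched over the control (enrichment ratio TPM_ALL / TPM_CT >= 1) are
*high-confidence*; the rest are false positives. High-confidence TSSs are
then split by the CIP ratio TPM_ALL / TPM_CIP: ratio >= 4 means the signal is
CIP-sensitive (triphosphorylated, non-Pol II), ratio < 4 means CIP-resistant
(capped, Pol II). The two ratios define four quadrants:

=========  ==============  =============
quadrant   enrichment      CIP ratio
=========  ==============  =============
I          < 1 (FP)        >= 4
II         >= 1 (HC)       >= 4 (non-Pol II)
III        < 1 (FP)        < 4
IV         >= 1 (HC)       < 4 (Pol II)
=========  ==============  =============

All thresholds are inclusive exactly as written above. Ratios with a zero
denominator are +inf (a position absent from the control / CIP library is
maximally enriched / depleted); an optional pseudocount exposes the
alternative convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .tags import AlignedRead, TagCountTable, TagKey, extract_five_prime_tag


class Status(str, Enum):
    CANDIDATE = "candidate"
    HIGH_CONFIDENCE = "high_confidence"
    FALSE_POSITIVE = "false_positive"


class PolClass(str, Enum):
    POL2 = "pol2"
    NON_POL2 = "non_pol2"
    UNASSIGNED = "unassigned"


class Quadrant(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    NONE = "none"


@dataclass
class TssRecord:
    chrom: str
    position: int
    strand: str
    tpm_all: float
    tpm_ct: float = 0.0
    tpm_cip: float = 0.0
    enrich_ratio: float = math.nan
    cip_ratio: float = math.nan
    status: Status = Status.CANDIDATE
    pol_class: PolClass = PolClass.UNASSIGNED
    quadrant: Quadrant = Quadrant.NONE

    @property
    def key(self) -> TagKey:
        return (self.chrom, self.position, self.strand)


def _ratio(num: float, den: float, pseudocount: float = 0.0) -> float:
    num += pseudocount
    den += pseudocount
    if den > 0:
        return num / den
    return math.inf if num > 0 else math.nan


def call_candidates(all_table: TagCountTable, min_tpm: float = 1.0) -> list[TssRecord]:
    """Call candidate TSSs: positions with enriched-library TPM >= ``min_tpm``.

    The threshold is inclusive (TPM exactly 1 is a candidate).
    """
    if all_table.library_size <= 0:
        raise ValueError("cannot call candidates: library_size is 0")
    records = []
    for key in sorted(all_table.keys()):
        t = all_table.tpm(key)
        if t >= min_tpm:
            chrom, pos, strand = key
            records.append(TssRecord(chrom, pos, strand, tpm_all=t))
    return records


def filter_high_confidence(
    candidates: Iterable[TssRecord],
    ct_table: TagCountTable,
    hc_ratio: float = 1.0,
    pseudocount: float = 0.0,
) -> list[TssRecord]:
    """Split candidates into high-confidence vs false-positive on the control.

    Sets ``tpm_ct`` and ``enrich_ratio = tpm_all / tpm_ct`` on each record;
    ratio >= ``hc_ratio`` (inclusive) is high-confidence. A position absent
    from the control has ratio +inf and is high-confidence.
    """
    out = []
    for rec in candidates:
        rec.tpm_ct = ct_table.tpm(rec.key) if rec.key in ct_table else 0.0
        rec.enrich_ratio = _ratio(rec.tpm_all, rec.tpm_ct, pseudocount)
        rec.status = (
            Status.HIGH_CONFIDENCE if rec.enrich_ratio >= hc_ratio else Status.FALSE_POSITIVE
        )
        out.append(rec)
    return out


def classify_polymerase(
    hc_records: Iterable[TssRecord],
    cip_table: TagCountTable,
    cip_threshold: float = 4.0,
) -> list[TssRecord]:
    """Assign high-confidence TSSs to Pol II or non-Pol II via the CIP library.

    ``cip_ratio = tpm_all / tpm_cip``; ratio >= ``cip_threshold`` (inclusive)
    means the position is CIP-sensitive, hence triphosphorylated and
    non-Pol II (quadrant II); otherwise Pol II (quadrant IV). Only
    high-confidence records are accepted.
    """
    out = []
    for rec in hc_records:
        if rec.status is not Status.HIGH_CONFIDENCE:
            raise ValueError(
                f"classify_polymerase requires high-confidence records, got {rec.status.value}"
            )
        rec.tpm_cip = cip_table.tpm(rec.key) if rec.key in cip_table else 0.0
        rec.cip_ratio = _ratio(rec.tpm_all, rec.tpm_cip)
        if rec.cip_ratio >= cip_threshold:
            rec.pol_class = PolClass.NON_POL2
            rec.quadrant = Quadrant.II
        else:
            rec.pol_class = PolClass.POL2
            rec.quadrant = Quadrant.IV
        out.append(rec)
    return out


def classify_from_tpm(
    chrom: str,
    position: int,
    strand: str,
    tpm_all: float,
    tpm_ct: float,
    tpm_cip: float,
    min_tpm: float = 1.0,
    hc_ratio: float = 1.0,
    cip_threshold: float = 4.0,
    pseudocount: float = 0.0,
) -> TssRecord | None:
    """Classify one position straight from its three TPM values.

    Returns ``None`` when the position does not reach ``min_tpm`` in the
    enriched library. False positives get a quadrant (I or III, split by the
    CIP ratio) but no polymerase class; polymerase class is only meaningful
    for high-confidence positions.
    """
    if tpm_all < min_tpm:
        return None
    rec = TssRecord(chrom, position, strand, tpm_all=tpm_all, tpm_ct=tpm_ct, tpm_cip=tpm_cip)
    rec.enrich_ratio = _ratio(tpm_all, tpm_ct, pseudocount)
    rec.cip_ratio = _ratio(tpm_all, tpm_cip)
    hc = rec.enrich_ratio >= hc_ratio
    cip_sensitive = rec.cip_ratio >= cip_threshold
    rec.status = Status.HIGH_CONFIDENCE if hc else Status.FALSE_POSITIVE
    if hc:
        rec.pol_class = PolClass.NON_POL2 if cip_sensitive else PolClass.POL2
        rec.quadrant = Quadrant.II if cip_sensitive else Quadrant.IV
    else:
        rec.pol_class = PolClass.UNASSIGNED
        rec.quadrant = Quadrant.I if cip_sensitive else Quadrant.III
    return rec


def classify_tss(
    all_table: TagCountTable,
    ct_table: TagCountTable,
    cip_table: TagCountTable,
    min_tpm: float = 1.0,
    hc_ratio: float = 1.0,
    cip_threshold: float = 4.0,
    pseudocount: float = 0.0,
) -> list[TssRecord]:
    """Full calling pipeline: candidates -> HC filter -> polymerase class.

    Positions are matched across the three libraries by exact
    (chrom, position, strand) key — single-nucleotide resolution, no window.
    Every returned record carries both ratios and a quadrant; false positives
    keep ``pol_class = unassigned``.
    """
    if all_table.library_size <= 0:
        raise ValueError("cannot call candidates: library_size is 0")
    records = []
    for key in sorted(all_table.keys()):
        chrom, pos, strand = key
        rec = classify_from_tpm(
            chrom,
            pos,
            strand,
            tpm_all=all_table.tpm(key),
            tpm_ct=ct_table.tpm(key) if key in ct_table else 0.0,
            tpm_cip=cip_table.tpm(key) if key in cip_table else 0.0,
            min_tpm=min_tpm,
            hc_ratio=hc_ratio,
            cip_threshold=cip_threshold,
            pseudocount=pseudocount,
        )
        if rec is not None:
            records.append(rec)
    return records


# --- Mitochondrial unique-mapping filter ------------------------------------


@dataclass
class MitoPositionStat:
    """Unique-mapping tally for one (mitochondrial) tag position."""

    key: TagKey
    n_unique: int
    n_total: int

    @property
    def ratio(self) -> float:
        return self.n_unique / self.n_total if self.n_total else math.nan


def mito_unique_tallies(
    reads: Iterable[AlignedRead], mapq_threshold: int = 3
) -> dict[TagKey, MitoPositionStat]:
    """Per-position counts of uniquely mapping tags (MAPQ strictly above
    ``mapq_threshold``) versus all tags.

    The default threshold 3 matches the STAR convention (unique alignments get
    MAPQ 255); use 39 for Bowtie 2 output.
    """
    stats: dict[TagKey, MitoPositionStat] = {}
    for read in reads:
        if not read.is_mapped or not read.is_primary:
            continue
        key = extract_five_prime_tag(read)
        st = stats.get(key)
        if st is None:
            st = stats[key] = MitoPositionStat(key, 0, 0)
        st.n_total += 1
        if read.mapq > mapq_threshold:
            st.n_unique += 1
    return stats


def mito_unique_filter(
    tallies: Iterable[MitoPositionStat], min_ratio: float = 0.8
) -> list[TagKey]:
    """Keep positions whose unique-mapping ratio is >= ``min_ratio`` (inclusive).

    Repeat-derived positions on the mitochondrial genome (reads that also map
    to nuclear sites) fail this filter. Positions with no tags are dropped
    with a warning.
    """
    kept = []
    for st in tallies:
        if st.n_total == 0:
            warnings.warn(f"position {st.key} has no tags; dropped", stacklevel=2)
            continue
        if st.n_unique > st.n_total:
            raise ValueError(f"n_unique > n_total at {st.key}")
        if st.ratio >= min_ratio:
            kept.append(st.key)
    return kept


# --- Serialization ----------------------------------------------------------

_TSV_COLUMNS = [
    "chrom",
    "position",
    "strand",
    "tpm_all",
    "tpm_ct",
    "tpm_cip",
    "enrich_ratio",
    "cip_ratio",
    "status",
    "pol_class",
    "quadrant",
]


def records_to_frame(records: Sequence[TssRecord]) -> pd.DataFrame:
    rows = [
        (
            r.chrom,
            r.position,
            r.strand,
            r.tpm_all,
            r.tpm_ct,
            r.tpm_cip,
            r.enrich_ratio,
            r.cip_ratio,
            r.status.value,
            r.pol_class.value,
            r.quadrant.value,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def write_tss_table(records: Sequence[TssRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_tss_table(path: str | Path) -> list[TssRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            TssRecord(
                chrom=str(row.chrom),
                position=int(row.position),
                strand=row.strand,
                tpm_all=float(row.tpm_all),
                tpm_ct=float(row.tpm_ct),
                tpm_cip=float(row.tpm_cip),
                enrich_ratio=float(row.enrich_ratio),
                cip_ratio=float(row.cip_ratio),
                status=Status(row.status),
                pol_class=PolClass(row.pol_class),
                quadrant=Quadrant(row.quadrant),
            )
        )
    return records


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_bedgraph(records: Sequence[TssRecord], path: str | Path) -> None:
    """Write classified TSSs as a bedGraph browser track.

    Sign convention: positive values are CIP-resistant Pol II TSSs
    (quadrant IV), negative values are CIP-sensitive non-Pol II TSSs
    (quadrant II); the magnitude is the enriched-library TPM. bedGraph has no
    strand column, so this track is lossy — BED6 is the lossless companion.
    """
    with open(path, "w") as fh:
        for r in records:
            if r.pol_class is PolClass.UNASSIGNED:
                raise ValueError(
                    f"unclassified record at {r.key} cannot be written to bedGraph"
                )
            value = r.tpm_all if r.pol_class is PolClass.POL2 else -r.tpm_all
            fh.write(f"{r.chrom}\t{r.position}\t{r.position + 1}\t{_fmt(value)}\n")


def read_bedgraph(path: str | Path) -> list[tuple[str, int, float, PolClass]]:
    """Read a bedGraph written by :func:`write_bedgraph`.

    Returns (chrom, position, tpm magnitude, pol_class) tuples; strand is not
    representable in bedGraph.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, _end, value = line.split("\t")[:4]
            v = float(value)
            cls = PolClass.POL2 if v >= 0 else PolClass.NON_POL2
            out.append((chrom, int(start), abs(v), cls))
    return out


def write_bed6(records: Sequence[TssRecord], path: str | Path) -> None:
    """Write TSS records as BED6: name = pol_class, score = TPM, plus strand."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.position}\t{r.position + 1}\t"
                f"{r.pol_class.value}\t{_fmt(r.tpm_all)}\t{r.strand}\n"
            )


def read_bed6(path: str | Path) -> list[TssRecord]:
    """Read BED6 written by :func:`write_bed6` back into bare records."""
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, _end, name, score, strand = line.rstrip("\n").split("\t")[:6]
            rec = TssRecord(chrom, int(start), strand, tpm_all=float(score))
            rec.pol_class = PolClass(name)
            records.append(rec)
    return records


# --- Headline summaries ------------------------------------------------------


def high_confidence_fraction(n_candidates: int, n_high_confidence: int) -> float:
    """Percentage of candidate TSSs passing the control filter."""
    if n_candidates <= 0:
        raise ValueError("n_candidates must be > 0")
    return 100.0 * n_high_confidence / n_candidates


def non_pol2_share(n_pol2: int, n_non_pol2: int) -> float:
    """Percentage of high-confidence TSSs classified non-Pol II."""
    total = n_pol2 + n_non_pol2
    if total <= 0:
        raise ValueError("no classified TSSs")
    return 100.0 * n_non_pol2 / total
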