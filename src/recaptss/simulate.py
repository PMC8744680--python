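"""Synthetic-library simulator for 5'-end capture sequencing.

Builds a toy genome and annotation, places transcription units with known
5'-end chemistries, and emits already-aligned read sets for the three
libraries (ALL / CIP / CT) under the enrichment logic of the chemistry:

* ``capped`` — m7G-capped Pol II transcripts: decapped and recapped, so
  captured in both enriched libraries;
* ``ppp`` — 5'-triphosphorylated Pol I/III/mitochondrial transcripts:
  captured when untreated, destroyed by phosphatase pretreatment (CIP);
* ``methyl_ppp`` — gamma-methyl-triphosphate ends (7SK-like): phosphatase
  resistant, so retained under CIP and therefore *mis*-classified as Pol II
  by the method — the truth table encodes this known caveat rather than
  idealising it;
* ``processed`` — monophosphate/processed ends (rRNA-like): not cappable,
  captured only at a small background rate in enriched libraries but fully
  present in the unenriched control.

Every artifact of this module is a pure function of (config, seed). Reads
are emitted as aligned SAM records so the downstream pipeline is testable
without an external aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam
import yaml

from .tags import AlignedRead, TagCountTable, count_tags
from .tss import PolClass, Status, TssRecord, classify_tss


class EndClass(str, Enum):
    CAPPED = "capped"
    PPP = "ppp"
    METHYL_PPP = "methyl_ppp"
    PROCESSED = "processed"


class Library(str, Enum):
    ALL = "ALL"
    CIP = "CIP"
    CT = "CT"


# Expected pipeline outcome per chemistry. ``None`` means the position should
# never become a high-confidence TSS.
TRUTH_RULES: dict[EndClass, PolClass | None] = {
    EndClass.CAPPED: PolClass.POL2,
    EndClass.PPP: PolClass.NON_POL2,
    EndClass.METHYL_PPP: PolClass.POL2,  # CIP-resistant, the method's known caveat
    EndClass.PROCESSED: None,
}


def default_capture_matrix(epsilon: float = 0.01) -> dict[tuple[EndClass, Library], float]:
    """Capture probability of each 5'-end chemistry in each library.

    Enriched libraries capture cappable ends at probability 1 and everything
    else at a small background ``epsilon``; CIP pretreatment moves ``ppp``
    ends into the background; the unenriched control captures everything.
    """
    eps = float(epsilon)
    m: dict[tuple[EndClass, Library], float] = {}
    for cls in EndClass:
        m[(cls, Library.CT)] = 1.0
    m[(EndClass.CAPPED, Library.ALL)] = 1.0
    m[(EndClass.PPP, Library.ALL)] = 1.0
    m[(EndClass.METHYL_PPP, Library.ALL)] = 1.0
    m[(EndClass.PROCESSED, Library.ALL)] = eps
    m[(EndClass.CAPPED, Library.CIP)] = 1.0
    m[(EndClass.PPP, Library.CIP)] = eps
    m[(EndClass.METHYL_PPP, Library.CIP)] = 1.0
    m[(EndClass.PROCESSED, Library.CIP)] = eps
    return m


# gene_type written to the synthetic GTF, one plausible biotype per chemistry
_GENE_TYPES = {
    EndClass.CAPPED: "protein_coding",
    EndClass.PPP: "tRNA",
    EndClass.METHYL_PPP: "snRNA",
    EndClass.PROCESSED: "rRNA",
}


@dataclass(frozen=True)
class SimGene:
    gene_id: str
    chrom: str
    strand: str
    tss_pos: int  # 0-based genomic position of the true TSS
    length: int
    end_class: EndClass
    abundance: float

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError("abundance must be > 0")
        if self.length <= 0:
            raise ValueError("length must be > 0")

    @property
    def footprint(self) -> tuple[int, int]:
        """Genomic interval [start, end) covered by the transcription unit."""
        if self.strand == "+":
            return (self.tss_pos, self.tss_pos + self.length)
        return (self.tss_pos - self.length + 1, self.tss_pos + 1)


@dataclass(frozen=True)
class TruthRecord:
    chrom: str
    position: int
    strand: str
    end_class: EndClass
    expected_pol_class: PolClass | None
    expected_hc: bool

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.position, self.strand)


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe a small transcriptome with all four 5'-end chemistries:
    50 transcription units on two 100 kb contigs, lognormal abundances, a
    1% background capture rate for non-cappable ends, and 30% of the RNA
    mass being degraded fragments with processed 5' ends (degradation is
    pervasive in real total-RNA preparations and is what the unenriched
    control exists to flag).
    """

    genome_length: int = 100_000  # per contig
    n_contigs: int = 2
    genes_per_class: dict = field(
        default_factory=lambda: {
            EndClass.CAPPED: 20,
            EndClass.PPP: 15,
            EndClass.METHYL_PPP: 5,
            EndClass.PROCESSED: 10,
        }
    )
    gene_length_range: tuple[int, int] = (400, 1200)
    capture: dict = field(default_factory=default_capture_matrix)
    degraded_fraction: float = 0.3
    read_length: int = 50
    n_reads: int = 200_000
    positional_jitter: float = 0.0  # probability mass on +/-1 start offsets
    abundance_sigma: float = 1.0  # lognormal spread of expression weights
    mapq: int = 255
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be > 0")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be > 0")
        for key, p in self.capture.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"capture probability out of [0, 1] for {key}: {p}")
        if not 0.0 <= self.degraded_fraction <= 1.0:
            raise ValueError("degraded_fraction must be in [0, 1]")
        if not 0.0 <= self.positional_jitter <= 1.0:
            raise ValueError("positional_jitter must be in [0, 1]")

    def contig_names(self) -> list[str]:
        return [f"sim{i + 1}" for i in range(self.n_contigs)]

    # -- YAML round trip ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "genome_length": self.genome_length,
            "n_contigs": self.n_contigs,
            "genes_per_class": {k.value: v for k, v in self.genes_per_class.items()},
            "gene_length_range": list(self.gene_length_range),
            "capture": {f"{c.value}/{l.value}": p for (c, l), p in self.capture.items()},
            "degraded_fraction": self.degraded_fraction,
            "read_length": self.read_length,
            "n_reads": self.n_reads,
            "positional_jitter": self.positional_jitter,
            "abundance_sigma": self.abundance_sigma,
            "mapq": self.mapq,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "genes_per_class" in data:
            data["genes_per_class"] = {
                EndClass(k): v for k, v in data["genes_per_class"].items()
            }
        if "capture" in data:
            cap = {}
            for key, p in data["capture"].items():
                c, l = key.split("/")
                cap[(EndClass(c), Library(l))] = float(p)
            data["capture"] = cap
        if "gene_length_range" in data:
            data["gene_length_range"] = tuple(data["gene_length_range"])
        return cls(**data)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per subsystem
    return np.random.default_rng([config.seed, stream])


def make_genome(config: SimConfig) -> dict[str, str]:
    """Seeded i.i.d. uniform A/C/G/T contigs; deterministic per seed."""
    rng = _rng(config, 1)
    bases = np.array(list("ACGT"))
    genome = {}
    for name in config.contig_names():
        idx = rng.integers(0, 4, size=config.genome_length)
        genome[name] = "".join(bases[idx])
    return genome


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def place_genes(
    config: SimConfig, genome: dict[str, str], max_tries: int = 10_000
) -> tuple[list[SimGene], list[TruthRecord]]:
    """Place non-overlapping transcription units on both strands.

    Each unit gets a lognormal abundance weight and a truth record derived
    mechanically from its 5'-end chemistry.
    """
    rng = _rng(config, 2)
    contigs = list(genome.keys())
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    genes: list[SimGene] = []
    truth: list[TruthRecord] = []
    counter = 0
    for cls in EndClass:
        n = config.genes_per_class.get(cls, 0)
        for _ in range(n):
            counter += 1
            lo, hi = config.gene_length_range
            length = int(rng.integers(lo, hi + 1))
            placed = False
            for _try in range(max_tries):
                chrom = contigs[int(rng.integers(0, len(contigs)))]
                contig_len = len(genome[chrom])
                if contig_len < length:
                    continue
                start = int(rng.integers(0, contig_len - length + 1))
                end = start + length
                if any(s < end and start < e for s, e in occupied[chrom]):
                    continue
                occupied[chrom].append((start, end))
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place gene {counter} without overlap after {max_tries} tries"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end - 1
            abundance = float(rng.lognormal(0.0, config.abundance_sigma))
            gene = SimGene(
                gene_id=f"simg{counter:04d}_{cls.value}",
                chrom=chrom,
                strand=strand,
                tss_pos=tss,
                length=length,
                end_class=cls,
                abundance=abundance,
            )
            genes.append(gene)
            expected = TRUTH_RULES[cls]
            truth.append(
                TruthRecord(
                    chrom=chrom,
                    position=tss,
                    strand=strand,
                    end_class=cls,
                    expected_pol_class=expected,
                    expected_hc=expected is not None,
                )
            )
    return genes, truth


def write_gtf(genes: Sequence[SimGene], path: str | Path) -> None:
    """One gene + one exon feature per unit, GENCODE-dialect attributes."""
    with open(path, "w") as fh:
        for g in genes:
            start, end = g.footprint
            attrs = (
                f'gene_id "{g.gene_id}"; gene_type "{_GENE_TYPES[g.end_class]}"; '
                f'gene_name "{g.gene_id}";'
            )
            for feature in ("gene", "exon"):
                fh.write(
                    f"{g.chrom}\tsim\t{feature}\t{start + 1}\t{end}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def write_truth(truth: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tposition\tstrand\tend_class\texpected_pol_class\texpected_hc\n")
        for t in truth:
            cls = t.expected_pol_class.value if t.expected_pol_class else "none"
            fh.write(
                f"{t.chrom}\t{t.position}\t{t.strand}\t{t.end_class.value}\t{cls}\t"
                f"{int(t.expected_hc)}\n"
            )


def read_truth(path: str | Path) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            chrom, pos, strand, cls, pol, hc = line.rstrip("\n").split("\t")
            out.append(
                TruthRecord(
                    chrom=chrom,
                    position=int(pos),
                    strand=strand,
                    end_class=EndClass(cls),
                    expected_pol_class=None if pol == "none" else PolClass(pol),
                    expected_hc=bool(int(hc)),
                )
            )
    return out


def simulate_library(
    genes: Sequence[SimGene],
    config: SimConfig,
    library: Library,
    contig_lengths: dict[str, int] | None = None,
) -> list[AlignedRead]:
    """Draw ``config.n_reads`` aligned reads for one library.

    Each gene contributes two emission units: reads starting at its TSS
    (weight abundance x (1 - degraded_fraction) x capture[end_class]) and
    degraded fragments starting at uniform internal positions, which carry a
    processed 5' end regardless of the gene's own chemistry (weight
    abundance x degraded_fraction x capture[processed]). TSS starts are
    jittered to +/-1 with probability ``positional_jitter`` (split evenly).
    """
    library = Library(library)
    weights = []
    units = []  # (gene, is_degraded)
    for g in genes:
        cap_tss = config.capture[(g.end_class, library)]
        cap_deg = config.capture[(EndClass.PROCESSED, library)]
        w_tss = g.abundance * (1.0 - config.degraded_fraction) * cap_tss
        w_deg = g.abundance * config.degraded_fraction * cap_deg
        if w_tss > 0:
            units.append((g, False))
            weights.append(w_tss)
        if w_deg > 0 and g.length > 1:
            units.append((g, True))
            weights.append(w_deg)
    total = float(sum(weights))
    if total <= 0:
        raise ValueError(f"all capture probabilities are 0 for library {library.value}")
    probs = np.asarray(weights) / total
    rng = _rng(config, 10 + list(Library).index(library))
    counts = rng.multinomial(config.n_reads, probs)
    j = config.positional_jitter
    reads: list[AlignedRead] = []
    for (gene, degraded), n in zip(units, counts):
        if n == 0:
            continue
        contig_len = (
            contig_lengths[gene.chrom]
            if contig_lengths is not None
            else config.genome_length
        )
        if degraded:
            # internal transcript positions 1..length-1, never the TSS itself
            offsets = rng.integers(1, gene.length, size=n)
        else:
            offsets = np.zeros(n, dtype=np.int64)
            if j > 0:
                u = rng.random(n)
                offsets[u < j / 2] = -1
                offsets[(u >= j / 2) & (u < j)] = 1
        if gene.strand == "+":
            starts5 = gene.tss_pos + offsets
        else:
            starts5 = gene.tss_pos - offsets
        starts5 = np.clip(starts5, 0, contig_len - 1)
        for p5 in starts5:
            p5 = int(p5)
            if gene.strand == "+":
                start = p5
                end = min(p5 + config.read_length, contig_len)
            else:
                end = p5 + 1
                start = max(0, end - config.read_length)
            reads.append(
                AlignedRead(
                    chrom=gene.chrom,
                    start=start,
                    end=end,
                    strand=gene.strand,
                    mapq=config.mapq,
                )
            )
    return reads


def write_sam(
    reads: Sequence[AlignedRead],
    contig_lengths: dict[str, int],
    path: str | Path,
    genome: dict[str, str] | None = None,
) -> None:
    """Emit reads as an aligned SAM file (text, sorted as given).

    With ``genome`` the query sequences are filled in from the reference
    (reverse-complemented for minus-strand reads); otherwise SEQ is ``*``.
    """
    from ._util import revcomp

    names = list(contig_lengths.keys())
    header = pysam.AlignmentHeader.from_references(names, list(contig_lengths.values()))
    ref_id = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i, r in enumerate(reads):
            seg = pysam.AlignedSegment(header)
            seg.query_name = f"simread{i + 1}"
            seg.reference_id = ref_id[r.chrom]
            seg.reference_start = r.start
            seg.mapping_quality = r.mapq
            seg.flag = 0 if r.strand == "+" else 16
            if not r.is_primary:
                seg.flag |= 256
            span = r.end - r.start
            if genome is not None:
                seq = genome[r.chrom][r.start : r.end]
                if r.strand == "-":
                    seq = revcomp(seq)
                clip = r.softclip_seq
                if r.strand == "+":
                    seg.query_sequence = clip + seq if clip else seq
                    seg.cigarstring = (f"{len(clip)}S" if clip else "") + f"{span}M"
                else:
                    # stored clip is reference-forward; it trails in SAM space
                    seg.query_sequence = seq + clip if clip else seq
                    seg.cigarstring = f"{span}M" + (f"{len(clip)}S" if clip else "")
            else:
                seg.cigarstring = f"{span}M"
            fh.write(seg)


@dataclass
class SimDataset:
    """Everything one simulation run produces, in memory."""

    config: SimConfig
    genome: dict[str, str]
    genes: list[SimGene]
    truth: list[TruthRecord]
    reads: dict[Library, list[AlignedRead]]

    def tag_tables(self) -> dict[Library, TagCountTable]:
        return {lib: count_tags(reads) for lib, reads in self.reads.items()}

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, out / "genome.fa")
        write_gtf(self.genes, out / "annotation.gtf")
        write_truth(self.truth, out / "truth.tsv")
        lengths = {c: len(s) for c, s in self.genome.items()}
        for lib, reads in self.reads.items():
            write_sam(reads, lengths, out / f"{lib.value.lower()}.sam", genome=self.genome)


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Genome + annotation + three read libraries + truth, from one config."""
    genome = make_genome(config)
    genes, truth = place_genes(config, genome)
    lengths = {c: len(s) for c, s in genome.items()}
    reads = {
        lib: simulate_library(genes, config, lib, contig_lengths=lengths)
        for lib in Library
    }
    return SimDataset(config=config, genome=genome, genes=genes, truth=truth, reads=reads)


# --- End-to-end check ---------------------------------------------------------


@dataclass
class EndToEndReport:
    """Outcome of simulate -> count -> call -> classify versus the truth table.

    ``confusion`` maps each end-class to outcome counts with keys
    ``pol2`` / ``non_pol2`` (detected high-confidence, classified), ``fp``
    (candidate rejected by the control filter), ``absent`` (never reached
    candidate level). ``background`` tallies candidate positions that are not
    true TSSs (degraded/noise positions) and how the control filter handled
    them.
    """

    confusion: dict[str, dict[str, int]]
    background: dict[str, int]
    n_truth: int
    n_candidates: int

    @property
    def true_tss_accuracy(self) -> float:
        """Fraction of true TSSs with exactly the expected pipeline outcome."""
        correct = 0
        total = 0
        for cls, outcomes in self.confusion.items():
            expected = TRUTH_RULES[EndClass(cls)]
            total += sum(outcomes.values())
            if expected is None:
                correct += outcomes["fp"] + outcomes["absent"]
            else:
                correct += outcomes[expected.value]
        return correct / total if total else float("nan")


def end_to_end_check(
    config: SimConfig,
    min_tpm: float = 1.0,
    hc_ratio: float = 1.0,
    cip_threshold: float = 4.0,
) -> EndToEndReport:
    """Run the full pipeline on one simulated dataset and score it."""
    ds = simulate_dataset(config)
    tables = ds.tag_tables()
    records = classify_tss(
        tables[Library.ALL],
        tables[Library.CT],
        tables[Library.CIP],
        min_tpm=min_tpm,
        hc_ratio=hc_ratio,
        cip_threshold=cip_threshold,
    )
    by_key: dict[tuple[str, int, str], TssRecord] = {r.key: r for r in records}
    confusion: dict[str, dict[str, int]] = {
        cls.value: {"pol2": 0, "non_pol2": 0, "fp": 0, "absent": 0} for cls in EndClass
    }
    truth_keys = set()
    for t in ds.truth:
        truth_keys.add(t.key)
        rec = by_key.get(t.key)
        if rec is None:
            outcome = "absent"
        elif rec.status is Status.FALSE_POSITIVE:
            outcome = "fp"
        else:
            outcome = rec.pol_class.value
        confusion[t.end_class.value][outcome] += 1
    background = {"candidates": 0, "filtered_fp": 0, "hc_pol2": 0, "hc_non_pol2": 0}
    for rec in records:
        if rec.key in truth_keys:
            continue
        background["candidates"] += 1
        if rec.status is Status.FALSE_POSITIVE:
            background["filtered_fp"] += 1
        elif rec.pol_class is PolClass.POL2:
            background["hc_pol2"] += 1
        else:
            background["hc_non_pol2"] += 1
    return EndToEndReport(
        confusion=confusion,
        background=background,
        n_truth=len(ds.truth),
        n_candidates=len(records),
    )


def noise_free_config(**overrides) -> SimConfig:
    """A convenience config with all noise sources off (exact-recovery regime)."""
    base = SimConfig(
        capture=default_capture_matrix(epsilon=0.0),
        degraded_fraction=0.0,
        positional_jitter=0.0,
    )
    return replace(base, **overrides)
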