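"""Core domain containers shared across the pipeline.

Every interval in the package is 0-based half-open on genomic coordinates;
strand is '+' or '-'. Reads carry their condition (MN = motoneuron-specific
CLIP, WSC = whole-spinal-cord reference) and biological-replicate label,
which the biological-complexity filters and per-condition counts rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from Bio.Seq import reverse_complement

STRANDS = ("+", "-")
CONDITIONS = ("MN", "WSC")


class Genome:
    """In-memory genome: chromosome name -> uppercase DNA string."""

    def __init__(self, seqs: dict[str, str]):
        for name, seq in seqs.items():
            if len(seq) == 0:
                raise ValueError(f"chromosome {name!r} has empty sequence")
        self.seqs = {name: seq.upper() for name, seq in seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.seqs

    def length(self, chrom: str) -> int:
        return len(self.seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end); reverse-complemented for '-'.

        Raises if the window falls outside the chromosome.
        """
        if chrom not in self.seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > len(self.seqs[chrom]) or start > end:
            raise ValueError(f"window [{start}, {end}) outside {chrom}")
        seq = self.seqs[chrom][start:end]
        return reverse_complement(seq) if strand == "-" else seq

    def composition(self, intervals=None) -> dict[str, float]:
        """Mononucleotide frequencies over the genome or given (chrom, start, end)s."""
        counts = {b: 0 for b in "ACGT"}
        if intervals is None:
            chunks = self.seqs.values()
        else:
            chunks = (self.seqs[c][s:e] for c, s, e in intervals)
        for chunk in chunks:
            for b in "ACGT":
                counts[b] += chunk.count(b)
        total = sum(counts.values())
        if total == 0:
            raise ValueError("no A/C/G/T bases in the requested region")
        return {b: counts[b] / total for b in "ACGT"}


@dataclass(frozen=True)
class AlignedRead:
    """One uniquely mapped, strand-specific CLIP read interval."""

    chrom: str
    start: int
    end: int
    strand: str
    condition: str
    replicate: int
    read_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"zero/negative-length read [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        if self.replicate < 1:
            raise ValueError("replicate labels are 1-based")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def shifted(self, k: int) -> "AlignedRead":
        return replace(self, start=self.start + k, end=self.end + k)


@dataclass
class GeneModel:
    """A stranded transcription unit: gene span plus 10 kb downstream.

    ``exons`` is the merged exon union across transcripts (sorted,
    non-overlapping). The transcription unit [tu_start, tu_end) extends the
    gene span 10 kb past the 3' end, strand-aware, clipped at chromosome
    bounds.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    tu_start: int
    tu_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    transcripts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if not (self.tu_start <= self.start < self.end <= self.tu_end):
            raise ValueError(f"transcription unit does not contain gene {self.gene_id}")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"exon [{s}, {e}) outside gene span of {self.gene_id}")

    @property
    def tu_length(self) -> int:
        return self.tu_end - self.tu_start

    def classify(self, pos: int) -> str:
        """Region of a genomic position: exon | intron | downstream | unassigned."""
        if not self.tu_start <= pos < self.tu_end:
            return "unassigned"
        if self.start <= pos < self.end:
            for s, e in self.exons:
                if s <= pos < e:
                    return "exon"
            return "intron"
        return "downstream"


@dataclass
class Peak:
    """A maximal run of CLIP coverage exceeding the gene-specific null height."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    summit_height: int
    read_count: int
    p_value: float
    region_class: str = ""
    normalized_height: float = float("nan")
    bc: int = 0

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class JointPeakCounts:
    """Per-condition read counts of one joint peak and its gene-level totals.

    m / n: MN / WSC reads in the JP; M / N: MN / WSC reads in all JPs of the
    same region class (intron vs exon) in the gene.
    """

    jp_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    region_class: str
    m: int
    n: int
    M: int = 0
    N: int = 0
    bc_mn: int = 0
    bc_wsc: int = 0

    def __post_init__(self) -> None:
        if self.m < 0 or self.n < 0:
            raise ValueError("negative read counts")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def validate_totals(self) -> None:
        if not (0 <= self.m <= self.M and 0 <= self.n <= self.N):
            raise ValueError(f"inconsistent totals for {self.jp_id}")
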