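"""Readers and writers for the on-disk formats plus run configuration.

Formats: FASTA (genome), GTF (gene models), BED6 (reads and peaks),
BedGraph (per-base conservation scores), GMT (gene sets), TSV (result
tables), YAML (configuration). All intervals on disk and in memory are
0-based half-open except GTF, which is converted from its native 1-based
closed convention on read/write.
"""

from __future__ import annotations

import io
import math
from dataclasses import asdict, dataclass, field

import gffutils
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import AlignedRead, GeneModel, Genome

DOWNSTREAM_EXTENSION = 10_000


@dataclass
class RunConfig:
    """Named cutoffs of the analysis; defaults are the study's printed values."""

    seed: int = 0
    peak_alpha: float = 0.01
    site_fdr: float = 0.1
    site_fold: float = 2.0
    coverage_min: int = 10
    gene_fdr: float = 0.01
    splicing_fdr: float = 0.1
    ale_dI: float = 0.2
    expressed_junction_min: int = 10
    hotspot_nt: int = 400
    motif_halfwindow: int = 100
    bc_mn: int = 4
    bc_wsc: int = 2
    n_reps_mn: int = 8
    n_reps_wsc: int = 4
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "peak_alpha", "site_fdr", "site_fold", "coverage_min", "splicing_fdr",
            "ale_dI", "expressed_junction_min", "hotspot_nt", "motif_halfwindow",
            "bc_mn", "bc_wsc", "n_reps_mn", "n_reps_wsc", "gene_fdr",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> Genome:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return Genome(seqs)


def write_fasta(genome: Genome, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(genome.seqs.items())
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- BED6

def read_bed6(path) -> list[AlignedRead]:
    """Read aligned CLIP reads from BED6.

    The name column encodes provenance as ``condition:replicate:read_id``
    (BED has no dedicated columns for either). Order is preserved.
    """
    reads: list[AlignedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 tab-separated columns")
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: start >= end")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            parts = name.split(":", 2)
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: name must be condition:replicate:read_id"
                )
            condition, rep_s, read_id = parts
            try:
                replicate = int(rep_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer replicate") from exc
            reads.append(
                AlignedRead(chrom, start, end, strand, condition, replicate, read_id)
            )
    return reads


def write_bed6(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            name = f"{r.condition}:{r.replicate}:{r.read_id}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")


def write_peaks_bed(peaks, path) -> None:
    """Peaks as BED6; the score column carries the raw read count."""
    with open(path, "w") as fh:
        for p in sorted(peaks, key=lambda p: (p.chrom, p.start, p.gene_id)):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.gene_id}\t{p.read_count}\t{p.strand}\n"
            )


# ---------------------------------------------------------------- GTF

def _gene_model_from_db(db, gene, chrom_lengths) -> GeneModel:
    gene_id = gene.attributes.get("gene_id", [gene.id])[0]
    if gene.strand not in ("+", "-"):
        raise ValueError(f"unknown strand for gene {gene_id}")
    start = gene.start - 1  # to 0-based half-open
    end = gene.end
    transcripts: dict[str, list[tuple[int, int]]] = {}
    for tx in db.children(gene, featuretype="transcript"):
        tx_id = tx.attributes.get("transcript_id", [tx.id])[0]
        exons = sorted((e.start - 1, e.end) for e in db.children(tx, featuretype="exon"))
        for s, e in exons:
            if s < start or e > end:
                raise ValueError(f"exon [{s}, {e}) outside gene span of {gene_id}")
        transcripts[tx_id] = exons
    # merged exon union across transcripts
    all_exons = sorted(iv for ivs in transcripts.values() for iv in ivs)
    merged: list[tuple[int, int]] = []
    for s, e in all_exons:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    chrom_len = None if chrom_lengths is None else chrom_lengths.get(gene.seqid)
    if gene.strand == "+":
        tu_start = start
        tu_end = end + DOWNSTREAM_EXTENSION
        if chrom_len is not None:
            tu_end = min(tu_end, chrom_len)
    else:
        tu_start = max(0, start - DOWNSTREAM_EXTENSION)
        tu_end = end
    return GeneModel(
        gene_id=gene_id,
        chrom=gene.seqid,
        strand=gene.strand,
        start=start,
        end=end,
        tu_start=tu_start,
        tu_end=tu_end,
        exons=merged,
        transcripts=transcripts,
    )


def read_gtf(path, chrom_lengths: dict[str, int] | None = None) -> list[GeneModel]:
    """Read gene models from GTF; one transcription unit per gene_id.

    Each unit is the gene span extended 10 kb past the 3' end (strand-aware),
    clipped at chromosome bounds when ``chrom_lengths`` is given.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = [
        _gene_model_from_db(db, g, chrom_lengths) for g in db.features_of_type("gene")
    ]
    genes.sort(key=lambda g: (g.chrom, g.tu_start, g.gene_id))
    return genes


def write_gtf(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tclipmap\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for tx_id, exons in g.transcripts.items():
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{tx_id}";'
                tx_start = min(s for s, _ in exons)
                tx_end = max(e for _, e in exons)
                fh.write(
                    f"{g.chrom}\tclipmap\ttranscript\t{tx_start + 1}\t{tx_end}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for s, e in exons:
                    fh.write(
                        f"{g.chrom}\tclipmap\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tattrs}\n"
                    )


# ---------------------------------------------------------------- BedGraph

def read_bedgraph(path, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-base score arrays from BedGraph; uncovered bases are NaN.

    Tolerant of unsorted input; later lines overwrite earlier ones.
    """
    track = {c: np.full(n, np.nan) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in track:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            track[chrom][start:end] = value
    return track


def write_bedgraph(track: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track):
            values = track[chrom]
            covered = ~np.isnan(values)
            if not covered.any():
                continue
            # maximal runs of equal, covered values
            pos = 0
            n = len(values)
            while pos < n:
                if not covered[pos]:
                    pos += 1
                    continue
                run_end = pos + 1
                while run_end < n and covered[run_end] and values[run_end] == values[pos]:
                    run_end += 1
                fh.write(f"{chrom}\t{pos}\t{run_end}\t{values[pos]:g}\n")
                pos = run_end


# ---------------------------------------------------------------- GMT

def read_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected name, description, genes")
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


# ---------------------------------------------------------------- TSV reports

_SORT_CANDIDATES = ("chrom", "start", "gene_id", "jp_id", "event_id", "id")


def write_tsv_report(records: pd.DataFrame, path) -> None:
    """Deterministic TSV: stable sort, fixed float precision, NaN -> "NA"."""
    df = records.copy()
    sort_cols = [c for c in _SORT_CANDIDATES if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_tsv_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
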