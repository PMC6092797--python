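"""Read deduplication, the RT-artifact pentamer filter, and read summaries.

The artifact filter targets a reverse-transcription caveat: the RT primer
can prime internally by hybridising to GUGUC-like pentamers in the CLIPed
RNA, preferentially amplifying reads that end immediately upstream of such
a pentamer. Reads whose strand-aware downstream 5-mer ranks among the most
frequent pentamers and is GTGTC-like are removed.
"""

from __future__ import annotations

from collections import Counter

import pandas as pd

from .models import AlignedRead, Genome

ARTIFACT_PENTAMER = "GTGTC"


def deduplicate(reads) -> list[AlignedRead]:
    """Collapse reads to one per (chrom, start, end, strand) per replicate.

    Keep-first and stable: the surviving read is the first seen in input
    order. Reads from different replicates never collapse onto each other,
    which the biological-complexity filters depend on.
    """
    seen: set[tuple] = set()
    out: list[AlignedRead] = []
    for r in reads:
        key = (r.condition, r.replicate, r.chrom, r.start, r.end, r.strand)
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))


def downstream_pentamer(read: AlignedRead, genome: Genome) -> str | None:
    """The 5-mer starting at the base after the read's 3' end, on the read strand.

    Returns None when the chromosome leaves fewer than 5 nt of flank.
    """
    if read.chrom not in genome:
        raise KeyError(f"read chromosome {read.chrom!r} not in genome")
    n = genome.length(read.chrom)
    if read.end > n or read.start < 0:
        raise ValueError(f"read [{read.start}, {read.end}) outside {read.chrom}")
    if read.strand == "+":
        if read.end + 5 > n:
            return None
        return genome.fetch(read.chrom, read.end, read.end + 5, "+")
    if read.start - 5 < 0:
        return None
    return genome.fetch(read.chrom, read.start - 5, read.start, "-")


def filter_rt_artifacts(
    reads,
    genome: Genome,
    top_n: int = 20,
    max_mismatch: int = 1,
    rule: str = "top-then-like",
):
    """Remove reads lying immediately upstream of frequent GTGTC-like pentamers.

    Procedure: (1) take the strand-aware downstream 5-mer of every read;
    (2) rank observed pentamers by frequency (ties broken lexicographically
    for determinism); (3) flag pentamers to remove; (4) drop every read whose
    downstream pentamer is flagged. Reads with under 5 nt of flank cannot be
    evaluated and are kept.

    ``rule`` selects which pentamers are flagged:

    - ``"top-then-like"`` (default): GTGTC-like (Hamming <= ``max_mismatch``)
      members of the ``top_n`` most frequent pentamers;
    - ``"like-then-top"``: the ``top_n`` most frequent among GTGTC-like
      pentamers, regardless of global rank.

    Returns ``(kept, removed, pentamer_report)`` where the report lists every
    observed pentamer with its count, rank, distance to GTGTC and flag.
    """
    if rule not in ("top-then-like", "like-then-top"):
        raise ValueError(f"unknown rule {rule!r}")
    pent_of: list[str | None] = [downstream_pentamer(r, genome) for r in reads]
    counts = Counter(p for p in pent_of if p is not None)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    report = pd.DataFrame(
        {
            "pentamer": [p for p, _ in ranked],
            "count": [c for _, c in ranked],
            "rank": range(1, len(ranked) + 1),
            "distance_to_GTGTC": [hamming(p, ARTIFACT_PENTAMER) for p, _ in ranked],
        }
    )
    if rule == "top-then-like":
        flagged = set(
            report.loc[
                (report["rank"] <= top_n)
                & (report["distance_to_GTGTC"] <= max_mismatch),
                "pentamer",
            ]
        )
    else:
        like = report[report["distance_to_GTGTC"] <= max_mismatch]
        flagged = set(like["pentamer"].head(top_n))
    report["flagged"] = report["pentamer"].isin(flagged)
    kept, removed = [], []
    for r, p in zip(reads, pent_of):
        (removed if p in flagged else kept).append(r)
    return kept, removed, report


def genomic_distribution(reads, genes) -> pd.DataFrame:
    """Fraction of reads per genomic category, assigned by read midpoint.

    Priority exon > intron > downstream-10kb; reads outside every
    transcription unit are reported as "unassigned". Fractions sum to 1.
    """
    from .peaks import assign_reads_to_genes  # local import to avoid a cycle

    assigned = assign_reads_to_genes(reads, genes)
    gene_by_id = {g.gene_id: g for g in genes}
    counts = Counter()
    n_assigned = 0
    for gene_id, gene_reads in assigned.items():
        gene = gene_by_id[gene_id]
        for r in gene_reads:
            counts[gene.classify(r.midpoint)] += 1
            n_assigned += 1
    counts["unassigned"] += len(reads) - n_assigned
    total = sum(counts.values())
    rows = [
        {"category": cat, "count": c, "fraction": c / total if total else float("nan")}
        for cat, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows)
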