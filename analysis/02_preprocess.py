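#!/usr/bin/env python
"""Deduplicate CLIP reads, apply the RT-artifact pentamer filter, and
summarise the genomic distribution of the surviving reads."""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location("paths", Path(__file__).parent / "00_paths.py")
paths = importlib.util.module_from_spec(spec)
spec.loader.exec_module(paths)

import pandas as pd

from clipmap.io_formats import read_bed6, read_fasta, read_gtf, write_bed6, write_tsv_report
from clipmap.preprocess import deduplicate, filter_rt_artifacts, genomic_distribution


def main() -> None:
    genome = read_fasta(paths.SCRATCH / "genome.fa")
    chrom_lengths = {c: genome.length(c) for c in genome.seqs}
    genes = read_gtf(paths.SCRATCH / "genes.gtf", chrom_lengths=chrom_lengths)
    reads = read_bed6(paths.SCRATCH / "reads_mn.bed") + read_bed6(paths.SCRATCH / "reads_wsc.bed")

    deduped = deduplicate(reads)
    kept, removed, report = filter_rt_artifacts(deduped, genome)
    write_tsv_report(report, paths.RESULTS / "pentamer_report.tsv")
    write_bed6(kept, paths.SCRATCH / "reads_filtered.bed")

    truth_ids = set(
        pd.read_csv(paths.SCRATCH / "truth_artifact_reads.tsv", sep="\t")["read_id"]
    )
    removed_ids = {f"{r.condition}:{r.replicate}:{r.read_id}" for r in removed}
    reached = truth_ids & {f"{r.condition}:{r.replicate}:{r.read_id}" for r in kept + removed}
    recall = len(truth_ids & removed_ids) / len(reached) if reached else float("nan")

    dist = genomic_distribution(kept, genes)
    write_tsv_report(dist, paths.RESULTS / "read_distribution.tsv")

    flagged = report[report["flagged"]]
    print(f"{len(reads)} reads -> {len(deduped)} after deduplication "
          f"-> {len(kept)} after the pentamer filter ({len(removed)} removed)")
    print(f"flagged pentamers: {', '.join(flagged['pentamer'])} "
          f"(top-ranked: {report.iloc[0]['pentamer']})")
    print(f"recall of planted artifact reads: {recall:.1%}")
    print(dist.to_string(index=False))


if __name__ == "__main__":
    main()
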