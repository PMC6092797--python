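#!/usr/bin/env python
"""Call joint peaks on pooled MN+WSC reads and apply the biological
complexity filter (MN BC >= 4/8 or WSC BC >= 2/4)."""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location("paths", Path(__file__).parent / "00_paths.py")
paths = importlib.util.module_from_spec(spec)
spec.loader.exec_module(paths)

import pandas as pd

from clipmap.io_formats import RunConfig, read_bed6, read_fasta, read_gtf, write_tsv_report
from clipmap.peaks import define_joint_peaks


def main() -> None:
    cfg = RunConfig(seed=paths.SEED)
    genome = read_fasta(paths.SCRATCH / "genome.fa")
    genes = read_gtf(
        paths.SCRATCH / "genes.gtf",
        chrom_lengths={c: genome.length(c) for c in genome.seqs},
    )
    reads = read_bed6(paths.SCRATCH / "reads_filtered.bed")
    mn = [r for r in reads if r.condition == "MN"]
    wsc = [r for r in reads if r.condition == "WSC"]

    jps = define_joint_peaks(mn, wsc, genes, cfg)
    table = pd.DataFrame(
        [
            {"jp_id": jp.jp_id, "gene_id": jp.gene_id, "chrom": jp.chrom,
             "start": jp.start, "end": jp.end, "strand": jp.strand,
             "region_class": jp.region_class, "m": jp.m, "n": jp.n,
             "M": jp.M, "N": jp.N, "bc_mn": jp.bc_mn, "bc_wsc": jp.bc_wsc}
            for jp in jps
        ]
    )
    write_tsv_report(table, paths.RESULTS / "joint_peaks.tsv")
    by_class = table["region_class"].value_counts().to_dict()
    print(f"{len(jps)} joint peaks over {table['gene_id'].nunique()} genes "
          f"({by_class.get('intron', 0)} intronic, {by_class.get('exon', 0)} exonic)")
    print(f"table -> {paths.RESULTS / 'joint_peaks.tsv'}")


if __name__ == "__main__":
    main()
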