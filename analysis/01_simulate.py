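#!/usr/bin/env python
"""Simulate the two-condition CLIP study and write it to disk.

Emulates the study design: 8 motoneuron (MN) CLIP replicates against 4
whole-spinal-cord (WSC) replicates at ~8x the depth, 30-80 nt reads,
planted YCAY binding-site clusters (a sparse subset with fourfold MN
binding changes), GTGTC RT-artifact reads, and junction counts whose
inclusion shifts are coupled to binding changes by the position rule.
"""

import importlib.util
import sys
from pathlib import Path

spec = importlib.util.spec_from_file_location("paths", Path(__file__).parent / "00_paths.py")
paths = importlib.util.module_from_spec(spec)
spec.loader.exec_module(paths)

from clipmap.io_formats import write_bed6, write_fasta, write_gtf, write_tsv_report
from clipmap.synthetic import SimulationParams, simulate_dataset


def main() -> None:
    params = SimulationParams(n_genes=paths.N_GENES, seed=paths.SEED)
    ds = simulate_dataset(params)
    out = paths.SCRATCH
    out.mkdir(parents=True, exist_ok=True)

    write_fasta(ds.genome, out / "genome.fa")
    write_gtf(ds.genes, out / "genes.gtf")
    write_bed6(ds.mn_reads, out / "reads_mn.bed")
    write_bed6(ds.wsc_reads, out / "reads_wsc.bed")
    ds.junction_counts.to_csv(out / "junction_counts.tsv", sep="\t", index=False)

    import pandas as pd

    sites = pd.DataFrame(
        [
            {"site_id": s.site_id, "gene_id": s.gene_id, "chrom": s.chrom,
             "start": s.start, "end": s.end, "mn_multiplier": s.mn_multiplier,
             "coupled_event_id": s.coupled_event_id, "side": s.side}
            for s in ds.truth.planted_sites
        ]
    )
    paths.RESULTS.mkdir(parents=True, exist_ok=True)
    write_tsv_report(sites, paths.RESULTS / "truth_sites.tsv")
    write_tsv_report(ds.truth.events, paths.RESULTS / "truth_events.tsv")
    pd.DataFrame(
        [{"read_id": rid} for rid in sorted(ds.truth.artifact_read_ids)]
    ).to_csv(out / "truth_artifact_reads.tsv", sep="\t", index=False)

    n_diff = sum(1 for s in ds.truth.planted_sites if s.is_differential)
    print(f"simulated {len(ds.genes)} genes, {len(ds.reads)} reads "
          f"({len(ds.mn_reads)} MN / {len(ds.wsc_reads)} WSC)")
    print(f"planted {len(ds.truth.planted_sites)} sites ({n_diff} differential), "
          f"{len(ds.truth.events)} splicing events, "
          f"{len(ds.truth.artifact_read_ids)} artifact reads")
    print(f"raw data -> {out}")


if __name__ == "__main__":
    main()
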