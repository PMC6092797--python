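#!/usr/bin/env python
"""The position-dependent RNA map: predict splicing direction from
differential binding within 400 nt of regulated exons, score concordance
against the observed dI signs, and test the binding-splicing overlap."""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location("paths", Path(__file__).parent / "00_paths.py")
paths = importlib.util.module_from_spec(spec)
spec.loader.exec_module(paths)

import numpy as np
import pandas as pd

from clipmap.integration import evaluate_concordance, overlap_enrichment, predict_for_events
from clipmap.io_formats import RunConfig, read_fasta, read_gtf, read_tsv_report, write_tsv_report
from clipmap.pipeline import permuted_concordance

load_jps = importlib.util.spec_from_file_location(
    "diff04", Path(__file__).parent / "04_differential_binding.py"
)
diff04 = importlib.util.module_from_spec(load_jps)
load_jps.loader.exec_module(diff04)

from clipmap.differential import site_differential_test


def main() -> None:
    cfg = RunConfig(seed=paths.SEED)
    genome = read_fasta(paths.SCRATCH / "genome.fa")
    genes = read_gtf(
        paths.SCRATCH / "genes.gtf",
        chrom_lengths={c: genome.length(c) for c in genome.seqs},
    )
    sites = site_differential_test(diff04.load_joint_peaks(), cfg)
    events = read_tsv_report(paths.RESULTS / "splicing_events.tsv").merge(
        read_tsv_report(paths.RESULTS / "truth_events.tsv")[
            ["event_id", "exon_start", "exon_end"]
        ],
        on="event_id",
    )

    predictions = predict_for_events(sites, events, genes, cfg)
    table = pd.DataFrame(
        [
            {"event_id": p.event_id, "jp_id": p.jp_id, "gene_id": p.gene_id,
             "offset": p.offset, "predicted": p.predicted, "site_fdr": p.site_fdr}
            for p in predictions
        ]
    )
    obs = events.set_index("event_id")
    if not table.empty:
        table["observed_dI"] = obs.loc[table["event_id"], "dI"].to_numpy()
        table["observed_fdr"] = obs.loc[table["event_id"], "fdr"].to_numpy()
    write_tsv_report(table, paths.RESULTS / "rna_map_predictions.tsv")

    n_pred, n_conc, frac = evaluate_concordance(predictions, events, cfg)
    perm = [
        permuted_concordance(predictions, events, cfg, seed=paths.SEED * 100 + j)
        for j in range(10)
    ]
    perm_frac = sum(c for _, c, _ in perm) / max(sum(n for n, _, _ in perm), 1)
    print(f"{len(predictions)} hotspot predictions; {n_conc}/{n_pred} concordant "
          f"({100 * frac:.0f}%) among significant events; permuted pairing: "
          f"{100 * perm_frac:.0f}%")

    # overlap of binding-target events with differentially spliced events
    expressed = events[events["expressed"]]
    universe = set(expressed["event_id"])
    spliced = set(expressed.loc[expressed["significant"], "event_id"])
    targets = {p.event_id for p in predictions} & universe
    if targets:
        overlap, expected, p = overlap_enrichment(targets, spliced, universe)
        print(f"binding-target events vs spliced: {overlap}/{len(targets)} overlap "
              f"(expected {expected:.1f}), hypergeometric p = {p:.3g}")

    summary = pd.DataFrame([
        {"n_predicted": n_pred, "n_concordant": n_conc,
         "concordance": frac, "permuted_concordance": perm_frac}
    ])
    write_tsv_report(summary, paths.RESULTS / "concordance_summary.tsv")


if __name__ == "__main__":
    main()
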