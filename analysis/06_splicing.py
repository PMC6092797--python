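#!/usr/bin/env python
"""Junction-based differential splicing: cassette-exon psi/dI with Fisher
tests and BH over expressed events, and alternative last exon usage."""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location("paths", Path(__file__).parent / "00_paths.py")
paths = importlib.util.module_from_spec(spec)
spec.loader.exec_module(paths)

import pandas as pd

from clipmap.io_formats import RunConfig, write_tsv_report
from clipmap.splicing import multiple_testing_and_filters, quantify_events


def main() -> None:
    cfg = RunConfig(seed=paths.SEED)
    counts = pd.read_csv(paths.SCRATCH / "junction_counts.tsv", sep="\t")
    events = multiple_testing_and_filters(quantify_events(counts, cfg), cfg)
    write_tsv_report(events, paths.RESULTS / "splicing_events.tsv")

    for kind, sub in events.groupby("kind"):
        expressed = sub[sub["expressed"]]
        sig = expressed[expressed["significant"]]
        line = (f"{kind}: {len(sub)} events, {len(expressed)} expressed, "
                f"{len(sig)} significant (FDR <= {cfg.splicing_fdr}")
        if kind == "ALE":
            line += f", |dI| >= {cfg.ale_dI}"
        print(line + ", replicate-consistent)")
        if len(sig):
            top = sig.loc[sig["fdr"].idxmin()]
            print(f"  strongest: {top['event_id']} dI = {top['dI']:+.2f}, "
                  f"FDR = {top['fdr']:.2g}")


if __name__ == "__main__":
    main()
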