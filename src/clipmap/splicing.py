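"""Junction-count differential splicing: cassette exons and alternative last exons.

Cassette exons are quantified from the two inclusion junctions (upstream
exon -> cassette, cassette -> downstream exon) and the skip junction.
Per condition the pooled inclusion count is the average of the two
inclusion junctions, I = (sum I1 + sum I2) / 2, and psi = I / (I + E).
dI = psi_MN - psi_WSC. Significance is a Fisher exact test on the pooled
[[I_MN, E_MN], [I_WSC, E_WSC]] counts (inclusion averages rounded
half-even to integers), BH-corrected within event kind over expressed
events only. Alternative last exons (ALEs) are quantified analogously from
the junction reads entering each of the two last exons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import RunConfig
from .statcore import bh_fdr, fisher_exact_two_sided

COUNT_COLUMNS = ["event_id", "gene_id", "kind", "condition", "replicate", "inc1", "inc2", "skip"]


def _condition_counts(df: pd.DataFrame, kind: str):
    """Pooled (inclusion, exclusion) and per-replicate psi for one condition."""
    if kind == "cassette":
        inc = (df["inc1"].sum() + df["inc2"].sum()) / 2.0
        exc = float(df["skip"].sum())
        rep_psi = []
        for rec in df.itertuples(index=False):
            i = (rec.inc1 + rec.inc2) / 2.0
            tot = i + rec.skip
            rep_psi.append(i / tot if tot > 0 else np.nan)
    elif kind == "ALE":
        inc = float(df["inc1"].sum())
        exc = float(df["skip"].sum())
        rep_psi = []
        for rec in df.itertuples(index=False):
            tot = rec.inc1 + rec.skip
            rep_psi.append(rec.inc1 / tot if tot > 0 else np.nan)
    else:
        raise ValueError(f"unknown event kind {kind!r}")
    return inc, exc, rep_psi


def _quantify_one(event_df: pd.DataFrame, cfg: RunConfig) -> dict:
    event_id = event_df["event_id"].iloc[0]
    gene_id = event_df["gene_id"].iloc[0]
    kind = event_df["kind"].iloc[0]
    out = {"event_id": event_id, "gene_id": gene_id, "kind": kind}
    per_cond = {}
    for cond in ("MN", "WSC"):
        sub = event_df[event_df["condition"] == cond]
        inc, exc, rep_psi = _condition_counts(sub, kind)
        per_cond[cond] = (inc, exc, rep_psi)
        cov = inc + exc
        out[f"coverage_{cond.lower()}"] = cov
        out[f"psi_{cond.lower()}"] = inc / cov if cov > 0 else np.nan
    expressed = all(
        per_cond[c][0] + per_cond[c][1] > cfg.expressed_junction_min for c in ("MN", "WSC")
    )
    out["expressed"] = expressed
    i_mn, e_mn, psi_mn_reps = per_cond["MN"]
    i_wsc, e_wsc, psi_wsc_reps = per_cond["WSC"]
    if out["coverage_mn"] > 0 and out["coverage_wsc"] > 0:
        dI = out["psi_mn"] - out["psi_wsc"]
        table = [
            [round(i_mn), round(e_mn)],
            [round(i_wsc), round(e_wsc)],
        ]
        p = fisher_exact_two_sided(table)
        pairs = [
            (pm, pw)
            for pm in psi_mn_reps
            for pw in psi_wsc_reps
            if not (np.isnan(pm) or np.isnan(pw))
        ]
        if dI == 0 or not pairs:
            bc = False
        else:
            bc = all(np.sign(pm - pw) == np.sign(dI) for pm, pw in pairs)
        out.update(dI=dI, p_value=p, bc_consistent=bc)
    else:
        out.update(dI=np.nan, p_value=np.nan, bc_consistent=False, expressed=False)
    return out


def quantify_events(counts: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Quantify every event in a junction-count table (one row per
    event x condition x replicate, columns ``COUNT_COLUMNS``)."""
    missing = set(COUNT_COLUMNS) - set(counts.columns)
    if missing:
        raise ValueError(f"junction count table missing columns {sorted(missing)}")
    if (counts[["inc1", "inc2", "skip"]] < 0).any().any():
        raise ValueError("negative junction counts")
    rows = [
        _quantify_one(sub, cfg) for _, sub in counts.groupby("event_id", sort=True)
    ]
    return pd.DataFrame(rows)


def quantify_cassette(event_counts: pd.DataFrame, cfg: RunConfig) -> dict:
    """Quantify a single cassette-exon event (convenience wrapper)."""
    if set(event_counts["kind"]) != {"cassette"}:
        raise ValueError("expected cassette counts")
    return _quantify_one(event_counts, cfg)


def quantify_ale(event_counts: pd.DataFrame, cfg: RunConfig) -> dict:
    """Quantify a single ALE event; inc1/skip are the reads entering
    the first/second last exon."""
    if set(event_counts["kind"]) != {"ALE"}:
        raise ValueError("expected ALE counts")
    return _quantify_one(event_counts, cfg)


def multiple_testing_and_filters(events: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """BH within event kind over expressed events; call significance.

    Cassette: FDR <= splicing_fdr and replicate-consistent dI sign.
    ALE: additionally |dI| >= ale_dI. Unexpressed events keep fdr = NA and
    are never significant.
    """
    out = events.copy()
    out["fdr"] = np.nan
    out["significant"] = False
    for kind, sub in out.groupby("kind"):
        idx = sub.index[sub["expressed"] & sub["p_value"].notna()]
        if len(idx) == 0:
            continue
        out.loc[idx, "fdr"] = bh_fdr(out.loc[idx, "p_value"])
    sig = (out["fdr"] <= cfg.splicing_fdr) & out["bc_consistent"] & out["expressed"]
    is_ale = out["kind"] == "ALE"
    sig &= ~is_ale | (out["dI"].abs() >= cfg.ale_dI)
    out["significant"] = sig.fillna(False)
    return out
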