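"""Couple differential binding to splicing: the position-dependent RNA map,
overlap and gene-set enrichment, and category concordance.

The RNA map encodes the empirical rule that binding within ~400 nt upstream
of an alternative exon predicts splicing repression while binding within
~400 nt downstream predicts activation. For a binding site over-represented
in MN, an upstream site therefore predicts lower inclusion in MN (dI < 0)
and a downstream site higher (dI > 0); under-represented sites flip the
sign. Exonic sites inside the regulated exon follow the repression arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import RunConfig
from .models import GeneModel
from .statcore import bh_fdr, chi_squared_gof, hypergeom_upper_tail


@dataclass
class RnaMapPrediction:
    event_id: str
    jp_id: str
    gene_id: str
    offset: int
    predicted: str  # "dI>0" | "dI<0" | "none"
    site_fdr: float


def signed_offset(site_center: int, exon: tuple[int, int], strand: str) -> int:
    """Strand-aware offset of a position from the nearest exon boundary.

    Negative = upstream of the exon (3' splice-site side in transcript
    orientation), positive = downstream, 0 = within the exon.
    """
    start, end = exon
    if start <= site_center < end:
        return 0
    if strand == "+":
        return site_center - start if site_center < start else site_center - (end - 1)
    return (end - 1) - site_center if site_center >= end else start - site_center


def predict_direction(site, exon: tuple[int, int], gene: GeneModel, cfg: RunConfig,
                      event_id: str = "") -> RnaMapPrediction:
    """RNA-map direction prediction for one differential site and one exon."""
    jp = site.jp
    if jp.gene_id != gene.gene_id:
        raise ValueError(f"site {jp.jp_id} and exon belong to different genes")
    offset = signed_offset(jp.center, exon, gene.strand)
    predicted = "none"
    if site.call in ("over", "under") and abs(offset) <= cfg.hotspot_nt:
        up = offset < 0 or offset == 0  # exonic sites follow the repression arm
        if site.call == "over":
            predicted = "dI<0" if up else "dI>0"
        else:
            predicted = "dI>0" if up else "dI<0"
    return RnaMapPrediction(
        event_id=event_id,
        jp_id=jp.jp_id,
        gene_id=gene.gene_id,
        offset=offset,
        predicted=predicted,
        site_fdr=float(site.fdr),
    )


def predict_for_events(sites, events: pd.DataFrame, genes, cfg: RunConfig) -> list[RnaMapPrediction]:
    """One prediction per event: every called site within the event exon's
    hotspot competes; the smallest-FDR site wins, ties with conflicting
    directions yield no prediction.

    ``events`` needs columns event_id, gene_id, exon_start, exon_end.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    by_gene: dict[str, list] = {}
    for s in sites:
        if s.call in ("over", "under"):
            by_gene.setdefault(s.jp.gene_id, []).append(s)
    predictions = []
    for rec in events.itertuples(index=False):
        gene = gene_by_id.get(rec.gene_id)
        if gene is None:
            continue
        exon = (int(rec.exon_start), int(rec.exon_end))
        candidates = []
        for s in by_gene.get(rec.gene_id, []):
            pred = predict_direction(s, exon, gene, cfg, event_id=rec.event_id)
            if pred.predicted != "none":
                candidates.append(pred)
        if not candidates:
            continue
        best_fdr = min(c.site_fdr for c in candidates)
        best = [c for c in candidates if c.site_fdr == best_fdr]
        directions = {c.predicted for c in best}
        if len(directions) > 1:
            continue
        predictions.append(best[0])
    return predictions


def evaluate_concordance(predictions, events: pd.DataFrame, cfg: RunConfig):
    """Fraction of predictions whose direction matches the observed dI sign,
    over events significant at the splicing FDR threshold.

    Returns (n_predicted, n_concordant, fraction); fraction is NaN when no
    prediction joins a significant event.
    """
    ev = events.set_index("event_id")
    n_pred = n_conc = 0
    for pred in predictions:
        if pred.predicted == "none" or pred.event_id not in ev.index:
            continue
        row = ev.loc[pred.event_id]
        if not (row["fdr"] <= cfg.splicing_fdr):
            continue
        n_pred += 1
        observed = np.sign(row["dI"])
        wanted = 1.0 if pred.predicted == "dI>0" else -1.0
        if observed == wanted:
            n_conc += 1
    fraction = n_conc / n_pred if n_pred else float("nan")
    return n_pred, n_conc, fraction


def overlap_enrichment(set_a, set_b, universe):
    """Hypergeometric upper-tail enrichment of the overlap of two gene sets."""
    a, b, u = set(set_a), set(set_b), set(universe)
    if not (a <= u and b <= u):
        raise ValueError("sets must be subsets of the universe")
    overlap = len(a & b)
    expected = len(a) * len(b) / len(u) if u else float("nan")
    p = hypergeom_upper_tail(len(u), len(b), len(a), overlap)
    return overlap, expected, p


def gene_set_enrichment(targets, background, sets: dict[str, set], fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Per-set hypergeometric enrichment of targets within a background, BH
    across sets. Sets disjoint from the background are skipped."""
    t, bg = set(targets), set(background)
    if not bg:
        raise ValueError("empty background")
    if not t <= bg:
        raise ValueError("targets must be a subset of the background")
    rows = []
    for name, members in sorted(sets.items()):
        K = len(members & bg)
        if K == 0:
            continue
        k = len(members & t)
        p = hypergeom_upper_tail(len(bg), K, len(t), k)
        rows.append({"set": name, "k": k, "K": K, "n_targets": len(t), "p_value": p})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr"] = bh_fdr(out["p_value"])
    out["significant"] = out["fdr"] < fdr_threshold
    return out.sort_values(["fdr", "p_value", "set"], kind="mergesort").reset_index(drop=True)


def category_concordance(categories: pd.DataFrame, enrichment: pd.DataFrame) -> pd.DataFrame:
    """Direction counts per gene category versus the global direction split.

    ``categories`` maps gene_id -> category (two columns); only genes with a
    significant direction (enriched/depleted) count. Each category row holds
    its enriched/depleted counts, enriched fraction, and a 1-df chi-squared
    goodness-of-fit p against the global enriched proportion.
    """
    directional = enrichment[enrichment["direction"].isin(["enriched", "depleted"])]
    merged = categories.merge(directional[["gene_id", "direction"]], on="gene_id", how="left")
    n_enr_global = (directional["direction"] == "enriched").sum()
    n_dir_global = len(directional)
    p0 = n_enr_global / n_dir_global if n_dir_global else np.nan
    rows = []
    for category, sub in merged.groupby("category", sort=True):
        n_e = int((sub["direction"] == "enriched").sum())
        n_d = int((sub["direction"] == "depleted").sum())
        n = n_e + n_d
        if n > 0 and 0.0 < p0 < 1.0:
            p = chi_squared_gof((n_e, n_d), p0)
            frac = n_e / n
        else:
            p, frac = np.nan, np.nan
        rows.append(
            {
                "category": category,
                "n_enriched": n_e,
                "n_depleted": n_d,
                "fraction_enriched": frac,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
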