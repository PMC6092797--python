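"""Site-wise and gene-wise differential CLIP binding between conditions.

The site test is a Fisher exact test on the 2x2 matrix

    m    M - m
    n    N - n

where m / n are MN / WSC reads in one joint peak and M / N the totals over
all same-class (intronic or exonic) joint peaks of the gene. Normalising
within the gene cancels both library depth and transcript abundance, so the
test isolates redistribution of binding along the gene. Coverage is the
smallest cell; sites under the coverage floor are untested. BH correction
runs separately within the intronic and exonic families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .io_formats import RunConfig
from .models import JointPeakCounts
from .statcore import bh_fdr, fisher_exact_two_sided

CALLS = ("over", "under", "unchanged", "untested")


@dataclass
class DifferentialSite:
    jp: JointPeakCounts
    rph_mn: float
    rph_wsc: float
    fold_change: float
    coverage: int
    p_value: float
    fdr: float
    call: str


def relative_peak_height(jp: JointPeakCounts, condition: str) -> float:
    """100 x (reads in the JP) / (reads in all same-class JPs of the gene)."""
    if condition == "MN":
        if jp.M <= 0:
            raise ValueError("relative peak height undefined for zero MN total")
        return 100.0 * jp.m / jp.M
    if condition == "WSC":
        if jp.N <= 0:
            raise ValueError("relative peak height undefined for zero WSC total")
        return 100.0 * jp.n / jp.N
    raise ValueError(f"unknown condition {condition!r}")


def site_differential_test(jps, cfg: RunConfig) -> list[DifferentialSite]:
    """Fisher 2x2 per joint peak, BH within each coverage-passing family.

    Fold change is the ratio of relative peak heights, oriented MN over WSC.
    Calls: ``over`` (fdr <= site_fdr and fold >= site_fold), ``under``
    (fdr <= site_fdr and fold <= 1/site_fold), ``unchanged`` otherwise;
    JPs with coverage < coverage_min or a zero gene total are ``untested``.
    """
    jps = list(jps)
    sites: list[DifferentialSite] = []
    for jp in jps:
        coverage = min(jp.m, jp.M - jp.m, jp.n, jp.N - jp.n)
        tested = jp.M > 0 and jp.N > 0 and coverage >= cfg.coverage_min
        if tested:
            rph_mn = relative_peak_height(jp, "MN")
            rph_wsc = relative_peak_height(jp, "WSC")
            fold = (jp.m / jp.M) / (jp.n / jp.N)
            p = fisher_exact_two_sided([[jp.m, jp.M - jp.m], [jp.n, jp.N - jp.n]])
            sites.append(
                DifferentialSite(jp, rph_mn, rph_wsc, fold, coverage, p, np.nan, "")
            )
        else:
            rph_mn = relative_peak_height(jp, "MN") if jp.M > 0 else np.nan
            rph_wsc = relative_peak_height(jp, "WSC") if jp.N > 0 else np.nan
            sites.append(
                DifferentialSite(
                    jp, rph_mn, rph_wsc, np.nan, coverage, np.nan, np.nan, "untested"
                )
            )
    for region_class in ("intron", "exon"):
        family = [
            s for s in sites
            if s.jp.region_class == region_class and s.call != "untested"
        ]
        if not family:
            continue
        fdrs = bh_fdr([s.p_value for s in family])
        for s, fdr in zip(family, fdrs):
            s.fdr = float(fdr)
            if fdr <= cfg.site_fdr and s.fold_change >= cfg.site_fold:
                s.call = "over"
            elif fdr <= cfg.site_fdr and s.fold_change <= 1.0 / cfg.site_fold:
                s.call = "under"
            else:
                s.call = "unchanged"
    return sites


def sites_to_frame(sites) -> pd.DataFrame:
    rows = []
    for s in sites:
        jp = s.jp
        rows.append(
            {
                "jp_id": jp.jp_id,
                "gene_id": jp.gene_id,
                "chrom": jp.chrom,
                "start": jp.start,
                "end": jp.end,
                "strand": jp.strand,
                "region_class": jp.region_class,
                "m": jp.m,
                "n": jp.n,
                "M": jp.M,
                "N": jp.N,
                "rph_mn": s.rph_mn,
                "rph_wsc": s.rph_wsc,
                "fold_change": s.fold_change,
                "coverage": s.coverage,
                "p_value": s.p_value,
                "fdr": s.fdr,
                "call": s.call,
            }
        )
    return pd.DataFrame(rows)


def genewise_enrichment(
    gene_counts: pd.DataFrame, lib_mn: int, lib_wsc: int, cfg: RunConfig
) -> pd.DataFrame:
    """Gene-level MN vs WSC CLIP-read enrichment by conditional exact binomial.

    Under the null, the MN count among a gene's T = mn + wsc in-peak reads is
    Binomial(T, lib_mn / (lib_mn + lib_wsc)); the two-sided exact binomial p
    is BH-corrected across genes. log_fold is the depth-normalised log2
    ratio with a 0.5 pseudo-count. Direction is called at fdr <= gene_fdr.
    """
    if lib_mn <= 0 or lib_wsc <= 0:
        raise ValueError("library sizes must be positive")
    p0 = lib_mn / (lib_mn + lib_wsc)
    rows = []
    for rec in gene_counts.itertuples(index=False):
        mn, wsc = int(rec.mn_count), int(rec.wsc_count)
        total = mn + wsc
        p = 1.0 if total == 0 else binomtest(mn, total, p0, alternative="two-sided").pvalue
        log_fold = float(
            np.log2(((mn + 0.5) / lib_mn) / ((wsc + 0.5) / lib_wsc))
        )
        rows.append(
            {
                "gene_id": rec.gene_id,
                "mn_count": mn,
                "wsc_count": wsc,
                "log_fold": log_fold,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["fdr"] = []
        out["direction"] = []
        return out
    out["fdr"] = bh_fdr(out["p_value"])
    out["direction"] = "ns"
    sig = out["fdr"] <= cfg.gene_fdr
    out.loc[sig & (out["log_fold"] > 0), "direction"] = "enriched"
    out.loc[sig & (out["log_fold"] < 0), "direction"] = "depleted"
    return out
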