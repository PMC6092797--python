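"""Peak calling against a per-gene uniform-background null, and joint peaks.

The null model: a gene's reads fall uniformly over its transcription unit,
so coverage at a position is approximately Poisson with rate
``lambda_g = R_g * Lbar / G_g`` (R_g reads, Lbar mean read length, G_g unit
length). The significance height ``k*`` is the smallest coverage whose
Poisson upper tail, Bonferroni-adjusted over the G_g positions of the unit,
drops to the requested alpha. Peaks are maximal runs of coverage >= k*.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from collections import defaultdict

import numpy as np

from .io_formats import RunConfig
from .models import AlignedRead, GeneModel, JointPeakCounts, Peak
from .statcore import poisson_upper_tail


def assign_reads_to_genes(reads, genes) -> dict[str, list[AlignedRead]]:
    """Map each read to the first gene whose transcription unit contains its
    midpoint on the matching strand. Reads matching no gene are dropped."""
    by_chrom_strand: dict[tuple[str, str], list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_chrom_strand[(g.chrom, g.strand)].append(g)
    index = {}
    for key, gs in by_chrom_strand.items():
        gs.sort(key=lambda g: g.tu_start)
        index[key] = ([g.tu_start for g in gs], gs)
    assigned: dict[str, list[AlignedRead]] = defaultdict(list)
    for r in reads:
        key = (r.chrom, r.strand)
        if key not in index:
            continue
        starts, gs = index[key]
        i = bisect_right(starts, r.midpoint) - 1
        # walk left across potentially overlapping units
        while i >= 0:
            g = gs[i]
            if g.tu_start <= r.midpoint < g.tu_end:
                assigned[g.gene_id].append(r)
                break
            if g.tu_end <= r.midpoint and i + 1 < len(gs) and gs[i + 1].tu_start > r.midpoint:
                break
            i -= 1
    return dict(assigned)


def coverage_profile(reads, gene: GeneModel) -> np.ndarray:
    """Per-base read coverage over the transcription unit (clipped to it)."""
    cov = np.zeros(gene.tu_length + 1)
    for r in reads:
        s = max(r.start, gene.tu_start) - gene.tu_start
        e = min(r.end, gene.tu_end) - gene.tu_start
        if e > s:
            cov[s] += 1
            cov[e] -= 1
    return np.cumsum(cov[:-1])


def significance_height(rate: float, n_tests: int, alpha: float) -> int:
    """Smallest k with Bonferroni-adjusted Poisson upper tail <= alpha."""
    k = 1
    while n_tests * poisson_upper_tail(rate, k) > alpha:
        k += 1
        if k > 100_000:  # pragma: no cover - guards pathological rates
            raise RuntimeError("significance height did not converge")
    return k


def call_peaks(
    reads, gene: GeneModel, alpha: float = 0.01, mean_read_length: float | None = None
) -> list[Peak]:
    """Peaks = maximal runs of coverage >= k* within the transcription unit.

    Per-peak p is the Bonferroni-adjusted Poisson tail at the run's maximum
    coverage; only peaks with p <= alpha are returned.
    """
    reads = list(reads)
    if gene.tu_length <= 0:
        raise ValueError(f"empty transcription unit for {gene.gene_id}")
    if not reads:
        return []
    lbar = mean_read_length or float(np.mean([r.length for r in reads]))
    rate = len(reads) * lbar / gene.tu_length
    # per-position Bonferroni over the whole unit: coverage exceedances are
    # narrow spikes pinned to read boundaries, so window-count corrections
    # (G/Lbar) undercount them badly; the full union bound calibrates
    # robustly and costs nothing against site stacks far above k*
    n_tests = gene.tu_length
    k_star = significance_height(rate, n_tests, alpha)
    cov = coverage_profile(reads, gene)
    above = cov >= k_star
    if not above.any():
        return []
    # maximal runs of True
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))))
    starts, ends = edges[0::2], edges[1::2]
    peaks = []
    for i, (s, e) in enumerate(zip(starts, ends)):
        summit = int(cov[s:e].max())
        p = min(1.0, n_tests * poisson_upper_tail(rate, summit))
        if p > alpha:
            continue
        abs_s, abs_e = gene.tu_start + int(s), gene.tu_start + int(e)
        read_count = sum(1 for r in reads if r.start < abs_e and r.end > abs_s)
        peaks.append(
            Peak(
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                start=abs_s,
                end=abs_e,
                summit_height=summit,
                read_count=read_count,
                p_value=p,
            )
        )
    return peaks


def biological_complexity(peak, reads) -> int:
    """Number of distinct replicates with >=1 read overlapping the peak."""
    reps = {
        r.replicate
        for r in reads
        if r.chrom == peak.chrom and r.start < peak.end and r.end > peak.start
    }
    return len(reps)


def normalize_heights(peaks, library_size: int) -> None:
    """Fill normalized peak height = reads-per-million of the library."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    for p in peaks:
        p.normalized_height = p.read_count / library_size * 1e6


def define_joint_peaks(mn_reads, wsc_reads, genes, cfg: RunConfig) -> list[JointPeakCounts]:
    """Joint peaks: peak calling on pooled MN+WSC reads, kept when either
    condition contributes reads from at least half of its replicates
    (MN BC >= bc_mn out of n_reps_mn, or WSC BC >= bc_wsc out of n_reps_wsc).

    Region class is assigned by JP midpoint; the downstream-10kb extension
    folds into the non-exonic ("intron") family, since only intronic and
    exonic JPs are tested. M / N are filled per gene x region class over the
    retained JPs.
    """
    if cfg.bc_mn > cfg.n_reps_mn or cfg.bc_wsc > cfg.n_reps_wsc:
        raise ValueError("BC thresholds exceed the configured replicate counts")
    for r in mn_reads:
        if r.condition != "MN":
            raise ValueError("mn_reads must all carry condition MN")
    for r in wsc_reads:
        if r.condition != "WSC":
            raise ValueError("wsc_reads must all carry condition WSC")
    pooled = list(mn_reads) + list(wsc_reads)
    assigned = assign_reads_to_genes(pooled, genes)
    jps: list[JointPeakCounts] = []
    for gene in genes:
        gene_reads = assigned.get(gene.gene_id, [])
        if not gene_reads:
            continue
        peaks = call_peaks(gene_reads, gene, alpha=cfg.peak_alpha)
        gene_jps = []
        for i, p in enumerate(peaks):
            mn_over = [
                r for r in gene_reads
                if r.condition == "MN" and r.start < p.end and r.end > p.start
            ]
            wsc_over = [
                r for r in gene_reads
                if r.condition == "WSC" and r.start < p.end and r.end > p.start
            ]
            bc_mn = len({r.replicate for r in mn_over})
            bc_wsc = len({r.replicate for r in wsc_over})
            if not (bc_mn >= cfg.bc_mn or bc_wsc >= cfg.bc_wsc):
                continue
            region = gene.classify(p.center)
            region_class = "exon" if region == "exon" else "intron"
            gene_jps.append(
                JointPeakCounts(
                    jp_id=f"{gene.gene_id}_jp{i}",
                    gene_id=gene.gene_id,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    start=p.start,
                    end=p.end,
                    region_class=region_class,
                    m=len(mn_over),
                    n=len(wsc_over),
                    bc_mn=bc_mn,
                    bc_wsc=bc_wsc,
                )
            )
        for region_class in ("intron", "exon"):
            fam = [jp for jp in gene_jps if jp.region_class == region_class]
            M = sum(jp.m for jp in fam)
            N = sum(jp.n for jp in fam)
            for jp in fam:
                jp.M, jp.N = M, N
                jp.validate_totals()
        jps.extend(gene_jps)
    return jps


def downsample_reads(reads, target_count: int, seed: int) -> list[AlignedRead]:
    """Uniform sample without replacement; seeded; input order preserved."""
    reads = list(reads)
    if target_count > len(reads):
        raise ValueError("target_count exceeds number of reads")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=target_count, replace=False)
    return [reads[i] for i in sorted(idx)]


def replicate_group_correlation(peaks_a, peaks_b) -> float:
    """R^2 of log10(normalized height + 0.5) over interval-matched peaks."""
    by_iv = {(p.chrom, p.start, p.end): p for p in peaks_b}
    pairs = [
        (a.normalized_height, by_iv[(a.chrom, a.start, a.end)].normalized_height)
        for a in peaks_a
        if (a.chrom, a.start, a.end) in by_iv
    ]
    if len(pairs) < 3:
        raise ValueError("need at least 3 matched peaks")
    x = np.log10(np.array([p[0] for p in pairs]) + 0.5)
    y = np.log10(np.array([p[1] for p in pairs]) + 0.5)
    if np.std(x) == 0 or np.std(y) == 0:
        return 1.0 if np.allclose(x - x.mean(), y - y.mean()) else 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r
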