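"""Synthetic genomes, gene models, CLIP reads and junction counts with truth.

The generator emulates the study design the pipeline is built for:

- two CLIP conditions with unequal replicate counts (8 MN vs 4 WSC) and an
  ~8x depth asymmetry (the MN library is about one eighth of WSC);
- read lengths uniform on 30-80 nt;
- YCAY-dense binding-site clusters written into the sequence, a fraction of
  which carry condition-specific intensity multipliers (default 4x up or
  down in MN);
- RT-artifact reads whose strand-aware downstream pentamer is exactly
  GTGTC, placed so their 3' end abuts a planted pentamer;
- cassette-exon and alternative-last-exon events whose inclusion shifts are
  coupled to planted binding changes following the position rule: an
  upstream site stronger in MN lowers inclusion in MN, a downstream one
  raises it.

Every planted feature is recorded in a :class:`SyntheticTruth` so recovery
and calibration tests can score the pipeline against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import AlignedRead, GeneModel, Genome

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationParams:
    n_genes: int = 200
    gene_length: tuple[int, int] = (5000, 10_000)
    n_reps_mn: int = 8
    n_reps_wsc: int = 4
    depth_mn: float = 150.0  # mean MN reads per gene, all replicates pooled
    wsc_depth_scale: float = 8.0
    read_length: tuple[int, int] = (30, 80)
    background_fraction: float = 0.30
    artifact_fraction: float = 0.05
    sites_per_gene: int = 5
    differential_fraction: float = 0.10
    coupled_fraction: float = 0.8
    fold_levels: tuple[float, ...] = (4.0, 0.25)
    cassette_fraction: float = 0.35
    ale_fraction: float = 0.15
    coupled_ddi: tuple[float, float] = (0.2, 0.5)
    splicing_depth: float = 50.0  # junction coverage per replicate per event
    n_rnaseq_reps: int = 2
    site_jitter: int = 10
    intergenic_gap: int = 12_000
    hotspot_nt: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background_fraction", "artifact_fraction", "differential_fraction",
                     "cassette_fraction", "ale_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.background_fraction + self.artifact_fraction > 1.0:
            raise ValueError("background + artifact fractions exceed 1")
        if any(f <= 0 for f in self.fold_levels):
            raise ValueError("fold levels must be positive")


@dataclass
class PlantedSite:
    site_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    base_intensity: float
    mn_multiplier: float
    coupled_event_id: str = ""
    side: str = ""  # "up" | "down" for coupled sites

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def is_differential(self) -> bool:
        return self.mn_multiplier != 1.0


@dataclass
class SyntheticTruth:
    planted_sites: list[PlantedSite]
    events: pd.DataFrame  # event_id, gene_id, kind, exon_start, exon_end, psi_wsc, psi_mn, coupled_site_id
    artifact_anchors: dict[str, int]  # gene_id -> genomic start of read 3' flank
    gene_weights: dict[str, float]
    artifact_read_ids: set[str] = field(default_factory=set)
    library_sizes: dict[tuple[str, int], int] = field(default_factory=dict)

    def sites_of(self, gene_id: str) -> list[PlantedSite]:
        return [s for s in self.planted_sites if s.gene_id == gene_id]


def _check_coupling(truth: SyntheticTruth) -> None:
    """Assert the regulation-direction rule holds for every coupled event."""
    sites = {s.site_id: s for s in truth.planted_sites}
    for rec in truth.events.itertuples(index=False):
        if not rec.coupled_site_id:
            continue
        site = sites[rec.coupled_site_id]
        ddi = rec.psi_mn - rec.psi_wsc
        up = site.side == "up"
        stronger = site.mn_multiplier > 1.0
        want_negative = up == stronger  # upstream & stronger, or downstream & weaker
        if want_negative and not ddi < 0:
            raise AssertionError(f"coupling violated for {rec.event_id}")
        if not want_negative and not ddi > 0:
            raise AssertionError(f"coupling violated for {rec.event_id}")


def _ycay_cluster(rng: np.random.Generator, n_motifs: int = 4) -> str:
    """A 20-40 nt pyrimidine cluster containing >= n_motifs YCAY elements."""
    parts = []
    for i in range(n_motifs):
        y1, y2 = rng.choice(["C", "T"], size=2)
        parts.append(f"{y1}CA{y2}")
        if i < n_motifs - 1:
            parts.append("".join(rng.choice(["G", "A"], size=2)))
    return "".join(parts)


def _transcript_to_genomic(iv: tuple[int, int], gene_start: int, L: int, strand: str):
    a, b = iv
    if strand == "+":
        return gene_start + a, gene_start + b
    return gene_start + (L - b), gene_start + (L - a)


class _GenePlan:
    """Scratch layout of one gene in transcript coordinates."""

    def __init__(self, gene_id, strand, exons_t, introns_t, length, kind, cassette_idx):
        self.gene_id = gene_id
        self.strand = strand
        self.exons_t = exons_t          # list of (start, end) in transcript coords
        self.introns_t = introns_t
        self.length = length
        self.kind = kind                # "plain" | "cassette" | "ALE"
        self.cassette_idx = cassette_idx
        self.occupied = list(exons_t)   # intervals no site may touch
        self.writes: list[tuple[int, str]] = []   # (transcript pos, motif text)
        self.site_pos: list[tuple[int, int]] = []  # transcript intervals of sites
        self.anchor_t: int | None = None

    def reserve(self, start, end) -> None:
        self.occupied.append((start, end))

    def free_at(self, start, end) -> bool:
        return all(e0 <= start or s0 >= end for s0, e0 in self.occupied)


def _plan_gene(rng: np.random.Generator, gene_id: str, params: SimulationParams,
               kind: str) -> _GenePlan:
    strand = rng.choice(["+", "-"])
    n_exons = int(rng.integers(4, 8))
    if kind == "ALE":
        n_exons += 1  # the extra terminal exon is the second ALE
    exon_lens = rng.integers(120, 301, size=n_exons)
    n_introns = n_exons - 1
    need = int(exon_lens.sum()) + 700 * n_introns + 400
    lo, hi = params.gene_length
    if hi < need:
        raise ValueError(
            f"gene length limit {hi} too small to host {n_exons} exons"
        )
    target_len = int(rng.integers(max(lo, need), hi + 1))
    remaining = target_len - int(exon_lens.sum())
    cuts = np.sort(rng.random(n_introns - 1)) if n_introns > 1 else np.array([])
    shares = np.diff(np.concatenate(([0.0], cuts, [1.0])))
    intron_lens = 700 + np.floor(shares * (remaining - 700 * n_introns)).astype(int)
    exons_t, introns_t = [], []
    pos = 0
    for i in range(n_exons):
        exons_t.append((pos, pos + int(exon_lens[i])))
        pos += int(exon_lens[i])
        if i < n_introns:
            introns_t.append((pos, pos + int(intron_lens[i])))
            pos += int(intron_lens[i])
    cassette_idx = None
    if kind == "cassette":
        cassette_idx = int(rng.integers(1, n_exons - 1))
    return _GenePlan(gene_id, strand, exons_t, introns_t, pos, kind, cassette_idx)


def _place_in_introns(plan: _GenePlan, rng, length: int, zones=None, margin: int = 30):
    """Sample a free transcript-coordinate slot inside an intron.

    ``zones`` optionally restricts sampling to given transcript intervals.
    Returns the start position, or None if no slot was found.
    """
    pool = zones if zones is not None else plan.introns_t
    weights = np.array([max(e - s - length - 2 * margin, 0) for s, e in pool], dtype=float)
    if weights.sum() == 0:
        return None
    for _ in range(200):
        i = rng.choice(len(pool), p=weights / weights.sum())
        s, e = pool[i]
        lo, hi = s + margin, e - margin - length
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi))
        # 100-nt guard keeps neighbouring planted features from merging
        # into a single coverage peak (reads are 30-80 nt with +-10 jitter)
        if plan.free_at(start - 100, start + length + 100):
            return start
    return None


def generate_genome_and_genes(params: SimulationParams):
    """Build (Genome, [GeneModel], SyntheticTruth) for one simulated study."""
    rng = np.random.default_rng([1, params.seed])
    chrom = "chr1"
    plans: list[_GenePlan] = []
    sites: list[PlantedSite] = []
    event_rows: list[dict] = []
    anchors: dict[str, int] = {}
    gene_weights: dict[str, float] = {}

    for gi in range(params.n_genes):
        gene_id = f"g{gi:04d}"
        u = rng.random()
        if u < params.cassette_fraction:
            kind = "cassette"
        elif u < params.cassette_fraction + params.ale_fraction:
            kind = "ALE"
        else:
            kind = "plain"
        plans.append(_plan_gene(rng, gene_id, params, kind))
        gene_weights[gene_id] = float(rng.lognormal(mean=0.0, sigma=0.4))

    # genomic layout
    offsets = {}
    cur = 1000
    for plan in plans:
        offsets[plan.gene_id] = cur
        cur += plan.length + params.intergenic_gap
    chrom_len = cur + 2000
    seq = rng.choice(_BASES, size=chrom_len)

    genes: list[GeneModel] = []
    for plan in plans:
        gene_start = offsets[plan.gene_id]
        gene_end = gene_start + plan.length
        rng_site = rng  # single stream keeps determinism simple

        # --- events ---------------------------------------------------
        coupled_site_id = ""
        event_id = ""
        if plan.kind == "cassette":
            event_id = f"{plan.gene_id}_cas"
            cas_exon_t = plan.exons_t[plan.cassette_idx]
            # the two flanking introns, trimmed to the hotspot
            up_intron = plan.introns_t[plan.cassette_idx - 1]
            dn_intron = plan.introns_t[plan.cassette_idx]
            psi_wsc = psi_mn = float(rng.uniform(0.25, 0.75))
            if params.differential_fraction > 0 and rng.random() < params.coupled_fraction:
                side = str(rng.choice(["up", "down"]))
                mult = float(rng.choice(params.fold_levels))
                cluster = _ycay_cluster(rng_site)
                zone_len = len(cluster)
                if side == "up":
                    zone = [(max(up_intron[0], cas_exon_t[0] - params.hotspot_nt + 20),
                             cas_exon_t[0] - 40)]
                else:
                    zone = [(cas_exon_t[1] + 40,
                             min(dn_intron[1], cas_exon_t[1] + params.hotspot_nt - 20))]
                start_t = _place_in_introns(plan, rng_site, zone_len, zones=zone, margin=0)
                if start_t is not None:
                    site_id = f"{plan.gene_id}_s_coupled"
                    plan.reserve(start_t, start_t + zone_len)
                    plan.writes.append((start_t, cluster))
                    plan.site_pos.append((start_t, start_t + zone_len))
                    g_s, g_e = _transcript_to_genomic(
                        (start_t, start_t + zone_len), gene_start, plan.length, plan.strand
                    )
                    ddi = float(rng.uniform(*params.coupled_ddi))
                    stronger = mult > 1.0
                    negative = (side == "up") == stronger
                    if negative:
                        psi_wsc = float(rng.uniform(ddi + 0.05, 0.93))
                        psi_mn = psi_wsc - ddi
                    else:
                        psi_wsc = float(rng.uniform(0.07, 0.93 - ddi))
                        psi_mn = psi_wsc + ddi
                    coupled_site_id = site_id
                    sites.append(
                        PlantedSite(site_id, plan.gene_id, chrom, g_s, g_e,
                                    1.0, mult, coupled_event_id=event_id, side=side)
                    )
            exon_g = _transcript_to_genomic(cas_exon_t, gene_start, plan.length, plan.strand)
            event_rows.append(
                {"event_id": event_id, "gene_id": plan.gene_id, "kind": "cassette",
                 "exon_start": exon_g[0], "exon_end": exon_g[1],
                 "psi_wsc": psi_wsc, "psi_mn": psi_mn,
                 "coupled_site_id": coupled_site_id}
            )
        elif plan.kind == "ALE":
            event_id = f"{plan.gene_id}_ale"
            usage_wsc = float(rng.uniform(0.2, 0.8))
            if params.differential_fraction > 0 and rng.random() < 0.3:
                shift = float(rng.uniform(0.25, 0.45)) * (1 if rng.random() < 0.5 else -1)
                usage_mn = float(np.clip(usage_wsc + shift, 0.05, 0.95))
            else:
                usage_mn = usage_wsc
            ale1_t = plan.exons_t[-2]
            exon_g = _transcript_to_genomic(ale1_t, gene_start, plan.length, plan.strand)
            event_rows.append(
                {"event_id": event_id, "gene_id": plan.gene_id, "kind": "ALE",
                 "exon_start": exon_g[0], "exon_end": exon_g[1],
                 "psi_wsc": usage_wsc, "psi_mn": usage_mn, "coupled_site_id": ""}
            )

        # --- uncoupled binding sites -----------------------------------
        # kept away from the cassette hotspot so only the coupled site
        # carries a map-rule prediction
        exclusion = []
        if plan.kind == "cassette":
            cas = plan.exons_t[plan.cassette_idx]
            exclusion.append((cas[0] - params.hotspot_nt - 80, cas[1] + params.hotspot_nt + 80))
        n_extra = params.sites_per_gene - sum(1 for s in plan.site_pos)
        # at most one differential site per gene: differential binding is a
        # sparse, site-specific redistribution, and the within-gene relative
        # height of one site is only interpretable against stable companions
        diff_slot = -1
        if not coupled_site_id and rng.random() < params.differential_fraction:
            diff_slot = int(rng.integers(0, n_extra)) if n_extra > 0 else -1
        for si in range(max(0, n_extra)):
            cluster = _ycay_cluster(rng_site)
            free_introns = []
            for s, e in plan.introns_t:
                blocked = any(s < ze and e > zs for zs, ze in exclusion)
                if not blocked:
                    free_introns.append((s, e))
            start_t = _place_in_introns(plan, rng_site, len(cluster),
                                        zones=free_introns or None)
            if start_t is None:
                continue
            plan.reserve(start_t, start_t + len(cluster))
            plan.writes.append((start_t, cluster))
            plan.site_pos.append((start_t, start_t + len(cluster)))
            g_s, g_e = _transcript_to_genomic(
                (start_t, start_t + len(cluster)), gene_start, plan.length, plan.strand
            )
            mult = float(rng.choice(params.fold_levels)) if si == diff_slot else 1.0
            sites.append(
                PlantedSite(f"{plan.gene_id}_s{si}", plan.gene_id, chrom,
                            g_s, g_e, 1.0, mult)
            )

        # --- artifact anchor -------------------------------------------
        anchor_t = _place_in_introns(plan, rng_site, 5)
        if anchor_t is not None:
            plan.reserve(anchor_t, anchor_t + 5)
            plan.writes.append((anchor_t, "GTGTC"))
            g_s, _ = _transcript_to_genomic(
                (anchor_t, anchor_t + 5), gene_start, plan.length, plan.strand
            )
            anchors[plan.gene_id] = g_s

        # --- write motifs into the chromosome ---------------------------
        for start_t, text in plan.writes:
            g_s, g_e = _transcript_to_genomic(
                (start_t, start_t + len(text)), gene_start, plan.length, plan.strand
            )
            oriented = text if plan.strand == "+" else _revcomp(text)
            seq[g_s:g_e] = list(oriented)

        # --- gene model --------------------------------------------------
        exons_g = sorted(
            _transcript_to_genomic(iv, gene_start, plan.length, plan.strand)
            for iv in plan.exons_t
        )
        transcripts = {}
        if plan.kind == "cassette":
            inc = plan.exons_t
            skip = [iv for i, iv in enumerate(plan.exons_t) if i != plan.cassette_idx]
            transcripts[f"{plan.gene_id}_t_inc"] = inc
            transcripts[f"{plan.gene_id}_t_skip"] = skip
        elif plan.kind == "ALE":
            transcripts[f"{plan.gene_id}_t_ale1"] = plan.exons_t[:-1]
            transcripts[f"{plan.gene_id}_t_ale2"] = plan.exons_t[:-2] + [plan.exons_t[-1]]
        else:
            transcripts[f"{plan.gene_id}_t1"] = plan.exons_t
        transcripts_g = {
            tx: sorted(
                _transcript_to_genomic(iv, gene_start, plan.length, plan.strand)
                for iv in ivs
            )
            for tx, ivs in transcripts.items()
        }
        if plan.strand == "+":
            tu_start, tu_end = gene_start, min(gene_end + 10_000, chrom_len)
        else:
            tu_start, tu_end = max(0, gene_start - 10_000), gene_end
        genes.append(
            GeneModel(plan.gene_id, chrom, plan.strand, gene_start, gene_end,
                      tu_start, tu_end, exons=exons_g, transcripts=transcripts_g)
        )

    genome = Genome({chrom: "".join(seq)})
    events = pd.DataFrame(
        event_rows,
        columns=["event_id", "gene_id", "kind", "exon_start", "exon_end",
                 "psi_wsc", "psi_mn", "coupled_site_id"],
    )
    truth = SyntheticTruth(
        planted_sites=sites,
        events=events,
        artifact_anchors=anchors,
        gene_weights=gene_weights,
    )
    _check_coupling(truth)
    return genome, genes, truth


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_clip_reads(genome: Genome, genes, truth: SyntheticTruth,
                        params: SimulationParams) -> list[AlignedRead]:
    """Simulate deduplicated CLIP read alignments for both conditions.

    Per replicate and gene the read count is Poisson with mean
    ``depth * weight * condition_scale / n_reps``; each read is an RT
    artifact with probability ``artifact_fraction`` (3' end abutting the
    gene's planted GTGTC), background (uniform start in the transcription
    unit) with probability ``background_fraction``, otherwise anchored on a
    planted site chosen proportionally to intensity x condition multiplier.
    """
    rng = np.random.default_rng([2, params.seed])
    lmin, lmax = params.read_length
    reads: list[AlignedRead] = []
    truth.artifact_read_ids = set()
    counters: dict[tuple[str, int], int] = {}
    gene_sites = {g.gene_id: truth.sites_of(g.gene_id) for g in genes}

    conditions = (
        ("MN", 1.0, params.n_reps_mn),
        ("WSC", params.wsc_depth_scale, params.n_reps_wsc),
    )
    for gene in genes:
        sites = gene_sites[gene.gene_id]
        weight = truth.gene_weights[gene.gene_id]
        centers = np.array([s.center for s in sites], dtype=int)
        anchor = truth.artifact_anchors.get(gene.gene_id)
        for cond, scale, n_reps in conditions:
            if sites:
                w = np.array(
                    [s.base_intensity * (s.mn_multiplier if cond == "MN" else 1.0)
                     for s in sites]
                )
                w = w / w.sum()
            for rep in range(1, n_reps + 1):
                mean = params.depth_mn * scale * weight / n_reps
                n = rng.poisson(mean)
                if n == 0:
                    continue
                lens = rng.integers(lmin, lmax + 1, size=n)
                u = rng.random(n)
                is_artifact = (u < params.artifact_fraction) & (anchor is not None)
                is_background = ~is_artifact & (
                    (u < params.artifact_fraction + params.background_fraction)
                    | (len(sites) == 0)
                )
                starts = np.empty(n, dtype=int)
                n_bg = int(is_background.sum())
                if n_bg:
                    starts[is_background] = rng.integers(
                        gene.tu_start,
                        np.maximum(gene.tu_end - lens[is_background], gene.tu_start) + 1,
                    )
                site_mask = ~is_artifact & ~is_background
                n_site = int(site_mask.sum())
                if n_site:
                    idx = rng.choice(len(sites), p=w, size=n_site)
                    jitter = rng.integers(-params.site_jitter, params.site_jitter + 1,
                                          size=n_site)
                    starts[site_mask] = centers[idx] - lens[site_mask] // 2 + jitter
                if is_artifact.any():
                    if gene.strand == "+":
                        starts[is_artifact] = anchor - lens[is_artifact]
                    else:
                        starts[is_artifact] = anchor + 5
                starts = np.clip(starts, gene.tu_start, gene.tu_end - lens)
                key = (cond, rep)
                base = counters.get(key, 0)
                for i in range(n):
                    rid = f"r{base + i}"
                    read = AlignedRead(gene.chrom, int(starts[i]),
                                       int(starts[i] + lens[i]), gene.strand,
                                       cond, rep, rid)
                    reads.append(read)
                    if is_artifact[i]:
                        truth.artifact_read_ids.add(f"{cond}:{rep}:{rid}")
                counters[key] = base + n
    truth.library_sizes = dict(counters)
    return reads


def simulate_junction_counts(truth: SyntheticTruth, params: SimulationParams) -> pd.DataFrame:
    """Junction-count table for every event in the truth.

    Per replicate the event coverage is Poisson(splicing_depth); cassette
    inclusion junctions are two independent Binomial(coverage, psi) draws
    and the skip junction Binomial(coverage, 1 - psi); ALE reads split
    Binomial(coverage, usage) between the two last exons.
    """
    rng = np.random.default_rng([3, params.seed])
    rows = []
    for rec in truth.events.itertuples(index=False):
        for cond, psi in (("MN", rec.psi_mn), ("WSC", rec.psi_wsc)):
            for rep in range(1, params.n_rnaseq_reps + 1):
                cov = int(rng.poisson(params.splicing_depth))
                if rec.kind == "cassette":
                    inc1 = int(rng.binomial(cov, psi)) if cov else 0
                    inc2 = int(rng.binomial(cov, psi)) if cov else 0
                    skip = int(rng.binomial(cov, 1.0 - psi)) if cov else 0
                else:
                    inc1 = int(rng.binomial(cov, psi)) if cov else 0
                    inc2 = 0
                    skip = cov - inc1
                rows.append(
                    {"event_id": rec.event_id, "gene_id": rec.gene_id,
                     "kind": rec.kind, "condition": cond, "replicate": rep,
                     "inc1": inc1, "inc2": inc2, "skip": skip}
                )
    return pd.DataFrame(
        rows, columns=["event_id", "gene_id", "kind", "condition", "replicate",
                       "inc1", "inc2", "skip"]
    )


@dataclass
class SimulatedDataset:
    params: SimulationParams
    genome: Genome
    genes: list[GeneModel]
    truth: SyntheticTruth
    reads: list[AlignedRead]
    junction_counts: pd.DataFrame

    @property
    def mn_reads(self):
        return [r for r in self.reads if r.condition == "MN"]

    @property
    def wsc_reads(self):
        return [r for r in self.reads if r.condition == "WSC"]


def simulate_dataset(params: SimulationParams) -> SimulatedDataset:
    """Full study simulation: genome, genes, reads and junction counts."""
    genome, genes, truth = generate_genome_and_genes(params)
    reads = simulate_clip_reads(genome, genes, truth, params)
    junctions = simulate_junction_counts(truth, params)
    return SimulatedDataset(params, genome, genes, truth, reads, junctions)
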