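# Methods

This note records the models behind each pipeline stage, the parameters
that matter, what the synthetic generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Input model and conventions

All intervals are 0-based half-open on genomic coordinates. Reads arrive
as stranded BED6 alignments whose name column encodes
`condition:replicate:read_id`; mapping itself is upstream of this
package. Gene models come from GTF; a gene's *transcription unit* is its
span extended 10,000 nt past the 3′ end (strand-aware, clipped at
chromosome bounds), emulating gene regions compiled with their downstream
10 kb. Reads are assigned to the unit containing their midpoint on the
matching strand.

## Preprocessing

*Deduplication* collapses reads to one per (chrom, start, end, strand)
within a replicate, keep-first. Degenerate-barcode collapsing is not
modelled; exact-position collapse is the conservative stand-in.

*RT-artifact filter.* Reverse transcription can be primed internally by
GUGUC-like pentamers, preferentially amplifying reads that end
immediately upstream of one. For every read the strand-aware 5-mer
starting right after its 3′ end is extracted; pentamers are ranked by
frequency over the pooled dataset (both conditions — the artifact is a
global chemistry effect), and reads whose pentamer is a top-20 member
within Hamming distance 1 of GTGTC are removed. The alternative reading
("the 20 most frequent among GTGTC-like pentamers") is available as
`rule="like-then-top"`. Reads with under 5 nt of chromosome flank cannot
be evaluated and are kept, so chromosome-edge genes are not biased.

## Peak calling

Null: a gene's R_g reads fall uniformly over its unit (length G_g), so
per-base coverage ≈ Poisson(λ_g), λ_g = R_g·L̄/G_g with L̄ the mean read
length. The significance height k\* is the smallest k whose Poisson upper
tail, Bonferroni-corrected, is ≤ α (default 0.01); peaks are maximal runs
of coverage ≥ k\*, with per-peak p the corrected tail at the run maximum.

The Bonferroni count is the *per-position* count G_g. Window-based counts
(G/L̄ or 2G/L̄) were measured over 80 simulated null seeds and are
anti-conservative here (2–4% of genes acquire a false peak at α = 0.01):
threshold exceedances are narrow spikes pinned to read boundaries, so the
effective number of opportunities is far larger than the window count.
With the per-position bound the measured null rate is ~0.1% of genes,
and the loss of power is immaterial because true site stacks sit far
above k\* (tens to hundreds of reads over a 20–40 nt cluster). Gene-level
(not transcriptome-level) control is used; each gene's α is spent on its
own unit.

Peak boundaries are the maximal run at k\*, which is deterministic and
parameter-free; summit height, raw read count (peak height, PH), and
reads-per-million normalized height are recorded per peak.

## Joint peaks and the site-wise differential test

Joint peaks (JPs) are peaks called on pooled MN+WSC reads, retained when
MN contributes reads from ≥ 4 of 8 replicates or WSC from ≥ 2 of 4
(biological complexity, BC). Each JP is classed *exon* or *intron* by its
midpoint; midpoints in the downstream-10 kb extension fold into the
non-exonic (intron) family, since only intronic and exonic families are
tested. Per gene and family, M and N are the totals of MN and WSC reads
over all retained JPs.

The site test is Fisher's exact test on [[m, M−m], [n, N−n]], two-sided
by the "sum of tables at most as probable" rule, computed from the
hypergeometric log-pmf so extreme tails stay accurate. Coverage is the
smallest cell; JPs under coverage 10 are untested. BH runs within each
family over tested JPs only. Fold change is the ratio of relative peak
heights (100·m/M over 100·n/N) — the axes of the published pairwise
comparisons — and calls require FDR ≤ 0.1 with fold ≥ 2 (over) or ≤ 1/2
(under).

The statistic is *compositional*: relative heights within a gene sum to
100 per condition, so a genuine gain at one site necessarily depresses
every companion site's relative share. This is a property of the method,
not an artifact; it is why truth scoring on synthetic data evaluates
calls against the *induced relative fold* (planted multiplier divided by
the gene's site-mass inflation), and why the fold ≥ 2 filter matters in
practice.

## Gene-wise enrichment

Gene-level differential CLIP coverage uses a conditional exact binomial:
given a gene's total in-peak reads T = mn + wsc, under the null
mn ~ Binomial(T, lib_MN/(lib_MN+lib_WSC)). Two-sided exact p, BH across
genes, direction called at FDR ≤ 0.01, log2 fold with a 0.5 pseudo-count.
This replaces a negative-binomial tagwise-dispersion fit with a
deterministic, calibration-tested engine; with pooled counts and
library-size conditioning it is the exact small-sample analogue of the
same comparison. Overdispersion across replicates is not modelled; on
data with strong biological gene-level scatter the test is liberal, which
is acceptable here because the package's claims rest on the site-level
statistics.

## Motif and conservation profiles

Motif classes on the DNA alphabet (T for U): YCAY (Y ∈ {C,T}); YYYY; and
U-rich, exactly the 4-mers with ≥ 2 T. Positional profiles report, per
offset x ∈ [−w, +w] from the peak center (floor midpoint, strand
oriented), the fraction of peaks with a class 4-mer starting at x,
normalised by the i.i.d. expectation from mononucleotide composition
(genome-wide by default). The windowed tetramer test counts all 4-mer
occurrences 100 nt around target and background peak centers and scores
each tetramer by the hypergeometric upper tail of its target occurrences
among background occurrences, BH over all 256 tetramers; overlapping
windows double-count by design. Conservation profiles average an input
per-base score track (phastCons-like, in [0,1]) per offset with normal
95% CIs; bases missing from the track are missing, not zero.

## Splicing

Cassette events: per condition, pooled inclusion I = (ΣI1 + ΣI2)/2 over
the two inclusion junctions, exclusion E = Σ skip-junction counts,
ψ = I/(I+E), dI = ψ_MN − ψ_WSC. Significance is Fisher's exact test on
the pooled [[I_MN, E_MN], [I_WSC, E_WSC]] with inclusion averages rounded
half-even (bias checked by the dI-recovery suite: |mean error| < 0.002 at
coverage 100, bound 0.02). Events are *expressed* when pooled junction
coverage exceeds 10 (strictly) in both conditions; BH runs within event
kind over expressed events only. Biological consistency requires every
cross-condition replicate pair to agree with the pooled dI sign.
Significance: FDR ≤ 0.1 and consistency; ALEs (quantified identically
from the junction reads into each terminal exon) additionally require
|dI| ≥ 0.2. For genes with more than two terminal exons, events are
emitted per ALE against the rest.

## The RNA map

A tested site predicts the direction of a splicing change when it lies
within the 400-nt hotspot: the window spans the exon body plus 400 nt
into each flanking intron (both published exemplars — 109 nt upstream,
121 nt downstream — fall inside under this reading). Offsets are
strand-aware from the nearest exon boundary, negative upstream. Binding
gained in MN upstream predicts dI < 0, downstream dI > 0;
under-represented sites flip the sign; exonic sites follow the repression
arm (the canonical position rule for this protein family). When several
called sites hit one exon's hotspot the smallest-FDR site wins; ties with
conflicting directions yield no prediction. Concordance is the fraction
of predictions whose sign matches the observed dI among events with
FDR ≤ 0.1; the permutation control shuffles observed event outcomes
across events, breaking the pairing while preserving both marginals.
Site significance is established before the hotspot restriction (filter
order: sites first, then position).

## Synthetic data: what it emulates, and what it does not

The generator writes a study onto one simulated chromosome: i.i.d.
uniform background sequence; 4–8 exon genes of 5–10 kb separated by 12 kb
gaps; per-gene lognormal expression weights shared by both conditions;
8 MN vs 4 WSC replicates with WSC holding 8× the reads (the published
depth asymmetry); read lengths uniform on 30–80 nt. Binding sites are
20–40 nt clusters with ≥ 3 YCAY elements written into introns, ≥ 100 nt
apart so one coverage peak corresponds to one site; site-anchored reads
jitter ±10 nt around the site center. At most one site per gene carries a
condition multiplier (default fourfold up or down in MN, 10% of genes):
differential binding is modelled as sparse site-specific redistribution,
matching the ~1–2% differential-site rate the method is designed for and
keeping the compositional statistic interpretable. 35% of genes carry a
cassette exon and 15% an ALE pair; 80% of cassette genes couple their
event to a differential site planted inside the hotspot with the
inclusion shift's sign set by the position rule and |ΔdI| ∈ [0.2, 0.5]
(spanning the published dI magnitudes). RT-artifact reads (5% by default)
end exactly at a planted GTGTC. Junction counts are Poisson coverage
(50 per replicate, 2 replicates per condition, i.e. per-condition
coverage ~100) with binomial splits at the true ψ.

Not emulated: sequencing errors, crosslink-site chemistry and truncation
biases, PCR duplication beyond exact-position duplicates,
condition-specific transcript abundance (gene weights are shared, so the
gene-wise engine is exercised by its own null/alternative simulations
rather than end-to-end), exonic/3′UTR binding sites in the coupled truth,
and overlapping genes. Passing recovery tests therefore demonstrates the
statistics behave as designed under the study's sampling model, not that
real libraries are free of these further effects.

## Problem sizes and determinism

Simulated studies in the test suite and acceptance script use 24–96 genes
per seed (10 seeds for recovery/concordance, 20 for peak-null
calibration, 3–5 for the other calibrations) — large enough that each
suite aggregates hundreds of sites/genes per estimate while the whole
suite completes in minutes. The generator's own defaults (200 genes)
define the reference study scale. All randomness flows from explicit
seeds through numpy Generators; identical parameters and seed reproduce
byte-identical FASTA/GTF/BED outputs. Exact tests compare hypergeometric
point masses with a 1e-13 relative tie tolerance; extreme tails are
carried in log space and exponentiated on output.

## Known limitations

- The Poisson-height peak caller ignores within-gene rate variation
  (e.g., intron/exon coverage structure in RNA-abundance-driven data);
  its null is per-gene uniform, as designed for CLIP tag background.
- The site test conditions on gene totals M, N; genes whose binding
  changes uniformly across all sites are invisible to it by construction
  (that signal belongs to the gene-wise engine).
- BC for splicing is implemented as cross-replicate sign consistency;
  other operationalisations exist.
- The ALE quantifier is junction-based only; 3′-coverage-based usage
  estimation is out of scope.
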